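"""Synthetic inputs with exactly known ground truth.

The package analyzes three kinds of data that originate, in the laboratory,
from gel-shift titrations, simulated-annealing (SA) conformational ensembles
and conjugate design tables.  This module generates all three from explicit
specifications so that every downstream statistic has a known expected
value:

* titration series drawn from the single-site binding model plus additive
  truncated Gaussian noise (the error character of gel densitometry);
* multi-model coordinate ensembles in which the number of frames with an
  in-line attack angle above threshold, and the number of frames with a
  guanidinium nitrogen within the proximity cutoff, are planted exactly;
* conjugate/target sequence families whose hybridization yields requested
  bulge-loop sizes by construction;
* SA schedule descriptors (bookkeeping only — no physics is simulated).

Every generator takes an explicit integer seed and uses its own
``numpy.random.Generator``; no global random state is touched, and output is
byte-identical across runs for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binding import fraction_bound
from .ensemble import Atom, Ensemble, Frame
from .geometry import DEFAULT_PROXIMITY_CUTOFF, DEFAULT_THETA_THRESHOLD, GUANIDINIUM_NITROGENS
from .sequences import ConjugateDesign, NucleotideSequence, bulge_size, hybridize, reverse_complement

__all__ = [
    "TitrationSpec",
    "EnsembleSpec",
    "SASchedule",
    "SpecError",
    "simulate_titration",
    "simulate_ensemble",
    "make_design_family",
    "schedule_total_time",
    "reference_sa_schedule",
]


class SpecError(ValueError):
    """Inconsistent generator specification."""


# ---------------------------------------------------------------------------
# titrations


@dataclass(frozen=True)
class TitrationSpec:
    """Ground truth for one simulated titration.

    Defaults mirror the study conditions: target RNA at 1 μM, conjugate
    titrated over 0.25–10 μM, and a fraction-bound read-out noise of
    sd 0.02 (gel densitometry scale).
    """

    ka_true: float                       # M^-1
    rna_total: float = 1e-6              # M
    bc_grid: tuple[float, ...] = (0.25e-6, 0.5e-6, 1e-6, 2e-6, 3e-6, 5e-6, 7.5e-6, 10e-6)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.ka_true <= 0:
            raise SpecError("ka_true must be positive")
        if not self.bc_grid:
            raise SpecError("bc_grid must be non-empty")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def simulate_titration(spec: TitrationSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate fraction-bound observations under the binding model.

    α_i = clamp(α_model(Kₐ, [BC]ᵢ, [RNA]₀) + N(0, noise_sd), [0, 0.999]).
    Returns (series table, ground-truth record).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for bc in spec.bc_grid:
        alpha = fraction_bound(spec.ka_true, bc, spec.rna_total)
        if spec.noise_sd > 0:
            alpha += rng.normal(0.0, spec.noise_sd)
        rows.append(
            {
                "bc_total": bc,
                "rna_total": spec.rna_total,
                "alpha": float(np.clip(alpha, 0.0, 0.999)),
            }
        )
    truth = {"ka_true": spec.ka_true, "noise_sd": spec.noise_sd, "seed": spec.seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# coordinate ensembles


@dataclass(frozen=True)
class EnsembleSpec:
    """Planted geometry statistics for a synthetic ensemble.

    For each scissile site (given by its attack residue number) the spec
    fixes how many of the ``n_frames`` frames carry an in-line angle above
    the threshold (``planted_inline``) and how many have one arginine's
    guanidinium nitrogen within the proximity cutoff of both O2' and P
    (``planted_productive``).  All other guanidinium distances are drawn
    from ``distance_background`` (Å), which must start above the cutoff so
    the planted counts are exact.

    ``n_frames`` defaults to 100, one frame per annealing round of the
    emulated SA protocol.
    """

    sites: tuple[int, ...]
    n_frames: int = 100
    planted_inline: tuple[tuple[int, int], ...] = ()     # (attack residue, count)
    planted_productive: tuple[tuple[int, int], ...] = () # (attack residue, count)
    theta_above: float = 165.0
    theta_below: float = 120.0
    theta_threshold: float = DEFAULT_THETA_THRESHOLD
    arg_residues: tuple[int, ...] = (201, 203, 205, 207)
    cutoff: float = DEFAULT_PROXIMITY_CUTOFF
    distance_background: tuple[float, float] = (10.0, 43.0)
    seed: int = 0

    def __post_init__(self):
        if not self.sites:
            raise SpecError("at least one site required")
        if self.n_frames < 1:
            raise SpecError("n_frames must be positive")
        for name, planted in (("inline", self.planted_inline), ("productive", self.planted_productive)):
            for res, count in planted:
                if res not in self.sites:
                    raise SpecError(f"{name} plant for unknown site {res}")
                if not 0 <= count <= self.n_frames:
                    raise SpecError(f"{name} plant count {count} outside 0..{self.n_frames}")
        if sum(c for _, c in self.planted_productive) > self.n_frames:
            raise SpecError("total productive plants exceed frame count")
        if not (self.theta_above > self.theta_threshold >= self.theta_below):
            raise SpecError("need theta_below <= threshold < theta_above")
        lo, hi = self.distance_background
        if lo <= self.cutoff + 3.0:
            # 3 Å is the O2'-P separation used below; the margin guarantees
            # background placements can never satisfy the criterion
            raise SpecError("background distances must start > cutoff + 3 Å")
        if hi <= lo:
            raise SpecError("empty background distance range")
        if not self.arg_residues:
            raise SpecError("at least one arginine residue required")


_O2P_SEP = 3.0     # Å, O2'(i) to P(i+1) in the synthetic triples
_PO5_BOND = 1.59   # Å


def _site_frame_atoms(base: np.ndarray, attack_res: int, theta_deg: float) -> list[Atom]:
    """One site's O2'/P/O5' pseudo-residue pair at the requested Θ."""
    p = base
    o5 = base + np.array([_PO5_BOND, 0.0, 0.0])
    t = np.radians(theta_deg)
    o2 = base + _O2P_SEP * np.array([np.cos(t), np.sin(t), 0.0])
    return [
        Atom(attack_res, "SYN", "O2'", "O", tuple(o2)),
        Atom(attack_res + 1, "SYN", "P", "P", tuple(p)),
        Atom(attack_res + 1, "SYN", "O5'", "O", tuple(o5)),
    ]


def _near_point(p_pos: np.ndarray, o2_pos: np.ndarray) -> np.ndarray:
    """A point within ~3 Å of both P and O2' (productive placement)."""
    mid = 0.5 * (p_pos + o2_pos)
    half = 0.5 * np.linalg.norm(o2_pos - p_pos)
    h = np.sqrt(max(9.0 - half * half, 0.25))
    return mid + np.array([0.0, 0.0, h])


def _background_point(
    rng: np.random.Generator,
    p_pos: np.ndarray,
    o2_pos: np.ndarray,
    lo: float,
    hi: float,
    cutoff: float,
) -> np.ndarray:
    """Random point at distance U(lo, hi) from P, rejected until it also
    clears the cutoff from O2' (always terminates: lo > cutoff + |O2'P|)."""
    while True:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = p_pos + rng.uniform(lo, hi) * u
        # 1 Å clearance absorbs the <=0.6 Å nitrogen scatter around the center
        if np.linalg.norm(pos - o2_pos) > cutoff + 1.0:
            return pos


def simulate_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, dict]:
    """Build a synthetic multi-frame ensemble with exact planted statistics.

    Topology: per site, a two-pseudo-residue triple (O2' on residue i; P and
    O5' on residue i+1) placed in its own spatial region 200 Å from the
    next site; per arginine residue, the three guanidinium nitrogens NE,
    NH1, NH2 (residue name ARG).  Residue name SYN marks the synthetic
    nucleotide stand-ins.

    Returns (ensemble, ground truth) where the truth record carries the
    per-site theta series and the exact planted inline/productive counts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    inline_counts = dict(spec.planted_inline)
    productive_counts = dict(spec.planted_productive)
    site_base = {res: np.array([200.0 * k, 0.0, 0.0]) for k, res in enumerate(spec.sites)}

    # choose which frames carry the in-line angle, per site
    theta_by_site: dict[int, np.ndarray] = {}
    for res in spec.sites:
        k = inline_counts.get(res, 0)
        thetas = np.full(n, spec.theta_below, dtype=float)
        hot = rng.choice(n, size=k, replace=False)
        thetas[hot] = spec.theta_above
        theta_by_site[res] = thetas

    # choose disjoint productive frames across sites, and a serving arginine
    pool = rng.permutation(n)
    cursor = 0
    productive_plan: dict[int, dict[int, int]] = {}  # frame -> {site: arg index}
    for res in spec.sites:
        k = productive_counts.get(res, 0)
        for j in range(k):
            f = int(pool[cursor])
            cursor += 1
            productive_plan.setdefault(f, {})[res] = j % len(spec.arg_residues)

    lo, hi = spec.distance_background
    frames: list[Frame] = []
    for f in range(n):
        atoms: list[Atom] = []
        geom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for res in spec.sites:
            site_atoms = _site_frame_atoms(site_base[res], res, theta_by_site[res][f])
            atoms.extend(site_atoms)
            geom[res] = (np.array(site_atoms[1].xyz), np.array(site_atoms[0].xyz))  # (P, O2')
        served = productive_plan.get(f, {})
        arg_site = {a_idx: res for res, a_idx in served.items()}
        for a_idx, arg_res in enumerate(spec.arg_residues):
            if a_idx in arg_site:
                p_pos, o2_pos = geom[arg_site[a_idx]]
                center = _near_point(p_pos, o2_pos)
            else:
                ref = spec.sites[int(rng.integers(len(spec.sites)))]
                p_pos, o2_pos = geom[ref]
                center = _background_point(rng, p_pos, o2_pos, lo, hi, spec.cutoff)
            # the three nitrogens cluster within ~1.2 Å of the guanidinium
            # center, far smaller than the margin separating planted from
            # background placements
            for name in GUANIDINIUM_NITROGENS:
                offset = rng.normal(scale=0.2, size=3)
                offset *= min(1.0, 0.6 / max(np.linalg.norm(offset), 1e-9))
                atoms.append(Atom(arg_res, "ARG", name, "N", tuple(center + offset)))
        frames.append(Frame(atoms=tuple(atoms), frame_index=f))

    truth = {
        "n_frames": n,
        "seed": spec.seed,
        "theta_threshold": spec.theta_threshold,
        "cutoff": spec.cutoff,
        "sites": {
            int(res): {
                "theta_series": theta_by_site[res].tolist(),
                "inline_count": int(inline_counts.get(res, 0)),
                "inline_probability": inline_counts.get(res, 0) / n,
                "productive_count": int(productive_counts.get(res, 0)),
                "productive_fraction": productive_counts.get(res, 0) / n,
            }
            for res in spec.sites
        },
    }
    ensemble = Ensemble(frames=frames, provenance=f"synthetic ensemble seed={spec.seed}")
    return ensemble, truth


# ---------------------------------------------------------------------------
# design families


def make_design_family(
    bulge_sizes: Sequence[int],
    core: str | None = None,
    attachment: Literal["modified_adenosine", "abasic_alpha", "abasic_beta"] = "abasic_beta",
    seed: int | None = None,
    core_length: int = 40,
) -> tuple[NucleotideSequence, list[ConjugateDesign]]:
    """A local RNA target plus conjugates inducing the requested bulge sizes.

    Default target is the 23-nt local window of the study system
    (5'-UUCGAUC·CACAG·AAUUCGCACCA-3'); the 5' arm is fixed and the 3' arm is
    truncated from the fully complementary 12-mer by the requested bulge
    size.  With ``core`` or ``seed`` given, a synthetic target is used or
    generated instead, with arms built as exact reverse complements of its
    flanks (placements re-checked by exhaustive search; ambiguous random
    cores are re-drawn).
    """
    if any(not 0 <= s <= 8 for s in bulge_sizes):
        raise SpecError("bulge sizes must lie in 0..8")

    if core is None and seed is None:
        target = NucleotideSequence.from_str("UUCGAUCCACAGAAUUCGCACCA", "RNA")
    elif core is not None:
        target = NucleotideSequence.from_str(core, "RNA")
    else:
        rng = np.random.default_rng(seed)
        for _ in range(100):
            letters = rng.choice(list("ACGU"), size=core_length)
            candidate = NucleotideSequence.from_str("".join(letters), "RNA")
            if _family_fits(candidate, bulge_sizes):
                target = candidate
                break
        else:
            raise SpecError("could not draw an unambiguous random target")

    arm5_len = min(11, len(target) // 3)
    max_size = max(bulge_sizes)
    if len(target) < arm5_len + max_size + 2:
        raise SpecError(f"target too short for a {max_size}-nt bulge")

    arm5 = reverse_complement(
        NucleotideSequence.from_str(str(target)[-arm5_len:], "RNA"), "DNA"
    )
    designs = []
    for s in bulge_sizes:
        left_len = len(target) - arm5_len - s
        if left_len < 1:
            raise SpecError(f"bulge size {s} incompatible with target length {len(target)}")
        arm3 = reverse_complement(
            NucleotideSequence.from_str(str(target)[:left_len], "RNA"), "DNA"
        )
        designs.append(
            ConjugateDesign(
                name=f"fam-bulge{s}",
                arm5=arm5,
                arm3=arm3,
                attachment=attachment,
                peptide="acetyl-[LRLRG]2-CO2H",
                peptide_length_A=36.5,
                linker_length_A=8.6,
            )
        )
    return target, designs


def _family_fits(target: NucleotideSequence, bulge_sizes: Sequence[int]) -> bool:
    try:
        _, designs = make_design_family(bulge_sizes, core=str(target))
        for s, d in zip(bulge_sizes, designs):
            if bulge_size(hybridize(d, target)) != s:
                return False
    except Exception:
        return False
    return True


# ---------------------------------------------------------------------------
# SA schedule descriptors


@dataclass(frozen=True)
class SASchedule:
    """Bookkeeping descriptor of a simulated-annealing MD protocol.

    The restraint force constant is stored verbatim with its unit string;
    no unit normalization is attempted.
    """

    segments: tuple[tuple[str, float, float, float], ...]  # (kind, ns, T_start, T_end)
    rounds: int = 100
    restraint_force_constant: str = "0.01 kcal⋅mol−1⋅Å−1"
    salt_M: float = 0.1
    solvent_model: str = "GB implicit (igb=1)"
    timestep_fs: float = 1.0
    nonbonded_cutoff_A: float = 9999.0

    def __post_init__(self):
        if not self.segments:
            raise SpecError("schedule must contain at least one segment")
        for kind, dur, t0, t1 in self.segments:
            if kind not in ("heat", "equilibrate", "cool"):
                raise SpecError(f"unknown segment kind {kind!r}")
            if dur <= 0:
                raise SpecError("segment durations must be positive")
            if kind in ("heat", "cool") and t0 == t1:
                raise SpecError(f"{kind} segment must change temperature")


def schedule_total_time(schedule: SASchedule) -> float:
    """Total simulated time per SA step (ns): sum of segment durations."""
    return float(sum(dur for _, dur, _, _ in schedule.segments))


def reference_sa_schedule() -> SASchedule:
    """The annealing protocol the synthetic ensembles emulate: heat 300→800 K
    over 0.5 ns, hold 5 ns at 800 K, cool to 300 K over 0.5 ns, hold 5 ns
    at 300 K; 100 rounds per complex."""
    return SASchedule(
        segments=(
            ("heat", 0.5, 300.0, 800.0),
            ("equilibrate", 5.0, 800.0, 800.0),
            ("cool", 0.5, 800.0, 300.0),
            ("equilibrate", 5.0, 300.0, 300.0),
        ),
        rounds=100,
    )
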