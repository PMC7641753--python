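"""Cleavage-competence geometry on conformational ensembles.

RNA transesterification proceeds through 2'-OH attack on the adjacent
phosphodiester: the attacking 2'-oxygen, the phosphorus and the 5'-leaving
oxygen must approach collinearity ("in-line" attack).  For the linkage
between residues i and i+1 the attack angle is

    Θ = ∠ O2'(i) – P(i+1) – O5'(i+1)

and a frame counts as cleavage-competent when Θ exceeds a threshold
(155° by convention here; strictly greater-than).  Catalysis by the
arginine-rich peptide additionally requires a guanidinium group close to the
scissile site: a frame is "productive" when at least one arginine has a
guanidinium nitrogen within a cutoff (default 6 Å) of both O2'(i) and
P(i+1) simultaneously; "dyad" mode demands two distinct arginines satisfy
this at once, modeling cooperative two-guanidinium catalysis.

A coarser reach filter asks whether the unfolded peptide plus linker can
span from the conjugation-point phosphorus to a candidate site's phosphorus
at all (boundary inclusive).

All per-frame statistics weight frames uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .ensemble import Ensemble, Frame, select_atoms
from .sequences import SiteLabel

__all__ = [
    "ScissileSite",
    "InlineReport",
    "DistanceReport",
    "ReachAssessment",
    "GeometryError",
    "MissingAtomError",
    "bond_angle",
    "dihedral",
    "theta_series",
    "inline_probability",
    "guanidinium_distances",
    "productive_fraction",
    "weighted_average_distance",
    "max_reach",
    "reach_classify",
]

GUANIDINIUM_NITROGENS = ("NE", "NH1", "NH2")

DEFAULT_THETA_THRESHOLD = 155.0   # degrees
DEFAULT_PROXIMITY_CUTOFF = 6.0    # Å
HISTOGRAM_BIN_WIDTH = 0.5         # Å
HISTOGRAM_RANGE = (0.0, 45.0)     # Å; observations beyond go to an overflow bin


class GeometryError(ValueError):
    """Degenerate geometry (coincident points, zero-length vectors)."""


class MissingAtomError(KeyError):
    """A required named atom is absent from the topology."""


@dataclass(frozen=True)
class ScissileSite:
    """The linkage attacked at residue i: O2' from i, P and O5' from i+1."""

    attack_residue: int

    @property
    def phosphate_residue(self) -> int:
        return self.attack_residue + 1

    def __str__(self) -> str:
        return f"site {self.attack_residue}-{self.phosphate_residue}"


@dataclass(frozen=True)
class InlineReport:
    site: ScissileSite
    theta_per_frame: np.ndarray    # degrees, one per frame
    threshold: float               # degrees
    inline_probability: float


@dataclass(frozen=True)
class DistanceReport:
    """Per-frame, per-arginine minimum guanidinium-N distances to the site.

    ``distances`` has shape (n_frames, n_arginines, 2): the last axis is
    (distance to O2'(i), distance to P(i+1)), each already minimized over the
    arginine's available guanidinium nitrogens.
    """

    site: ScissileSite
    arg_residues: tuple[int, ...]
    distances: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    def histogram(
        self,
        bin_width: float = HISTOGRAM_BIN_WIDTH,
        limits: tuple[float, float] = HISTOGRAM_RANGE,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(edges, counts) over all (frame, arginine, target-atom)
        observations; a final open bin collects observations beyond the
        upper limit so counts always sum to the number of observations."""
        lo, hi = limits
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        edges = np.append(edges, np.inf)
        counts, _ = np.histogram(self.distances.ravel(), bins=edges)
        return edges, counts


@dataclass(frozen=True)
class ReachAssessment:
    site: SiteLabel
    distance_A: float
    max_reach_A: float

    @property
    def reachable(self) -> bool:
        return self.distance_A <= self.max_reach_A


# ---------------------------------------------------------------------------
# primitives


def bond_angle(p1, p2, p3) -> float:
    """Angle at p2 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1, v2 = p1 - p2, p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, IUPAC convention, (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b1) == 0 or np.linalg.norm(b2) == 0 or np.linalg.norm(b3) == 0:
        raise GeometryError("coincident consecutive points in dihedral computation")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise GeometryError("collinear points leave the torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def _single_index(ensemble: Ensemble, residue: int, atom_name: str) -> int:
    idx = select_atoms(ensemble, {residue}, {atom_name})
    if not idx:
        raise MissingAtomError(f"atom {atom_name} of residue {residue} not in topology")
    if len(idx) > 1:
        raise GeometryError(f"atom {atom_name} of residue {residue} is not unique")
    return idx[0]


# ---------------------------------------------------------------------------
# in-line attack statistics


def theta_series(ensemble: Ensemble, site: ScissileSite) -> np.ndarray:
    """Θ = O2'(i)–P(i+1)–O5'(i+1) per frame (degrees), frame order kept."""
    i_o2 = _single_index(ensemble, site.attack_residue, "O2'")
    i_p = _single_index(ensemble, site.phosphate_residue, "P")
    i_o5 = _single_index(ensemble, site.phosphate_residue, "O5'")
    xyz = ensemble.coords
    v1 = xyz[:, i_o2] - xyz[:, i_p]
    v2 = xyz[:, i_o5] - xyz[:, i_p]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise GeometryError("zero-length vector in theta computation")
    cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def inline_probability(theta: Sequence[float], threshold: float = DEFAULT_THETA_THRESHOLD) -> float:
    """Fraction of frames with Θ strictly above the threshold.

    Counted as an exact integer ratio; frames exactly at the threshold do
    not count.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("empty theta series")
    return int(np.count_nonzero(theta > threshold)) / theta.size


def inline_report(
    ensemble: Ensemble,
    site: ScissileSite,
    threshold: float = DEFAULT_THETA_THRESHOLD,
) -> InlineReport:
    theta = theta_series(ensemble, site)
    return InlineReport(site, theta, threshold, inline_probability(theta, threshold))


# ---------------------------------------------------------------------------
# guanidinium proximity


def guanidinium_distances(
    ensemble: Ensemble,
    arg_residues: Sequence[int],
    site: ScissileSite,
) -> DistanceReport:
    """Minimum guanidinium-N distance to O2'(i) and to P(i+1), per frame and
    per arginine (recorded separately for the two target atoms)."""
    i_o2 = _single_index(ensemble, site.attack_residue, "O2'")
    i_p = _single_index(ensemble, site.phosphate_residue, "P")
    xyz = ensemble.coords
    targets = xyz[:, [i_o2, i_p]]                      # (frames, 2, 3)

    per_arg = []
    for res in arg_residues:
        n_idx = select_atoms(ensemble, {res}, set(GUANIDINIUM_NITROGENS))
        if not n_idx:
            raise MissingAtomError(
                f"no guanidinium nitrogens (NE/NH1/NH2) found for residue {res}"
            )
        npos = xyz[:, n_idx]                           # (frames, nN, 3)
        d = np.linalg.norm(npos[:, :, None, :] - targets[:, None, :, :], axis=-1)
        per_arg.append(d.min(axis=1))                  # (frames, 2)
    distances = np.stack(per_arg, axis=1)              # (frames, n_args, 2)
    return DistanceReport(site, tuple(arg_residues), distances)


def productive_fraction(
    report: DistanceReport,
    cutoff: float = DEFAULT_PROXIMITY_CUTOFF,
    mode: Literal["single", "dyad"] = "single",
) -> float:
    """Fraction of frames meeting the guanidinium proximity criterion.

    ``single``: some arginine lies within the cutoff of both O2'(i) and
    P(i+1) in the same frame.  ``dyad``: at least two distinct arginines do,
    so the dyad fraction can never exceed the single fraction.
    """
    ok = np.all(report.distances <= cutoff, axis=2)    # (frames, n_args)
    per_frame = ok.sum(axis=1)
    need = 1 if mode == "single" else 2
    if mode not in ("single", "dyad"):
        raise ValueError(f"unknown mode {mode!r}")
    return int(np.count_nonzero(per_frame >= need)) / report.n_frames


def weighted_average_distance(report: DistanceReport) -> float:
    """Mean over all (frame, arginine, target-atom) distance observations.

    Identical to the histogram-weighted mean, since every observation falls
    in exactly one bin with unit weight.
    """
    return float(report.distances.mean())


# ---------------------------------------------------------------------------
# peptide reach


def max_reach(peptide_length_A: float, linker_length_A: float) -> float:
    """Farthest P→P span the catalytic peptide can bridge (Å): unfolded
    peptide length plus linker length."""
    if peptide_length_A <= 0 or linker_length_A <= 0:
        raise ValueError("lengths must be positive")
    return peptide_length_A + linker_length_A


def reach_classify(
    structure: Frame | Ensemble,
    attachment_residue: int,
    sites: Sequence[SiteLabel],
    max_reach_A: float,
) -> list[ReachAssessment]:
    """Classify sites as peptide-reachable on a single structure.

    Distance is measured between the phosphorus of the attachment residue
    and the phosphorus of each site's 3'-residue (the scissile phosphate);
    a site at exactly the maximum reach counts as reachable.
    """
    if isinstance(structure, Ensemble):
        ens = structure
        if ens.n_frames != 1:
            raise ValueError("reach classification expects a single structure")
    else:
        ens = Ensemble(frames=[structure])
    i_att = _single_index(ens, attachment_residue, "P")
    p_att = ens.coords[0, i_att]
    out = []
    for site in sites:
        i_p = _single_index(ens, site.residue_3, "P")
        d = float(np.linalg.norm(ens.coords[0, i_p] - p_att))
        out.append(ReachAssessment(site=site, distance_A=d, max_reach_A=max_reach_A))
    return out
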