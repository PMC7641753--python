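"""Sequence-level design of bulge-loop-inducing conjugates.

A bulge-loop-inducing conjugate (BC) carries two DNA recognition arms joined
through a peptide attachment point — either an aminohexyl-modified adenosine
(``A*``, which still pairs as A) or an abasic sugar residue (``X``, which never
pairs).  Hybridized to its RNA target, the arms clamp the flanking regions
while the non-complementary stretch opposite the attachment point is forced
into a single-stranded bulge-loop, the intended cleavage site.

This module models that design arithmetic: Watson–Crick reverse complements,
exhaustive arm placement on a target, bulge derivation, mer-counting, and
classification of internucleotide linkages (bulge / duplex / junction /
dangling) under the study's residue numbering.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "NucleotideSequence",
    "ConjugateDesign",
    "HybridComplex",
    "SiteLabel",
    "SequenceError",
    "PlacementError",
    "AmbiguousPlacementError",
    "SiteValidationError",
    "reverse_complement",
    "hybridize",
    "bulge_size",
    "motif_length",
    "classify_site",
    "region_map",
    "read_target_fasta",
    "load_conjugate_table",
    "packaged_conjugate_table",
]

Alphabet = Literal["DNA", "RNA"]

_DNA = set("ACGT")
_RNA = set("ACGU")
_SPECIAL = {"A*", "X"}

# Watson–Crick complements keyed by (symbol, output alphabet).
_COMPLEMENT = {
    ("A", "DNA"): "T", ("A", "RNA"): "U",
    ("C", "DNA"): "G", ("C", "RNA"): "G",
    ("G", "DNA"): "C", ("G", "RNA"): "C",
    ("T", "DNA"): "A", ("T", "RNA"): "A",
    ("U", "DNA"): "A", ("U", "RNA"): "A",
}


class SequenceError(ValueError):
    """Invalid nucleotide sequence or operation on one."""


class PlacementError(ValueError):
    """A recognition arm has no exact-complement placement on the target."""


class AmbiguousPlacementError(PlacementError):
    """A recognition arm matches the target in more than one register."""

    def __init__(self, arm: str, candidates: Sequence[int]):
        self.candidates = list(candidates)
        super().__init__(
            f"arm {arm!r} has {len(self.candidates)} placements on the target "
            f"(1-based starts: {self.candidates}); supply an unambiguous design"
        )


class SiteValidationError(ValueError):
    """A site label's base letters disagree with the target sequence."""


def _tokenize(text: str) -> tuple[str, ...]:
    """Split a sequence string into residue tokens, accepting 'A*' and 'X'.

    Hyphens used as visual separators (as in ``TGGTGCGAATT-A*-GTGGATCGAA``)
    are ignored.
    """
    tokens: list[str] = []
    i = 0
    text = text.strip().upper()
    while i < len(text):
        ch = text[i]
        if ch in "- ":
            i += 1
            continue
        if ch == "A" and i + 1 < len(text) and text[i + 1] == "*":
            tokens.append("A*")
            i += 2
        else:
            tokens.append(ch)
            i += 1
    return tuple(tokens)


@dataclass(frozen=True)
class NucleotideSequence:
    """An ordered 5'→3' nucleotide sequence over DNA or RNA.

    Besides the four standard letters, two special residues are allowed:
    ``A*`` (aminohexyl-modified adenosine, pairs as A) and ``X`` (abasic
    sugar, never pairs).  At most one special residue may appear.
    """

    tokens: tuple[str, ...]
    alphabet: Alphabet

    def __post_init__(self):
        if not self.tokens:
            raise SequenceError("empty sequence")
        valid = _DNA if self.alphabet == "DNA" else _RNA
        if self.alphabet not in ("DNA", "RNA"):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        specials = 0
        for t in self.tokens:
            if t in _SPECIAL:
                specials += 1
            elif t not in valid:
                raise SequenceError(
                    f"symbol {t!r} not in {self.alphabet} alphabet or {{A*, X}}"
                )
        if specials > 1:
            raise SequenceError("at most one special residue (A*/X) allowed")

    @classmethod
    def from_str(cls, text: str, alphabet: Alphabet) -> "NucleotideSequence":
        return cls(_tokenize(text), alphabet)

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return "".join(self.tokens)

    def __getitem__(self, i) -> str:
        return self.tokens[i]


def reverse_complement(seq: NucleotideSequence, out_alphabet: Alphabet) -> NucleotideSequence:
    """Reverse complement under Watson–Crick pairing.

    ``A*`` complements as A.  The abasic residue ``X`` has no complement and
    is rejected.  Involution holds when input and output alphabets agree.
    """
    out: list[str] = []
    for t in reversed(seq.tokens):
        if t == "X":
            raise SequenceError("abasic residue X has no complement")
        base = "A" if t == "A*" else t
        out.append(_COMPLEMENT[(base, out_alphabet)])
    return NucleotideSequence(tuple(out), out_alphabet)


@dataclass(frozen=True)
class ConjugateDesign:
    """One conjugate: two DNA arms around a peptide attachment point."""

    name: str
    arm5: NucleotideSequence
    arm3: NucleotideSequence
    attachment: Literal["modified_adenosine", "abasic_alpha", "abasic_beta"]
    peptide: str
    peptide_length_A: float
    linker_length_A: float

    def __post_init__(self):
        if self.attachment not in ("modified_adenosine", "abasic_alpha", "abasic_beta"):
            raise SequenceError(f"unknown attachment mode {self.attachment!r}")
        if self.peptide_length_A <= 0 or self.linker_length_A <= 0:
            raise SequenceError("peptide and linker lengths must be positive")
        for arm in (self.arm5, self.arm3):
            if any(t in _SPECIAL for t in arm.tokens):
                raise SequenceError("special residues belong to the attachment point, not the arms")

    @property
    def attachment_symbol(self) -> str:
        return "A*" if self.attachment == "modified_adenosine" else "X"

    @property
    def max_reach_A(self) -> float:
        """Farthest distance (Å) the catalytic peptide can project from its
        conjugation point: unfolded peptide length plus aminohexyl linker."""
        return self.peptide_length_A + self.linker_length_A


def motif_length(design: ConjugateDesign) -> int:
    """Oligonucleotide length by the study's mer-counting convention.

    The modified adenosine ``A*`` counts as a nucleotide; the abasic residue
    does not carry a base and is not counted (e.g. an 11 + X + 15 conjugate
    is a 26-mer).
    """
    n = len(design.arm5) + len(design.arm3)
    if design.attachment == "modified_adenosine":
        n += 1
    return n


@dataclass(frozen=True)
class HybridComplex:
    """Antiparallel pairing of a conjugate with a local RNA target.

    ``pairs`` maps 1-based conjugate positions to 1-based local target
    positions; ``bulge`` is the contiguous run of unpaired target positions
    opposite the attachment point; ``dangling`` are unpaired target positions
    outside the arm span.  ``numbering_offset`` converts local position *p*
    to study numbering *p + numbering_offset*.
    """

    design: ConjugateDesign
    target: NucleotideSequence
    pairs: tuple[tuple[int, int], ...]
    bulge: tuple[int, ...]
    dangling: tuple[int, ...]
    numbering_offset: int = 0

    def __post_init__(self):
        conj_seen, targ_seen = set(), set()
        for c, t in self.pairs:
            if c in conj_seen or t in targ_seen:
                raise SequenceError("a position appears in more than one pair")
            conj_seen.add(c)
            targ_seen.add(t)
        # antiparallel monotonicity: target index strictly decreases with
        # conjugate index
        ordered = sorted(self.pairs)
        for (c0, t0), (c1, t1) in zip(ordered, ordered[1:]):
            if t1 >= t0:
                raise SequenceError("pairing is not antiparallel-monotone")
        if self.bulge:
            if sorted(self.bulge) != list(range(min(self.bulge), max(self.bulge) + 1)):
                raise SequenceError("bulge is not contiguous")
            if targ_seen & set(self.bulge):
                raise SequenceError("bulge overlaps paired positions")

    @property
    def paired_target_positions(self) -> frozenset[int]:
        return frozenset(t for _, t in self.pairs)

    def local_to_study(self, p: int) -> int:
        return p + self.numbering_offset

    def study_to_local(self, p: int) -> int:
        return p - self.numbering_offset

    def to_dict(self) -> dict:
        """JSON-ready report: pairs, bulge, dangling, per-linkage regions."""
        return {
            "conjugate": self.design.name,
            "pairs": [list(p) for p in self.pairs],
            "bulge_local": list(self.bulge),
            "bulge_study": [self.local_to_study(p) for p in self.bulge],
            "bulge_size": bulge_size(self),
            "dangling_local": list(self.dangling),
            "numbering_offset": self.numbering_offset,
            "regions": {
                f"{a}-{b}": r for (a, b), r in region_map(self).items()
            },
        }


def _find_placements(arm_rc_rna: NucleotideSequence, target: NucleotideSequence) -> list[int]:
    """All 1-based start positions where the arm's RNA complement occurs."""
    t = str(target)
    a = str(arm_rc_rna)
    return [m.start() + 1 for m in re.finditer(f"(?={re.escape(a)})", t)]


def hybridize(
    design: ConjugateDesign,
    target: NucleotideSequence,
    numbering_offset: int = 0,
) -> HybridComplex:
    """Place both arms on the RNA target by exhaustive exact-match search.

    The 5' arm binds the 3'-side target region and the 3' arm the 5'-side
    region (antiparallel duplex).  The unpaired target stretch strictly
    between the two arm footprints becomes the bulge; target positions
    outside the arm span are dangling.  G·U wobble is not considered.

    If the attachment is the modified adenosine and it sits opposite a single
    target U, that A*·U pair is counted as paired (bulge size 0); opposite
    any other single base it is left unpaired with a warning.
    """
    if target.alphabet != "RNA":
        raise SequenceError("target must be RNA")
    if any(t in _SPECIAL for t in target.tokens):
        raise SequenceError("target may not contain special residues")

    arm5_rc = reverse_complement(design.arm5, "RNA")
    arm3_rc = reverse_complement(design.arm3, "RNA")
    p5 = _find_placements(arm5_rc, target)
    p3 = _find_placements(arm3_rc, target)
    for arm, places in ((str(design.arm5), p5), (str(design.arm3), p3)):
        if not places:
            raise PlacementError(f"arm {arm!r} has no exact-complement placement on the target")
        if len(places) > 1:
            raise AmbiguousPlacementError(arm, places)

    a, b = len(design.arm5), len(design.arm3)
    start5, start3 = p5[0], p3[0]  # windows [start, start+len-1]
    end3 = start3 + b - 1
    if end3 >= start5:
        raise PlacementError(
            "arm footprints overlap or are mis-ordered on the target "
            f"(arm3 window ends at {end3}, arm5 window starts at {start5})"
        )

    pairs: list[tuple[int, int]] = []
    # arm5 occupies conjugate positions 1..a, pairing target start5+a-1 .. start5
    for k in range(1, a + 1):
        pairs.append((k, start5 + a - k))
    # attachment occupies conjugate position a+1
    # arm3 occupies conjugate positions a+2..a+1+b, pairing target end3 .. start3
    for k in range(1, b + 1):
        pairs.append((a + 1 + k, end3 - k + 1))

    gap = list(range(end3 + 1, start5))  # unpaired target between footprints
    bulge = tuple(gap)
    if design.attachment == "modified_adenosine" and len(gap) == 1:
        opposite = target[gap[0] - 1]
        if opposite == "U":
            pairs.append((a + 1, gap[0]))
            bulge = ()
        else:
            warnings.warn(
                f"modified adenosine opposite {opposite} at target position "
                f"{gap[0]}: treated as unpaired (mismatch)",
                stacklevel=2,
            )

    dangling = tuple(
        p for p in range(1, len(target) + 1)
        if p < start3 or p > start5 + a - 1
    )
    return HybridComplex(
        design=design,
        target=target,
        pairs=tuple(sorted(pairs)),
        bulge=bulge,
        dangling=dangling,
        numbering_offset=numbering_offset,
    )


def bulge_size(complex: HybridComplex) -> int:
    """Number of unpaired target nucleotides in the induced bulge-loop."""
    return len(complex.bulge)


@dataclass(frozen=True)
class SiteLabel:
    """An internucleotide linkage in study numbering, e.g. ``C63-A64``."""

    nucleotide_5: str
    nucleotide_3: str

    def __post_init__(self):
        n5, _ = self._split(self.nucleotide_5)
        n3, _ = self._split(self.nucleotide_3)
        if n3 != n5 + 1:
            raise SiteValidationError(
                f"site residues must be consecutive: {self.nucleotide_5}-{self.nucleotide_3}"
            )

    @staticmethod
    def _split(label: str) -> tuple[int, str]:
        m = re.fullmatch(r"([ACGU])(\d+)", label.strip().upper())
        if not m:
            raise SiteValidationError(f"malformed site residue label {label!r}")
        return int(m.group(2)), m.group(1)

    @classmethod
    def from_str(cls, text: str) -> "SiteLabel":
        a, _, b = text.partition("-")
        return cls(a.strip(), b.strip())

    @property
    def residue_5(self) -> int:
        return self._split(self.nucleotide_5)[0]

    @property
    def residue_3(self) -> int:
        return self._split(self.nucleotide_3)[0]

    def __str__(self) -> str:
        return f"{self.nucleotide_5}-{self.nucleotide_3}"


Region = Literal["bulge", "duplex", "junction", "dangling", "outside"]


def _residue_state(complex: HybridComplex, local: int) -> str:
    if local < 1 or local > len(complex.target):
        return "outside"
    if local in complex.paired_target_positions:
        return "paired"
    if local in complex.bulge:
        return "bulge"
    if local in complex.dangling:
        return "dangling"
    return "outside"


def classify_site(site: SiteLabel, complex: HybridComplex) -> Region:
    """Region of an internucleotide linkage relative to the hybrid.

    ``bulge`` if both flanking residues are in the bulge, ``duplex`` if both
    are paired, ``junction`` if mixed, ``dangling`` if within a dangling run,
    ``outside`` if beyond the modeled local target.  Base letters in the
    label are validated against the target sequence.
    """
    states = []
    for label in (site.nucleotide_5, site.nucleotide_3):
        num, base = SiteLabel._split(label)
        local = complex.study_to_local(num)
        state = _residue_state(complex, local)
        if state != "outside":
            actual = complex.target[local - 1]
            if actual != base:
                raise SiteValidationError(
                    f"site label {label} disagrees with target base {actual} "
                    f"at study position {num}"
                )
        states.append(state)
    s5, s3 = states
    if "outside" in states:
        return "outside"
    if s5 == "bulge" and s3 == "bulge":
        return "bulge"
    if s5 == "paired" and s3 == "paired":
        return "duplex"
    if s5 == "dangling" and s3 == "dangling":
        return "dangling"
    return "junction"


def region_map(complex: HybridComplex) -> dict[tuple[int, int], Region]:
    """Region of every internucleotide linkage of the local target,
    keyed by (study number of 5' residue, study number of 3' residue)."""
    out: dict[tuple[int, int], Region] = {}
    for local in range(1, len(complex.target)):
        n5 = complex.local_to_study(local)
        site = SiteLabel(
            f"{complex.target[local - 1]}{n5}",
            f"{complex.target[local]}{n5 + 1}",
        )
        out[(n5, n5 + 1)] = classify_site(site, complex)
    return out


# ---------------------------------------------------------------------------
# External interfaces


def read_target_fasta(path: str | Path) -> NucleotideSequence:
    """Read the first record of a FASTA file as an RNA target.

    T is accepted and normalized to U with a warning.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    text = str(record.seq).upper()
    if "T" in text:
        warnings.warn(f"{path}: T normalized to U in RNA target", stacklevel=2)
        text = text.replace("T", "U")
    return NucleotideSequence.from_str(text, "RNA")


_TABLE_COLUMNS = [
    "name", "arm5", "attachment", "arm3",
    "peptide", "peptide_length_A", "linker_length_A",
]


def load_conjugate_table(path: str | Path) -> list[ConjugateDesign]:
    """Load conjugate designs from a tab-delimited table.

    Columns: name, arm5, attachment, arm3, peptide, peptide_length_A,
    linker_length_A.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"conjugate table missing columns: {sorted(missing)}")
    designs = []
    for row in df.itertuples(index=False):
        designs.append(
            ConjugateDesign(
                name=str(row.name),
                arm5=NucleotideSequence.from_str(row.arm5, "DNA"),
                arm3=NucleotideSequence.from_str(row.arm3, "DNA"),
                attachment=row.attachment,
                peptide=str(row.peptide),
                peptide_length_A=float(row.peptide_length_A),
                linker_length_A=float(row.linker_length_A),
            )
        )
    return designs


def packaged_conjugate_table() -> list[ConjugateDesign]:
    """The 14-conjugate study library shipped with the package."""
    with resources.as_file(resources.files("poc") / "data" / "table1.tsv") as p:
        return load_conjugate_table(p)


def write_hybrid_report(complexes: Iterable[HybridComplex], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in complexes], fh, indent=2)
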