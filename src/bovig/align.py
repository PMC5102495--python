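"""Pairwise global alignment with affine gaps and nucleotide-class scoring.

Every germline assignment in this framework compares one sample sequence
against one reference sequence, so an exact affine-gap global aligner
(Gotoh three-state dynamic programme, provided by Biopython's
``PairwiseAligner``) replaces the heuristic multiple-alignment engines
such a comparison is usually delegated to.

Three named scoring schemes are built in.  ``procedure1`` is the default
used for IGHV and IGHJ assignment (match +2, uniform mismatch -1,
gap open -4, gap extend -1).  ``procedure2`` softens gap extension to
-0.3.  ``procedure3`` additionally distinguishes substitution classes
(match +2, transition +1, transversion -1) so that the chemically more
frequent purine<->purine / pyrimidine<->pyrimidine changes are penalised
less than transversions.  IUB ambiguity codes are scored by set
intersection: two codes whose base sets overlap count as a match.

A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "IUB_SETS",
    "ScoringScheme",
    "PairwiseAlignment",
    "Divergence",
    "builtin_scheme",
    "score_pair",
    "classify_substitution",
    "global_align",
    "divergence",
    "reverse_complement",
]

#: IUB/IUPAC nucleotide codes and the base sets they denote
IUB_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUB_ALPHABET = "".join(IUB_SETS)

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class ScoringScheme:
    """Scores for one alignment procedure (real-valued, no rescaling)."""

    name: str
    match: float
    transition: float
    transversion: float
    gap_open: float
    gap_extend: float
    ambiguity_rule: str = "intersection-match"

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match < self.transition:
            raise ValueError("match score must be >= transition score")
        if self.ambiguity_rule not in ("intersection-match", "strict"):
            raise ValueError(f"unknown ambiguity rule {self.ambiguity_rule!r}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScoringScheme":
        return cls(**json.loads(text))


_BUILTINS = {
    "procedure1": ScoringScheme("procedure1", 2.0, -1.0, -1.0, -4.0, -1.0),
    "procedure2": ScoringScheme("procedure2", 2.0, -1.0, -1.0, -4.0, -0.3),
    "procedure3": ScoringScheme("procedure3", 2.0, 1.0, -1.0, -4.0, -0.3),
}


def builtin_scheme(name: str | int) -> ScoringScheme:
    """Look up a built-in scheme by name or procedure number (1, 2, 3)."""
    if isinstance(name, int):
        name = f"procedure{name}"
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(f"no built-in scoring scheme {name!r}") from None


def classify_substitution(x: str, y: str) -> str:
    """Classify a resolved base pair as match / transition / transversion."""
    x, y = x.upper(), y.upper()
    for b in (x, y):
        if b not in "ACGT":
            raise ValueError(f"classification requires a resolved base, got {b!r}")
    if x == y:
        return "match"
    if {x, y} <= _PURINES or {x, y} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def score_pair(x: str, y: str, scheme: ScoringScheme) -> float:
    """Score one column under a scheme, honouring IUB ambiguity codes."""
    x, y = x.upper(), y.upper()
    for b in (x, y):
        if b not in IUB_SETS:
            raise ValueError(f"{b!r} is not an IUB nucleotide code")
    sx, sy = IUB_SETS[x], IUB_SETS[y]
    if scheme.ambiguity_rule == "intersection-match":
        if sx & sy:
            return scheme.match
    else:  # strict: only identical resolved bases match
        if x == y and x in "ACGT":
            return scheme.match
    union = sx | sy
    if union <= _PURINES or union <= _PYRIMIDINES:
        return scheme.transition
    return scheme.transversion


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped sequence pair with its total alignment score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


@dataclass(frozen=True)
class Divergence:
    """Fraction of mismatching gap-free columns (a p-distance)."""

    value: float
    compared_columns: int


@lru_cache(maxsize=None)
def _matrix_for(scheme: ScoringScheme):
    m = substitution_matrices.Array(IUB_ALPHABET, dims=2, dtype=float)
    for x in IUB_ALPHABET:
        for y in IUB_ALPHABET:
            m[x, y] = score_pair(x, y, scheme)
    return m


@lru_cache(maxsize=None)
def _aligner_for(scheme: ScoringScheme, free_a_overhangs: tuple[bool, bool]):
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _matrix_for(scheme)
    al.open_gap_score = scheme.gap_open
    al.extend_gap_score = scheme.gap_extend
    # an overhang of sequence a corresponds to end gaps in the b row
    # (b is the query): leave those unpenalised where requested
    left, right = free_a_overhangs
    if left:
        al.open_left_deletion_score = 0.0
        al.extend_left_deletion_score = 0.0
    if right:
        al.open_right_deletion_score = 0.0
        al.extend_right_deletion_score = 0.0
    return al


def global_align(
    a: str,
    b: str,
    scheme: ScoringScheme,
    *,
    free_a_overhangs: tuple[bool, bool] = (False, False),
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of ``a`` and ``b``.

    ``free_a_overhangs`` optionally waives end-gap penalties where ``a``
    extends beyond ``b`` on the 5' / 3' side (used when a short reference
    is placed inside a longer sample region); ``b`` itself is always
    aligned end to end at full penalty.  Traceback is deterministic (the
    engine's first optimal path).
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    for seq in (a, b):
        bad = set(seq) - set(IUB_ALPHABET)
        if bad:
            raise ValueError(f"non-IUB characters in input: {sorted(bad)}")
    result = _aligner_for(scheme, free_a_overhangs).align(a, b)
    best = result[0]
    return PairwiseAlignment(str(best[0]), str(best[1]), float(best.score))


def divergence(aln: PairwiseAlignment) -> Divergence:
    """p-distance over gap-free columns, matching by IUB set intersection."""
    compared = 0
    mismatches = 0
    for x, y in aln.columns():
        if x == "-" or y == "-":
            continue
        compared += 1
        if not IUB_SETS[x] & IUB_SETS[y]:
            mismatches += 1
    if compared == 0:
        raise ValueError("alignment has no gap-free columns")
    return Divergence(mismatches / compared, compared)


def pairwise_divergence(a: str, b: str, scheme: ScoringScheme, **kw) -> Divergence:
    """Convenience: align then measure divergence."""
    return divergence(global_align(a, b, scheme, **kw))


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUB ambiguity codes."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUB character {exc.args[0]!r}") from None
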