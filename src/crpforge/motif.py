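"""Eight-cysteine CRP framework scanner and classifier.

The eight-cysteine hevein-like peptide (8C-HLP) framework is the
cysteine spacing pattern C-Xn-C-Xn-CC-Xn-C-X-C-Xn-C-Xn-C: eight
cysteines, with the third and fourth adjacent (the tandem CC) and a
characteristic one-residue gap between the fifth and sixth (the CXC
motif) in the ginsentide-like subfamily. Chitin-binding 8C-HLPs are
distinguished instead by a conserved S-x-Phi-x-Phi stretch (Phi an
aromatic residue F/Y/W) between Cys IV and Cys V and a six-residue
aromatic-containing loop between Cys V and Cys VI.

Loop numbering: "gap k" below means the segment between the k-th and
(k+1)-th framework cysteines (7 gaps, gap 3 being the empty tandem-CC
gap). The family literature numbers loops skipping the empty CC gap,
so its "loop 3" is gap 4 (Cys IV-V) and its "loop 4" is gap 5
(Cys V-VI); reports emit both numberings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

from .seqio import SequenceRecord

log = logging.getLogger(__name__)

AROMATIC = frozenset("FYW")

#: Per-gap (min, max) length bounds; gap 3 is the tandem CC and must be 0.
#: Chosen to bracket ginsentide/coffeetide/cocotide-scale frameworks
#: (the cocotide tC1 gaps are 6,6,0,2,1,6,4) without admitting arbitrary
#: cysteine arrangements.
DEFAULT_LOOP_BOUNDS: tuple[tuple[int, int], ...] = (
    (2, 12), (2, 12), (0, 0), (1, 8), (1, 8), (2, 12), (1, 10),
)

#: Fixed disulfide pairing of the framework, as roman-numeral pairs.
CONNECTIVITY_PATTERN: tuple[tuple[int, int], ...] = ((1, 4), (2, 6), (3, 7), (5, 8))
_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII", 8: "VIII"}


@dataclass
class MotifMatch:
    """One occurrence of the 8-cysteine framework in a protein.

    ``cys_positions`` are the 1-based residue indices of Cys I-VIII;
    ``loops`` are the 7 inter-cysteine segments (loops[2] == "" for the
    tandem CC). ``low_confidence`` flags matches whose loops contain
    ambiguous residues (X).
    """

    source_id: str
    cys_positions: tuple[int, ...]
    loops: tuple[str, ...]
    span: tuple[int, int]
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 8 or len(self.loops) != 7:
            raise ValueError("a framework match needs 8 cysteines and 7 loops")
        if any(b <= a for a, b in zip(self.cys_positions, self.cys_positions[1:])):
            raise ValueError("cysteine positions must be strictly increasing")
        if self.loops[2] != "":
            raise ValueError("gap between Cys III and Cys IV must be the tandem CC")
        if any("C" in lp for lp in self.loops):
            raise ValueError("loops must be cysteine-free")

    @property
    def loop_lengths(self) -> tuple[int, ...]:
        return tuple(len(lp) for lp in self.loops)


@dataclass
class CRPClass:
    """Subfamily assignment for a framework match with rule evidence."""

    label: str  # ginsentide_like | chitin_binding_8C_HLP | other_8C
    evidence: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CysPair:
    """One disulfide bond of the fixed I-IV / II-VI / III-VII / V-VIII pattern."""

    roman_pair: str
    positions: tuple[int, int]


@dataclass
class CompositionReport:
    """Residue composition and integer formal charge of a peptide."""

    length: int
    counts: dict[str, int]
    percents: dict[str, float]
    net_formal_charge: int


def scan_crp_motif(
    protein: SequenceRecord,
    bounds: Sequence[tuple[int, int]] = DEFAULT_LOOP_BOUNDS,
) -> list[MotifMatch]:
    """Find all 8-cysteine framework occurrences in a protein sequence.

    A match is 8 cysteines whose 7 inter-cysteine gaps are cysteine-free
    and satisfy the per-gap length *bounds* (gap 3, the tandem CC, must
    allow 0). Because loops are Cys-free, consecutive framework
    cysteines are forced to be consecutive cysteines of the sequence,
    so candidate frameworks are runs of 8 consecutive Cys. Overlapping
    candidates are resolved greedily left to right so no two reported
    matches share a cysteine; skipped alternatives are logged.
    """
    if protein.kind != "protein":
        raise ValueError("scan_crp_motif requires a protein record")
    _validate_bounds(bounds)
    seq = protein.seq
    cys = [i for i, ch in enumerate(seq) if ch == "C"]  # 0-based
    matches: list[MotifMatch] = []
    i = 0
    while i + 8 <= len(cys):
        window = cys[i : i + 8]
        gaps = [window[k + 1] - window[k] - 1 for k in range(7)]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, bounds)):
            loops = tuple(seq[window[k] + 1 : window[k + 1]] for k in range(7))
            matches.append(
                MotifMatch(
                    source_id=protein.id,
                    cys_positions=tuple(p + 1 for p in window),
                    loops=loops,
                    span=(window[0] + 1, window[7] + 1),
                    low_confidence=any("X" in lp for lp in loops),
                )
            )
            i += 8  # greedy: consume all 8 cysteines
        else:
            i += 1
    return matches


def _validate_bounds(bounds: Sequence[tuple[int, int]]) -> None:
    if len(bounds) != 7:
        raise ValueError("need 7 per-gap bounds")
    for k, (lo, hi) in enumerate(bounds):
        if lo < 0 or lo > hi:
            raise ValueError(f"invalid bounds for gap {k + 1}: ({lo}, {hi})")


def classify_8c_hlp(match: MotifMatch) -> CRPClass:
    """Classify a framework match into the known 8C-HLP subfamilies.

    ginsentide_like: the Cys V-Cys VI loop is exactly one residue (the
    CXC motif). chitin_binding_8C_HLP: the Cys IV-Cys V loop contains
    the conserved serine/aromatic stretch S-x-Phi-x-Phi (Phi in
    {F, Y, W}; the x spacers may each be absent, so S-Phi-x-Phi also
    qualifies) and the Cys V-Cys VI loop is six residues with at least
    one aromatic. Anything else is other_8C.
    """
    loop_iv_v = match.loops[3]   # family "loop 3"
    loop_v_vi = match.loops[4]   # family "loop 4"
    evidence: list[str] = []
    if len(loop_v_vi) == 1:
        evidence.append("cxc_loop4_len1")
        return CRPClass("ginsentide_like", evidence)
    if _has_sxfxf(loop_iv_v):
        evidence.append("sxfxf_loop3")
    if len(loop_v_vi) == 6 and any(a in AROMATIC for a in loop_v_vi):
        evidence.append("aromatic_loop4_len6")
    if {"sxfxf_loop3", "aromatic_loop4_len6"} <= set(evidence):
        return CRPClass("chitin_binding_8C_HLP", evidence)
    return CRPClass("other_8C", [])


_SXFXF = re.compile("S.{0,1}[FYW].{0,1}[FYW]")


def _has_sxfxf(loop: str) -> bool:
    return bool(_SXFXF.search(loop))


def assign_connectivity(match: MotifMatch) -> list[CysPair]:
    """Map the fixed I-IV / II-VI / III-VII / V-VIII disulfide pattern
    onto the match's cysteine positions."""
    pos = match.cys_positions
    return [
        CysPair(f"{_ROMAN[a]}-{_ROMAN[b]}", (pos[a - 1], pos[b - 1]))
        for a, b in CONNECTIVITY_PATTERN
    ]


_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0,
    open_gap_score=-1, extend_gap_score=-1,
)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two protein sequences.

    Equal-length inputs are compared ungapped: 100 x matches / length.
    Unequal lengths use a global alignment (match 1, mismatch 0, linear
    gap -1) and identity is matches over alignment length. Symmetric.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return 100.0 * matches / len(a)
    aln = _aligner.align(a, b)[0]
    sa, sb = aln[0], aln[1]
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return 100.0 * matches / len(sa)


# Side-chain formal charges at neutral pH; His treated as neutral.
_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1, "H": 0}
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


def compute_composition(seq: str, decimals: int = 1) -> CompositionReport:
    """Residue counts, rounded percentages and net formal charge.

    Percentages are rounded half away from zero to *decimals* places.
    Net formal charge counts Asp/Glu as -1, Lys/Arg as +1, His as 0,
    and the free termini as +1/-1 (which cancel).
    """
    seq = seq.upper()
    bad = [(i + 1, ch) for i, ch in enumerate(seq) if ch not in _CANONICAL]
    if bad:
        raise ValueError(f"non-canonical residue(s) at positions {bad}")
    n = len(seq)
    counts = {aa: seq.count(aa) for aa in sorted(set(seq))}
    percents = {aa: _round_half_up(100.0 * c / n, decimals) for aa, c in counts.items()}
    charge = sum(_CHARGE.get(aa, 0) * c for aa, c in counts.items())  # termini cancel
    return CompositionReport(length=n, counts=counts, percents=percents, net_formal_charge=charge)


def _round_half_up(x: float, decimals: int) -> float:
    import math

    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
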