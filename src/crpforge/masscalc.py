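"""Disulfide-aware peptide mass arithmetic and modification-shift algebra.

Peptide masses are residue-table sums plus one water; each disulfide
bond removes two hydrogens (2 x 1.007825 = 2.015650 Da monoisotopic).
Cysteine counting by chemical derivatization works on the same algebra:
reducing a disulfide restores +2.015650 Da and S-carbamidomethylation
with iodoacetamide adds +57.021464 Da per cysteine, so a fully bonded
8-Cys/4-SS peptide shifts by 8 x 57.021464 + 4 x 2.015650 = 464.23 Da
(nominal 464) on reduction + alkylation. Methionine oxidation to the
sulfoxide adds +15.994915 Da (nominal 16) per site.

All mass constants live in the tables below and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

Scale = Literal["monoisotopic", "average"]

PROTON_MASS = 1.007276  # Da, mass of H+

#: Water, added once per peptide chain.
WATER = {"monoisotopic": 18.010565, "average": 18.01528}

#: Removed per disulfide bond (two hydrogens).
DISULFIDE_LOSS = {"monoisotopic": 2.015650, "average": 2.01588}

#: Monoisotopic residue masses (Da), canonical 20 amino acids.
MONO_RESIDUE = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: Average residue masses (Da); linear-mode MALDI of 3+ kDa species may
#: report average rather than monoisotopic mass.
AVG_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Per-unit monoisotopic shifts of the supported modifications.
MODIFICATION_SHIFTS = {
    "carbamidomethyl": 57.021464,     # iodoacetamide adduct on Cys
    "met_oxidation": 15.994915,       # Met -> Met(O)
    "disulfide_reduction": 2.015650,  # +2 H per reduced bond
}


class MassError(ValueError):
    """Invalid mass-arithmetic input (unknown residue, impossible state)."""


@dataclass
class MassOptions:
    """Mass scale and disulfide state for a peptide mass computation."""

    scale: Scale = "monoisotopic"
    n_disulfides: int = 0
    charge_adduct: float = PROTON_MASS

    def __post_init__(self) -> None:
        if self.n_disulfides < 0:
            raise MassError("n_disulfides must be non-negative")
        if self.scale not in ("monoisotopic", "average"):
            raise MassError(f"unknown mass scale {self.scale!r}")


@dataclass
class ModificationSpec:
    """A counted chemical modification drawn from the constant table."""

    name: str
    count: int

    def __post_init__(self) -> None:
        if self.name not in MODIFICATION_SHIFTS:
            raise MassError(f"unknown modification {self.name!r}")
        if self.count < 0:
            raise MassError("modification count must be >= 0")

    @property
    def per_unit_shift(self) -> float:
        return MODIFICATION_SHIFTS[self.name]

    @property
    def total_shift(self) -> float:
        return self.count * self.per_unit_shift


def peptide_mass(seq: str, opts: MassOptions | None = None) -> float:
    """Neutral mass of a peptide in Da, disulfide-aware.

    Sum of residue masses plus one water, minus one H2 loss per
    disulfide bond. ``opts.n_disulfides`` may not exceed half the
    cysteine count.
    """
    opts = opts or MassOptions()
    seq = seq.upper()
    table = MONO_RESIDUE if opts.scale == "monoisotopic" else AVG_RESIDUE
    try:
        total = sum(table[aa] for aa in seq)
    except KeyError as exc:
        raise MassError(f"unknown residue {exc.args[0]!r} in sequence") from None
    n_cys = seq.count("C")
    if opts.n_disulfides > n_cys // 2:
        raise MassError(
            f"{opts.n_disulfides} disulfides impossible with {n_cys} cysteines"
        )
    return total + WATER[opts.scale] - opts.n_disulfides * DISULFIDE_LOSS[opts.scale]


def modification_shift(mods: Iterable[ModificationSpec]) -> float:
    """Total mass shift of a set of counted modifications (order-free)."""
    return sum(m.total_shift for m in mods)


def reduction_alkylation_shift(n_cys: int, n_disulfides: int) -> float:
    """Mass shift from the native disulfide-bonded form to the fully
    reduced, S-carbamidomethylated form.

    Each cysteine gains a carbamidomethyl group (+57.021464) and each
    reduced disulfide restores two hydrogens (+2.015650): 8 Cys / 4 SS
    gives 464.23 Da, the shift used to count cysteines by MS.
    """
    if n_cys < 0 or n_disulfides < 0 or n_cys < 2 * n_disulfides:
        raise MassError(
            f"need n_cys >= 2*n_disulfides, got n_cys={n_cys}, n_ss={n_disulfides}"
        )
    return (
        n_cys * MODIFICATION_SHIFTS["carbamidomethyl"]
        + n_disulfides * MODIFICATION_SHIFTS["disulfide_reduction"]
    )


def infer_cys_count(
    observed_shift: float,
    assume_max_ss: bool = True,
    tol: float = 2.0,
    max_n: int = 40,
) -> int:
    """Invert the reduction+alkylation shift to a cysteine count.

    Finds the n minimizing |observed - expected(n)| where expected(n)
    assumes floor(n/2) disulfides when *assume_max_ss* (the fully
    bonded case) else none. Ties break toward smaller n. Raises if no
    candidate lies within *tol* Da.
    """
    if observed_shift < 0:
        raise MassError("observed_shift must be >= 0")
    candidates = sorted(
        range(max_n + 1),
        key=lambda n: (
            abs(observed_shift - reduction_alkylation_shift(n, n // 2 if assume_max_ss else 0)),
            n,
        ),
    )
    best = candidates[0]
    residual = abs(
        observed_shift - reduction_alkylation_shift(best, best // 2 if assume_max_ss else 0)
    )
    if residual > tol:
        second = candidates[1]
        raise MassError(
            f"ambiguous shift {observed_shift:.3f} Da: nearest candidates "
            f"n={best} and n={second} both outside tolerance {tol} Da"
        )
    return best


def mz(mass: float, charge: int = 1) -> float:
    """m/z of the [M + charge*H]^charge+ ion."""
    if charge < 1:
        raise MassError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def nominal(shift: float) -> int:
    """Round a mass shift half away from zero to the nearest integer Da."""
    return int(math.floor(abs(shift) + 0.5)) * (1 if shift >= 0 else -1)
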