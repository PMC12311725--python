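"""MS1 peak-list matching, mass-window screening and oxoform analysis.

MALDI-TOF screening of plant extracts shows cysteine-rich peptides as
a cluster of singly protonated peaks in the 2-5 kDa window. This
module matches predicted proteoforms (disulfide state, alkylation,
methionine-sulfoxide count) against such peak lists and estimates the
molecule-level oxidized fraction from matched satellite intensities.
Site-level oxidation percentages require MS2 localization and are out
of scope; outputs are per-molecule oxoform fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

from .masscalc import (
    MODIFICATION_SHIFTS,
    MassOptions,
    ModificationSpec,
    modification_shift,
    mz,
    peptide_mass,
)

log = logging.getLogger(__name__)

DEFAULT_TOL_DA = 0.5     # external-calibration MALDI accuracy at ~3 kDa
DEFAULT_TOL_PPM = 200.0
PROTON = 1.007276


@dataclass
class PeakList:
    """An MS1 peak list: (m/z, intensity) pairs sorted by m/z."""

    peaks: list[tuple[float, float]]
    source: str = ""

    def __post_init__(self) -> None:
        if any(inten < 0 for _, inten in self.peaks):
            raise ValueError("negative intensity in peak list")
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class Proteoform:
    """A peptide in one specific modification state, with its mass.

    The state is (number of intact disulfides, alkylation yes/no,
    number of oxidized methionines); ``mass`` is the neutral
    monoisotopic mass and ``mz1`` the singly protonated m/z.
    """

    base_id: str
    seq: str
    n_disulfides: int
    n_met_ox: int = 0
    alkylated: bool = False
    scale: str = "monoisotopic"

    def __post_init__(self) -> None:
        n_met = self.seq.upper().count("M")
        if not 0 <= self.n_met_ox <= n_met:
            raise ValueError(
                f"{self.base_id}: n_met_ox={self.n_met_ox} outside 0..{n_met}"
            )

    @property
    def mass(self) -> float:
        base = peptide_mass(self.seq, MassOptions(scale=self.scale, n_disulfides=self.n_disulfides))
        mods = [ModificationSpec("met_oxidation", self.n_met_ox)]
        if self.alkylated:
            mods.append(ModificationSpec("carbamidomethyl", self.seq.upper().count("C")))
        return base + modification_shift(mods)

    @property
    def mz1(self) -> float:
        return mz(self.mass, 1)


@dataclass
class MassMatch:
    """One proteoform matched to one observed peak within tolerance."""

    proteoform: Proteoform
    peak_mz: float
    peak_intensity: float
    error_da: float
    error_ppm: float


def read_peaklist(path: str | Path) -> PeakList:
    """Read a two-column (m/z, intensity) text peak list.

    Whitespace- or comma-delimited; blank lines, comment lines (#) and
    a single non-numeric header line are skipped. Raises ValueError
    with the line number on any other non-numeric field.
    """
    path = Path(path)
    peaks: list[tuple[float, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mz_val, inten = float(fields[0]), float(fields[1])
            except ValueError:
                if lineno == 1:  # tolerate a header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
            peaks.append((mz_val, inten))
    if not peaks:
        log.warning("no peaks parsed from %s", path)
    return PeakList(peaks=peaks, source=str(path))


def enumerate_oxoforms(
    seq: str,
    base_id: str = "peptide",
    n_disulfides: int = 0,
    max_ox: int | None = None,
    alkylated: bool = False,
) -> list[Proteoform]:
    """Proteoforms for 0..min(max_ox, Met count) oxidized methionines.

    Masses increase by +15.994915 Da per oxidation, so the list is
    strictly mass-ordered. ``max_ox=None`` means all methionines.
    """
    n_met = seq.upper().count("M")
    top = n_met if max_ox is None else min(max_ox, n_met)
    return [
        Proteoform(
            base_id=base_id, seq=seq, n_disulfides=n_disulfides,
            n_met_ox=k, alkylated=alkylated,
        )
        for k in range(top + 1)
    ]


def match_peaks(
    pl: PeakList,
    forms: list[Proteoform],
    tol_da: float = DEFAULT_TOL_DA,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[MassMatch]:
    """Match each proteoform to its nearest in-tolerance peak.

    The effective tolerance at mass m is max(tol_da, tol_ppm * m/z /
    1e6). Ties on |error| break toward higher intensity, then lower
    m/z. A peak may satisfy several proteoforms; ambiguous assignments
    trigger a warning but are all reported.
    """
    if tol_da <= 0 or tol_ppm <= 0:
        raise ValueError("tolerances must be positive")
    matches: list[MassMatch] = []
    used: dict[float, list[str]] = {}
    for form in forms:
        target = form.mz1
        eff_tol = max(tol_da, tol_ppm * target / 1e6)
        in_tol = [(m, i) for m, i in pl.peaks if abs(m - target) <= eff_tol]
        if not in_tol:
            continue
        best = min(in_tol, key=lambda p: (abs(p[0] - target), -p[1], p[0]))
        err_da = best[0] - target
        matches.append(
            MassMatch(
                proteoform=form,
                peak_mz=best[0],
                peak_intensity=best[1],
                error_da=err_da,
                error_ppm=1e6 * err_da / target,
            )
        )
        used.setdefault(best[0], []).append(f"{form.base_id}+{form.n_met_ox}ox")
    for peak_mz, claimants in used.items():
        if len(claimants) > 1:
            warnings.warn(
                f"peak {peak_mz:.4f} matched by multiple proteoforms: {claimants}",
                stacklevel=2,
            )
    return matches


def screen_window(
    pl: PeakList,
    lo: float = 2000.0,
    hi: float = 5000.0,
    min_rel_intensity: float = 0.0,
) -> PeakList:
    """Keep peaks whose neutral mass (m/z - proton) lies in [lo, hi]
    and whose intensity is at least *min_rel_intensity* times the
    maximum intensity inside the window."""
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    in_window = [(m, i) for m, i in pl.peaks if lo <= m - PROTON <= hi]
    if not in_window:
        return PeakList(peaks=[], source=pl.source)
    cutoff = min_rel_intensity * max(i for _, i in in_window)
    return PeakList(
        peaks=[(m, i) for m, i in in_window if i >= cutoff],
        source=pl.source,
    )


def oxidation_fraction(matches: list[MassMatch]) -> dict[int, float]:
    """Intensity-weighted oxoform fractions for one base peptide.

    f(k) = intensity of the k-oxidation match over the summed
    intensity of all matched oxoforms; fractions sum to 1. All matches
    must share a base_id.
    """
    if not matches:
        raise ValueError("no matches supplied")
    base_ids = {m.proteoform.base_id for m in matches}
    if len(base_ids) > 1:
        raise ValueError(f"matches span multiple base peptides: {sorted(base_ids)}")
    total = sum(m.peak_intensity for m in matches)
    if total <= 0:
        raise ValueError("total matched intensity is zero; fractions undefined")
    out: dict[int, float] = {}
    for m in matches:
        out[m.proteoform.n_met_ox] = out.get(m.proteoform.n_met_ox, 0.0) + m.peak_intensity / total
    return out


# re-export for callers that need the oxidation step size
MET_OX_SHIFT = MODIFICATION_SHIFTS["met_oxidation"]
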