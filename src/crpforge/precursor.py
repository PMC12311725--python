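"""Three-domain precursor modeling and mature-peptide excision.

Ginsentide-like peptides are produced from precursors with a signal
peptide, a prodomain, and a C-terminal mature domain. Maturation is
modeled as asparaginyl endopeptidase (AEP) cleavage at an Asn|Cys
junction: the mature peptide starts at the cysteine immediately after
the prodomain's terminal asparagine (Cys I of the 8-cysteine
framework). Signal-peptide boundaries are expected from an external
predictor and supplied by the caller; a crude hydropathy heuristic is
available as an explicitly flagged fallback.

All positions are 1-based inclusive in this module's public fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .motif import scan_crp_motif, classify_8c_hlp
from .seqio import SequenceRecord

log = logging.getLogger(__name__)


class NoMatureDomainError(ValueError):
    """No AEP site with a downstream 8-Cys framework starting at Cys I."""


@dataclass
class PrecursorModel:
    """A parsed three-domain precursor.

    ``aep_site`` is the 1-based position of the Asn immediately
    preceding the mature domain; ``mature_start = aep_site + 1`` must
    be a Cys (Cys I of the framework). ``signal_end`` is the last
    residue of the signal peptide; ``signal_provenance`` records
    whether it was user-supplied or heuristic.
    """

    source_id: str
    full_seq: str
    signal_end: int | None
    aep_site: int
    signal_provenance: str = "user"

    def __post_init__(self) -> None:
        if self.full_seq[self.aep_site - 1] != "N":
            raise ValueError(f"residue at aep_site {self.aep_site} is not Asn")
        if self.full_seq[self.aep_site] != "C":
            raise ValueError(f"residue after aep_site {self.aep_site} is not Cys")
        if self.signal_end is not None and self.signal_end >= self.aep_site:
            raise ValueError(
                f"signal_end {self.signal_end} must precede aep_site {self.aep_site}"
            )

    @property
    def mature_start(self) -> int:
        return self.aep_site + 1

    @property
    def mature_seq(self) -> str:
        return self.full_seq[self.aep_site:]


def find_aep_sites(
    seq: str,
    acceptor: Iterable[str] = ("C",),
    donor: Iterable[str] = ("N",),
) -> list[int]:
    """1-based positions p where seq[p] is an AEP donor (Asn by default,
    optionally Asp) and seq[p+1] is in the acceptor set (Cys by default),
    in ascending order."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    donor, acceptor = set(donor), set(acceptor)
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in donor and seq[i + 1] in acceptor
    ]


def parse_precursor(
    seq: str,
    source_id: str = "precursor",
    signal_end: int | None = None,
    acceptor: Iterable[str] = ("C",),
) -> PrecursorModel:
    """Locate the maturation site and build a PrecursorModel.

    Selects the leftmost AEP site whose downstream segment begins with
    Cys I of a ginsentide-like framework match. When *signal_end* is
    not supplied, a Kyte-Doolittle hydropathy heuristic estimates it
    and the model is flagged ``signal_provenance="heuristic"``.
    """
    seq = seq.upper()
    sites = find_aep_sites(seq, acceptor=acceptor)
    chosen: int | None = None
    for site in sites:
        downstream = seq[site:]
        rec = SequenceRecord(id=f"{source_id}|candidate", seq=downstream, kind="protein")
        matches = scan_crp_motif(rec)
        if any(
            m.cys_positions[0] == 1 and classify_8c_hlp(m).label == "ginsentide_like"
            for m in matches
        ):
            if chosen is None:
                chosen = site
            else:
                log.info(
                    "%s: alternative qualifying AEP site at %d (kept leftmost %d)",
                    source_id, site, chosen,
                )
    if chosen is None:
        raise NoMatureDomainError(
            f"{source_id}: no Asn|Cys junction releases a ginsentide-like framework"
        )
    provenance = "user"
    if signal_end is None:
        signal_end = _heuristic_signal_end(seq)
        provenance = "heuristic" if signal_end is not None else "none"
    if signal_end is not None and signal_end >= chosen:
        raise ValueError(
            f"{source_id}: signal_end {signal_end} not upstream of AEP site {chosen}"
        )
    return PrecursorModel(
        source_id=source_id,
        full_seq=seq,
        signal_end=signal_end,
        aep_site=chosen,
        signal_provenance=provenance,
    )


def excise_mature(model: PrecursorModel) -> SequenceRecord:
    """Return the mature peptide as a new record with coordinates in
    the description (1-based inclusive)."""
    return SequenceRecord(
        id=f"{model.source_id}|mature",
        seq=model.mature_seq,
        kind="protein",
        description=(
            f"mature domain {model.mature_start}-{len(model.full_seq)} "
            f"(1-based) after AEP site Asn{model.aep_site}"
        ),
    )


# Kyte-Doolittle hydropathy values.
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


def _heuristic_signal_end(seq: str, window: int = 8, search_len: int = 40) -> int | None:
    """Crude signal-peptide end estimate: find the longest run of
    windows with mean hydropathy > 1.5 within the first *search_len*
    residues and place cleavage 5 residues after the run's end.
    Approximate by construction; callers should prefer predictor output.
    """
    region = seq[:search_len]
    if len(region) < window:
        return None
    hydro = [_KD.get(a, 0.0) for a in region]
    best_end = None
    run_start = None
    for i in range(len(region) - window + 1):
        if sum(hydro[i : i + window]) / window > 1.5:
            if run_start is None:
                run_start = i
            best_end = i + window  # 0-based exclusive end of hydrophobic core
        else:
            run_start = None
    if best_end is None:
        return None
    end = min(best_end + 5, len(seq) - 1)
    return end  # 1-based: 0-based exclusive index == 1-based inclusive position
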