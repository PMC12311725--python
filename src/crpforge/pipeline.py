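"""Composed discovery and enrichment workflows.

``run_discovery`` wires translate -> scan -> classify -> mature ->
mass -> peak-match into one pass over a contig or protein FASTA and
returns a tidy per-candidate report. ``run_enrichment`` runs the
two-group volcano analysis with optional contaminant exclusion.
Both are plain functions over in-memory objects; the CLI wraps them
with file I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import diffquant, masscalc, motif, peakmatch, precursor, seqio

log = logging.getLogger(__name__)


@dataclass
class DiscoveryConfig:
    """Stage parameters for the discovery pipeline."""

    min_orf: int = 60
    loop_bounds: tuple[tuple[int, int], ...] = motif.DEFAULT_LOOP_BOUNDS
    keep_classes: tuple[str, ...] = ("ginsentide_like",)
    n_disulfides: int = 4
    mass_scale: str = "monoisotopic"
    tol_da: float = peakmatch.DEFAULT_TOL_DA
    tol_ppm: float = peakmatch.DEFAULT_TOL_PPM
    max_ox: int | None = None
    signal_ends: dict[str, int] = field(default_factory=dict)


def run_discovery(
    records: Iterable[seqio.SequenceRecord],
    config: DiscoveryConfig | None = None,
    peaklist: peakmatch.PeakList | None = None,
) -> pd.DataFrame:
    """Mine candidate mature CRPs and annotate masses and peak matches.

    Nucleotide records are six-frame translated and ORF-scanned;
    protein records are used directly. Each candidate row reports the
    source, class, mature sequence, composition summary, predicted
    neutral/[M+H]+/reduced-alkylated masses, and (when a peak list is
    given) matched oxoform peaks.
    """
    config = config or DiscoveryConfig()
    proteins: list[seqio.SequenceRecord] = []
    for rec in records:
        if rec.kind == "nucleotide":
            frames = seqio.six_frame_translate(rec)
            proteins.extend(seqio.find_orfs(frames, min_len=config.min_orf))
        else:
            proteins.append(rec)
    rows = []
    for prot in proteins:
        mature_seq, source_id = _maturate(prot, config)
        if mature_seq is None:
            continue
        rec = seqio.SequenceRecord(id=source_id, seq=mature_seq, kind="protein")
        matches = motif.scan_crp_motif(rec, config.loop_bounds)
        for m in matches:
            crp_class = motif.classify_8c_hlp(m)
            if config.keep_classes and crp_class.label not in config.keep_classes:
                continue
            comp = motif.compute_composition(mature_seq)
            opts = masscalc.MassOptions(
                scale=config.mass_scale, n_disulfides=config.n_disulfides
            )
            mass = masscalc.peptide_mass(mature_seq, opts)
            n_cys = mature_seq.count("C")
            row = {
                "source_id": source_id,
                "class": crp_class.label,
                "evidence": ";".join(crp_class.evidence),
                "mature_seq": mature_seq,
                "length": comp.length,
                "n_cys": n_cys,
                "n_gly": comp.counts.get("G", 0),
                "net_charge": comp.net_formal_charge,
                "loop_lengths": ",".join(map(str, m.loop_lengths)),
                "connectivity": ";".join(
                    f"{p.roman_pair}:{p.positions[0]}-{p.positions[1]}"
                    for p in motif.assign_connectivity(m)
                ),
                "mass_da": round(mass, 4),
                "mz1": round(masscalc.mz(mass, 1), 4),
                "reduced_alkylated_mass_da": round(
                    mass + masscalc.reduction_alkylation_shift(n_cys, config.n_disulfides), 4
                ),
                "low_confidence": m.low_confidence,
            }
            if peaklist is not None:
                forms = peakmatch.enumerate_oxoforms(
                    mature_seq, base_id=source_id,
                    n_disulfides=config.n_disulfides, max_ox=config.max_ox,
                )
                hits = peakmatch.match_peaks(
                    peaklist, forms, tol_da=config.tol_da, tol_ppm=config.tol_ppm
                )
                row["n_peak_matches"] = len(hits)
                row["matched_oxoforms"] = ",".join(
                    str(h.proteoform.n_met_ox) for h in hits
                )
            rows.append(row)
    report = pd.DataFrame(rows)
    if report.empty:
        log.warning("discovery produced no candidates")
    return report


def _maturate(prot, config) -> tuple[str | None, str]:
    """Try precursor parsing; fall back to the sequence itself when it
    already starts at the framework (a pre-excised mature peptide)."""
    try:
        model = precursor.parse_precursor(
            prot.seq,
            source_id=prot.id,
            signal_end=config.signal_ends.get(prot.id),
        )
        return model.mature_seq, prot.id
    except (precursor.NoMatureDomainError, ValueError):
        rec = seqio.SequenceRecord(id=prot.id, seq=prot.seq, kind="protein")
        if motif.scan_crp_motif(rec, config.loop_bounds):
            return prot.seq, prot.id
        return None, prot.id


@dataclass
class EnrichmentConfig:
    """Thresholds for the two-group enrichment analysis."""

    min_fc: float = 2.0
    min_sig: float = 15.0
    pseudocount: float = 1.0
    bh_correct: bool = False


def run_enrichment(
    matrix: diffquant.QuantMatrix,
    config: EnrichmentConfig | None = None,
    contaminants: Iterable[str] = (),
) -> dict:
    """Volcano analysis with optional contaminant exclusion.

    Returns a dict with the full per-protein stats table, the enriched
    and depleted id sets before and after contaminant removal, and the
    removed ids.
    """
    config = config or EnrichmentConfig()
    stats_list = diffquant.protein_stats(
        matrix, pseudocount=config.pseudocount, bh_correct=config.bh_correct
    )
    enriched, depleted = diffquant.volcano_filter(
        stats_list, min_fc=config.min_fc, min_sig=config.min_sig
    )
    final_enriched, removed = diffquant.exclude_contaminants(enriched, contaminants)
    table = pd.DataFrame(
        [
            {
                "protein": s.protein,
                "log2_fc": s.log2_fc,
                "significance": s.significance,
                "p_value": s.p_value,
                "direction": s.direction,
            }
            for s in stats_list
        ]
    )
    return {
        "stats": table,
        "enriched": enriched,
        "depleted": depleted,
        "enriched_final": final_enriched,
        "contaminants_removed": removed,
    }
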