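"""Two-group differential analysis of protein quantification matrices.

Implements the enrichment filter used in affinity-purification and TMT
proteomics screens: per-protein fold change between treatment and
control plus a significance score on the -10*log10(p) scale, followed
by a volcano-style cut (fold change >= 2, significance > 15, i.e.
p < 10^-1.5 ~ 0.0316) and contaminant exclusion against a supplied
list (e.g. CRAPome identifiers).

The significance score is -10*log10 of a two-sided two-sample t-test
p-value computed on log2 intensities. This is an approximation of the
proprietary score reported by commercial search engines on the same
scale; it makes the conventional ">15" cutoff meaningful. The default
pools the group variances, which keeps the score's null calibration
exact for the balanced three-replicate designs these screens use;
Welch's unequal-variance form is available via ``welch=True`` but is
conservative at such small samples. No multiple testing correction is
applied by default because the screen filters on raw significance;
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

Direction = Literal["up", "down", "ns"]


@dataclass
class QuantMatrix:
    """Protein x sample intensity matrix with a two-group design.

    ``values`` is a DataFrame (rows: proteins, columns: samples);
    ``groups`` maps each sample to "control" or "treatment". Missing
    values are NaN; intensities must be non-negative.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.values.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without a group label: {sorted(unknown)}")
        labels = set(self.groups.values())
        if not labels <= {"control", "treatment"}:
            raise ValueError(f"group labels must be control/treatment, got {labels}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative intensities in quantification matrix")

    def group_columns(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]


@dataclass
class ProteinStat:
    """Fold change and significance for one protein."""

    protein: str
    log2_fc: float
    significance: float  # -10 * log10(p), t-test on log2 intensities
    p_value: float
    direction: Direction = "ns"


def protein_stats(
    m: QuantMatrix,
    pseudocount: float = 1.0,
    bh_correct: bool = False,
    welch: bool = False,
) -> list[ProteinStat]:
    """Per-protein log2 fold change and t-test significance.

    Intensities get *pseudocount* added and are log2-transformed;
    log2_fc is the difference of group means; significance is
    -10*log10(p) from a two-sided two-sample t-test on the log2
    values (pooled variance by default; ``welch=True`` for the
    unequal-variance form). Degenerate proteins (zero variance in
    both groups with equal means) get p = 1. Proteins with fewer than
    two finite values in either group are excluded with a logged
    count.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    ctrl_cols = m.group_columns("control")
    trt_cols = m.group_columns("treatment")
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    log_vals = np.log2(m.values + pseudocount)
    stats_out: list[ProteinStat] = []
    n_untestable = 0
    for protein, row in log_vals.iterrows():
        ctrl = row[ctrl_cols].dropna().to_numpy(dtype=float)
        trt = row[trt_cols].dropna().to_numpy(dtype=float)
        if len(ctrl) < 2 or len(trt) < 2:
            n_untestable += 1
            continue
        fc = float(trt.mean() - ctrl.mean())
        if ctrl.var(ddof=1) == 0 and trt.var(ddof=1) == 0:
            p = 1.0 if fc == 0 else 0.0
        else:
            p = float(stats.ttest_ind(trt, ctrl, equal_var=not welch).pvalue)
        stats_out.append(ProteinStat(protein=str(protein), log2_fc=fc, significance=0.0, p_value=p))
    if n_untestable:
        log.warning("%d protein(s) untestable (<2 finite values in a group)", n_untestable)
    if bh_correct and stats_out:
        pvals = np.array([s.p_value for s in stats_out])
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        for idx, a in zip(order, adj):
            stats_out[idx].p_value = float(a)
    for s in stats_out:
        s.significance = float(-10.0 * np.log10(max(s.p_value, 1e-300)))
    return stats_out


def volcano_filter(
    stats_list: Iterable[ProteinStat],
    min_fc: float = 2.0,
    min_sig: float = 15.0,
) -> tuple[set[str], set[str]]:
    """Split proteins into enriched and depleted sets.

    Enriched: log2_fc >= log2(min_fc) and significance > min_sig;
    depleted is symmetric with log2_fc <= -log2(min_fc). The two sets
    are disjoint by construction; every stat's ``direction`` field is
    set as a side effect.
    """
    if min_fc < 1:
        raise ValueError("min_fc must be >= 1 (a fold change)")
    log2_cut = float(np.log2(min_fc))
    enriched: set[str] = set()
    depleted: set[str] = set()
    for s in stats_list:
        if s.significance > min_sig and s.log2_fc >= log2_cut:
            s.direction = "up"
            enriched.add(s.protein)
        elif s.significance > min_sig and s.log2_fc <= -log2_cut:
            s.direction = "down"
            depleted.add(s.protein)
        else:
            s.direction = "ns"
    return enriched, depleted


def exclude_contaminants(
    ids: set[str], contaminant_list: Iterable[str]
) -> tuple[set[str], list[str]]:
    """Remove known contaminants (e.g. CRAPome entries) from a hit set.

    Returns the surviving set and the sorted list of removed ids.
    """
    contaminants = set(contaminant_list)
    removed = sorted(ids & contaminants)
    if removed:
        log.info("excluded %d contaminant(s): %s", len(removed), removed)
    return ids - contaminants, removed


def read_quant_matrix(matrix_path, groups_path) -> QuantMatrix:
    """Load a TSV/CSV intensity matrix and a two-column sample->group map."""
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    gdf = pd.read_csv(groups_path, sep=None, engine="python", header=None,
                      names=["sample", "group"], comment="#")
    groups = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
    return QuantMatrix(values=values, groups=groups)
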