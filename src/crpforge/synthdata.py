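"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the data classes the pipeline consumes, each
returning the dataset plus a truth table sufficient to score the
downstream stage without re-running the generator:

* transcriptomes: decoy contigs of random codons plus planted
  three-domain precursor transcripts (signal + prodomain ending in Asn
  + mature 8-Cys domain), half on the reverse strand;
* MALDI-style MS1 peak lists: one [M+H]+ peak per peptide with ppm-scale
  Gaussian mass error, an oxidized (+16 Da) satellite at a planted
  intensity ratio, and uniform low-intensity noise peaks in 2-5 kDa;
* quantification matrices: log-normal intensities with a planted
  enriched fraction shifted by a fixed log2 fold change in the
  treatment group.

Every routine is a pure function of its config, seed included.
Substitutions in planted mature domains never touch cysteines, which
mirrors the near-absolute cysteine conservation of the family; the
``plant_broken_framework`` option adds 7-cysteine near-miss decoys to
probe scanner specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .diffquant import QuantMatrix
from .peakmatch import PeakList
from .masscalc import MODIFICATION_SHIFTS, MassOptions, mz, peptide_mass
from .seqio import SequenceRecord

#: Mature-domain template: the 33-residue, 8-cysteine ginsentide-like
#: peptide cocotide tC1 from Theobroma cacao.
TC1_SEQUENCE = "CLSAGGFCMFNPMDCCGNCGCLYPMGICYGSGC"

_HYDROPHOBIC = "ALVIF"
# prodomain residues: no Cys (avoids decoy frameworks), no Asn (avoids
# spurious AEP junctions upstream of the planted one), no Met
_PRO_RESIDUES = "ADEGKLPQRSTV"
_NONCYS = "ADEFGHIKLMNPQRSTVWY"

# inverse standard genetic code, stop codons excluded
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
_STOPS = list(unambiguous_dna_by_id[1].stop_codons)


@dataclass
class QuantConfig:
    """Design of a synthetic two-group quantification experiment.

    Defaults mirror an affinity-enrichment screen: a few thousand
    identified proteins, three replicates per group, a planted
    enriched fraction with a 4-fold (log2 FC = 2) shift, and tight
    log2 noise typical of summed reporter/LFQ protein intensities.
    """

    n_proteins: int = 2465
    n_planted_up: int = 151
    planted_log2fc: float = 2.0
    noise_sd: float = 0.1
    group_sizes: tuple[int, int] = (3, 3)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0


@dataclass
class SimConfig:
    """All knobs of the synthetic generators; ``seed`` is mandatory.

    signal_len=26 and pro_len=35 place the AEP junction at Asn61|Cys62
    of the precursor, the maturation coordinates of the template
    family. ``mutation_rate`` substitutes non-Cys residues of the
    mature template, producing a peptide family at ~85-95% identity at
    the default 0.05.
    """

    seed: int
    n_decoys: int = 50
    n_planted: int = 12
    mutation_rate: float = 0.05
    signal_len: int = 26
    pro_len: int = 35
    mature_template: str = TC1_SEQUENCE
    plant_broken_framework: int = 0
    mass_noise_ppm: float = 50.0
    ox_fraction: float = 0.27
    n_noise_peaks: int = 30
    noise_rel_intensity: float = 0.02
    quant: QuantConfig = field(default_factory=QuantConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.ox_fraction < 1:
            raise ValueError("ox_fraction must be in [0, 1)")
        if min(self.quant.group_sizes) < 2:
            raise ValueError("need >= 2 samples per group")


def _mutate_mature(template: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute non-Cys positions at *rate*; cysteines never change."""
    out = []
    for aa in template:
        if aa != "C" and rng.random() < rate:
            choices = [x for x in _NONCYS if x != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    """Seeded back-translation, uniform over synonymous codons."""
    return "".join(
        _BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))] for aa in protein
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_transcriptome(cfg: SimConfig) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Decoy contigs plus planted precursor transcripts with truth table.

    Planted transcripts encode M-initiated signal(signal_len) +
    prodomain(pro_len, ending in Asn) + mature domain + stop; a seeded
    half are reverse-complemented. The truth table lists strand,
    1-based precursor domain coordinates and the mature sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SequenceRecord] = []
    truth_rows = []
    for i in range(cfg.n_decoys):
        n_codons = int(rng.integers(60, 200))
        nt = "".join(
            _BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))]
            for aa in rng.choice(list(_NONCYS + "C"), n_codons)
        )
        records.append(SequenceRecord(id=f"decoy_{i:04d}", seq=nt, kind="nucleotide"))
    n_total_planted = cfg.n_planted + cfg.plant_broken_framework
    rev_flags = rng.random(n_total_planted) < 0.5
    for j in range(n_total_planted):
        broken = j >= cfg.n_planted
        mature = _mutate_mature(cfg.mature_template, cfg.mutation_rate, rng)
        if broken:
            # knock out one framework cysteine -> 7-Cys near-miss decoy
            cys_idx = [k for k, a in enumerate(mature) if a == "C"]
            k = cys_idx[rng.integers(len(cys_idx))]
            mature = mature[:k] + "S" + mature[k + 1 :]
        signal = "M" + "".join(
            _HYDROPHOBIC[rng.integers(len(_HYDROPHOBIC))]
            for _ in range(cfg.signal_len - 1)
        )
        pro = "".join(
            _PRO_RESIDUES[rng.integers(len(_PRO_RESIDUES))]
            for _ in range(cfg.pro_len - 1)
        ) + "N"
        protein = signal + pro + mature
        nt = _back_translate(protein, rng) + _STOPS[rng.integers(len(_STOPS))]
        strand = "-" if rev_flags[j] else "+"
        if strand == "-":
            nt = _revcomp(nt)
        pid = (f"broken_{j - cfg.n_planted:04d}" if broken else f"planted_{j:04d}")
        records.append(SequenceRecord(id=pid, seq=nt, kind="nucleotide"))
        truth_rows.append(
            {
                "transcript_id": pid,
                "planted": not broken,
                "strand": strand,
                "signal_end": cfg.signal_len,
                "aep_site": cfg.signal_len + cfg.pro_len,
                "mature_start": cfg.signal_len + cfg.pro_len + 1,
                "precursor_seq": protein,
                "mature_seq": mature,
            }
        )
    order = rng.permutation(len(records))
    records = [records[k] for k in order]
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_peaklist(
    peptides: list[tuple[str, str]],
    cfg: SimConfig,
    n_disulfides: int = 4,
) -> tuple[PeakList, pd.DataFrame]:
    """MALDI-style MS1 peak list for (id, sequence) pairs, with truth.

    Each peptide contributes its [M+H]+ peak with Gaussian m/z error
    of sigma = mass_noise_ppm, plus (if the sequence has Met and
    ox_fraction > 0) a single-oxidation satellite at +15.9949 Da with
    intensity ratio ox_fraction/(1 - ox_fraction). n_noise_peaks
    uniform peaks in the 2-5 kDa window sit at noise_rel_intensity of
    the base-peak intensity.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    peaks: list[tuple[float, float]] = []
    truth_rows = []
    base_intensity = 1000.0
    for pid, seq in peptides:
        m0 = peptide_mass(seq, MassOptions(n_disulfides=n_disulfides))
        targets = [(0, mz(m0, 1), base_intensity * (1 - cfg.ox_fraction))]
        if cfg.ox_fraction > 0 and "M" in seq:
            targets.append(
                (1, mz(m0 + MODIFICATION_SHIFTS["met_oxidation"], 1),
                 base_intensity * cfg.ox_fraction)
            )
        for n_ox, true_mz, inten in targets:
            obs = true_mz * (1 + rng.normal(0, cfg.mass_noise_ppm) * 1e-6)
            peaks.append((obs, inten))
            truth_rows.append(
                {"base_id": pid, "n_met_ox": n_ox, "true_mz": true_mz,
                 "observed_mz": obs, "intensity": inten}
            )
    for _ in range(cfg.n_noise_peaks):
        noise_mz = rng.uniform(2000.0, 5000.0) + 1.007276
        peaks.append((noise_mz, base_intensity * cfg.noise_rel_intensity))
        truth_rows.append(
            {"base_id": "noise", "n_met_ox": -1, "true_mz": np.nan,
             "observed_mz": noise_mz,
             "intensity": base_intensity * cfg.noise_rel_intensity}
        )
    return (
        PeakList(peaks=peaks, source=f"synthetic(seed={cfg.seed})"),
        pd.DataFrame(truth_rows),
    )


def simulate_quant(cfg: SimConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Two-group log-normal quantification matrix with planted hits.

    Per-protein log2 baselines ~ Normal(baseline_mean, baseline_sd);
    sample values add Normal(0, noise_sd) noise; the first
    n_planted_up proteins gain planted_log2fc in the treatment group.
    Returned intensities are on the raw (2^x) scale.
    """
    q = cfg.quant
    rng = np.random.default_rng(cfg.seed + 2)
    n_ctrl, n_trt = q.group_sizes
    proteins = [f"P{i:05d}" for i in range(q.n_proteins)]
    samples = [f"ctrl_{i}" for i in range(n_ctrl)] + [f"trt_{i}" for i in range(n_trt)]
    groups = {s: ("control" if s.startswith("ctrl") else "treatment") for s in samples}
    baseline = rng.normal(q.baseline_mean, q.baseline_sd, size=q.n_proteins)
    log2_vals = baseline[:, None] + rng.normal(0, q.noise_sd, size=(q.n_proteins, len(samples)))
    planted = np.zeros(q.n_proteins, dtype=bool)
    planted[: q.n_planted_up] = True
    log2_vals[planted, n_ctrl:] += q.planted_log2fc
    values = pd.DataFrame(np.exp2(log2_vals), index=proteins, columns=samples)
    truth = pd.DataFrame(
        {"protein": proteins, "planted_up": planted,
         "true_log2fc": np.where(planted, q.planted_log2fc, 0.0)}
    )
    return QuantMatrix(values=values, groups=groups), truth
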