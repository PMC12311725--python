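# crpforge

Discovery and mass-spectrometric verification of 8-cysteine
ginsentide-like peptides, built around the cocotide family — 33-residue
cysteine-rich peptides (CRPs) from *Theobroma cacao*.

Plants produce compact hevein-like peptides stabilized by four
disulfide bonds. The 8-cysteine subfamily (8C-HLP) shares the cysteine
spacing pattern

```
C-Xn-C-Xn-CC-Xn-C-X-C-Xn-C-Xn-C
```

with a tandem `CC` (Cys III/IV) and, in the ginsentide-like branch, a
single-residue `CXC` loop between Cys V and VI; the chitin-binding
branch instead carries a conserved Ser/aromatic stretch (S-x-Φ-x-Φ,
Φ ∈ {F, Y, W}) between Cys IV and V. Disulfides follow the fixed
pattern Cys I–IV, II–VI, III–VII, V–VIII, closing a pseudocyclic fold.
These peptides mature from three-domain precursors — signal peptide,
prodomain, mature domain — cleaved by asparaginyl endopeptidase (AEP)
at an Asn↓Cys junction.

`crpforge` is a Python library (with a thin CLI) for the complete
desk-side workflow around such peptides:

- **seqio** — FASTA I/O, six-frame translation, Met-initiated ORF
  extraction from transcriptome contigs;
- **motif** — the 8-Cys framework scanner, ginsentide-like vs
  chitin-binding classification, disulfide connectivity assignment,
  pairwise identity and residue composition;
- **precursor** — AEP-site detection and mature-domain excision;
- **masscalc** — disulfide-aware monoisotopic/average peptide masses
  and modification-shift algebra (carbamidomethylation +57.02146 Da,
  Met oxidation +15.99491 Da, +2.01565 Da per reduced disulfide), with
  cysteine-count inference from observed shifts;
- **peakmatch** — MS1 peak-list screening in the 2–5 kDa CRP window,
  proteoform (oxoform) matching at ppm/Da tolerances, and
  molecule-level methionine-sulfoxide fraction estimation;
- **diffquant** — two-group fold-change/significance analysis
  (significance = −10·log₁₀ p on log2 intensities) with the
  fold ≥ 2, significance > 15 volcano filter and contaminant
  exclusion;
- **synthdata** — seeded generators for decoy transcriptomes with
  planted precursors, MALDI-style peak lists and quantification
  matrices, each with a ground-truth table.

## Worked example

```python
import crpforge as cf

rec = cf.SequenceRecord(id="tC1", seq=cf.TC1_SEQUENCE, kind="protein")
(match,) = cf.scan_crp_motif(rec)
print(match.cys_positions)      # (1, 8, 15, 16, 19, 21, 28, 33)
print(match.loop_lengths)       # (6, 6, 0, 2, 1, 6, 4)
print(cf.classify_8c_hlp(match).label)   # ginsentide_like

mass = cf.peptide_mass(cf.TC1_SEQUENCE, cf.MassOptions(n_disulfides=4))
print(round(mass, 3))           # 3368.128  (Da, monoisotopic, 4 disulfides)
print(round(cf.mz(mass, 1), 3)) # 3369.136  ([M+H]+ seen in MALDI)

shift = cf.reduction_alkylation_shift(n_cys=8, n_disulfides=4)
print(cf.nominal(shift))        # 464  (Da; pins the cysteine count at 8)
```

The 33-residue peptide has its eight cysteines at positions
1,8,15,16,19,21,28,33; the one-residue loop between Cys V and VI is
the ginsentide-like signature; the 464 Da reduction/alkylation shift
is the mass-spectrometric fingerprint of 8 cysteines in 4 disulfides.
The `examples/` directory has one narrative script per capability
(scanning, mass arithmetic, transcriptome mining, MALDI peak matching,
enrichment screening); each prints the numbers above or their
synthetic-data counterparts.

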