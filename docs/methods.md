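# Methods

## Framework scanning

The 8-cysteine framework is defined by eight cysteines whose seven
inter-cysteine segments ("gaps") are cysteine-free and satisfy
per-gap length bounds; gap 3 (between Cys III and IV) must be empty —
the tandem `CC`. Because gaps are cysteine-free, framework cysteines
are necessarily *consecutive* cysteines of the sequence, so the
scanner slides over runs of eight consecutive Cys and checks the gap
bounds — O(number of cysteines) per protein, and provably equivalent
to enumerating all 8-subsets of cysteine positions under the same
constraints (the test suite checks this equivalence exhaustively at
small sizes and on random strings).

Default gap bounds (configurable):

| gap (Cys k → k+1) | 1 | 2 | 3 (CC) | 4 | 5 | 6 | 7 |
|---|---|---|---|---|---|---|---|
| min | 2 | 2 | 0 | 1 | 1 | 2 | 1 |
| max | 12 | 12 | 0 | 8 | 8 | 12 | 10 |

These bracket the known ginsentide/coffeetide/cocotide frameworks
(the cocotide tC1 gaps are 6,6,0,2,1,6,4) without admitting arbitrary
cysteine arrangements. Overlapping candidate frameworks are resolved
greedily left-to-right with no shared cysteines, which makes output
deterministic; skipped alternatives are logged.

Two loop numberings coexist in the field: gap numbering (above) and
the family literature's loop numbering, which skips the empty CC gap
so that "loop 3" is gap 4 (Cys IV–V) and "loop 4" is gap 5 (Cys V–VI).
Reports emit both.

### Classification

*ginsentide-like*: the Cys V–VI loop is exactly one residue (the CXC
motif). *chitin-binding 8C-HLP*: the Cys IV–V loop contains the
conserved serine/aromatic stretch and the Cys V–VI loop is six
residues with ≥ 1 aromatic. The serine/aromatic stretch is matched as
`S.{0,1}[FYW].{0,1}[FYW]`: the canonical notation S-x-Φ-x-Φ is
ambiguous about whether the spacer positions are obligatory, and
family alignments show both spaced and adjacent aromatics, so each
spacer may be absent. Anything matching neither rule is `other_8C`.
Classification depends only on loop strings, never on absolute
positions.

Disulfide connectivity is not predicted: the fixed 8C-HLP pattern
I–IV, II–VI, III–VII, V–VIII is mapped onto the matched cysteine
positions. Verifying it experimentally requires MS2 of partial
digests, which is out of scope.

### Identity and composition

`pairwise_identity` is ungapped percent identity for equal-length
sequences and global-alignment identity (match 1, mismatch 0, linear
gap −1, via Biopython's PairwiseAligner) otherwise. It is labeled
*identity* in all outputs: similarity measures with substitution
groups score higher and are not implemented. Composition percentages
round half away from zero to one decimal; net formal charge counts
Asp/Glu −1, Lys/Arg +1, His 0 at neutral pH, free termini +1/−1
(cancelling).

## Precursor maturation

AEP cleavage sites are Asn|Cys junctions (donor set configurable to
{N, D}, acceptor set configurable beyond {C} for other CRP families).
`parse_precursor` chooses the leftmost junction whose downstream
segment starts at Cys I of a ginsentide-like framework. Signal
peptides are *not* predicted here — dedicated predictors do that
better — so cleavage positions are accepted from the caller; the
fallback is a Kyte–Doolittle heuristic (longest run of 8-residue
windows with mean hydropathy > 1.5 within the first 40 residues,
cleavage 5 residues after the hydrophobic core) that is always
flagged `heuristic`. The mature domain runs to the precursor's C
terminus by default, since only the N-terminal maturation event is
modeled.

## Mass arithmetic

Peptide mass = Σ residue masses + water − n_SS × 2.015650 Da
(monoisotopic; an average-mass table is provided because linear-mode
MALDI of 3+ kDa species can report average mass). All constants live
in one table in `masscalc`; the monoisotopic residue table is
cross-checked in tests against elemental compositions and against
pyteomics. Modification shifts: carbamidomethyl +57.021464,
Met → Met(O) +15.994915, +2.015650 per reduced disulfide.

The cysteine-counting experiment (reduce with DTT, alkylate with
iodoacetamide) shifts a fully bonded peptide by
n_Cys × 57.021464 + n_SS × 2.015650; for 8 Cys in 4 disulfides that
is 464.23 Da (nominal 464). A per-cysteine increment of 56 Da is
sometimes quoted for this experiment but is inconsistent with the
observed 464 Da total; the correct chemistry is ≈ 58.03 Da per
cysteine when fully disulfide-bonded, which this module implements.
`infer_cys_count` inverts the shift by nearest-candidate search with
ties toward smaller counts and errors out (reporting the two nearest
candidates) when no count lies within tolerance. Nominal-Da reporting
rounds half away from zero.

## Peak matching and oxoforms

Peak lists are two-column (m/z, intensity) text; mzML ingestion is an
extension point. The default matching tolerance is
max(0.5 Da, 200 ppm) — typical of externally calibrated MALDI-TOF at
3 kDa; high-resolution ppm-only tolerances can be configured. Each
proteoform takes its nearest in-tolerance peak, ties broken toward
higher intensity then lower m/z; a peak may serve several proteoforms
but ambiguous assignments are warned about. Window screening keeps
peaks whose neutral mass (m/z − 1.007276) falls in [lo, hi] and whose
intensity clears a fraction of the in-window base peak.

Oxoform analysis enumerates 0..k oxidized methionines at
+15.994915 Da each and reports intensity-weighted fractions over the
matched ladder. These are *molecule-level* fractions; site-level
percentages (which methionine is oxidized) require MS2 localization
and are explicitly out of scope — output headers say so.

## Differential quantification

Intensities (+ pseudocount, default 1.0, guarding zeros in label-free
data) are log2-transformed; per-protein fold change is the difference
of group means and significance is −10·log₁₀ p from a two-sided
two-sample t-test on the log2 values. The score's ">15" convention
corresponds to p < 10^−1.5 ≈ 0.0316. The default test pools the group
variances: at the three-replicate balanced designs these screens use,
the pooled test is exactly calibrated under the equal-variance
Gaussian null, whereas the Welch/Satterthwaite form (available via
`welch=True`) is noticeably conservative at n = 3 (empirical type-I
≈ 2% at the 3.16% nominal cut) and costs power without protecting
against much at equal group sizes. No multiple-testing correction is
applied by default because the screen filters on raw significance;
Benjamini–Hochberg is behind a flag. Proteins with fewer than two
finite values in a group are reported as untestable, never imputed.
The volcano filter keeps log2FC ≥ log2(min_fc) with significance >
min_sig (depleted symmetric); contaminant exclusion is a set
difference against a caller-supplied identifier list (e.g. CRAPome).

## Synthetic data

The generators produce the statistical structure the pipeline
assumes, not realistic biology:

- **Transcriptomes**: planted precursors are
  signal(26, Met + hydrophobic) + prodomain(35, Asn-terminal,
  alphabet excluding Cys/Asn/Met to avoid spurious junctions and
  frameworks) + mature domain (template mutated at non-Cys positions,
  default rate 0.05, matching the family's near-absolute cysteine
  conservation and ~85–95% intra-family identity) + stop codon,
  back-translated with uniform synonymous-codon choice; the
  26 + 35 layout puts the AEP junction at Asn61|Cys62, the
  maturation coordinates of the template family. Half the planted
  transcripts are reverse-complemented. Decoys are random codon runs.
  A `plant_broken_framework` mode plants 7-Cys near-misses to probe
  scanner specificity. Not emulated: UTRs, introns, codon bias,
  sequencing error, fragmented contigs — so end-to-end recovery rates
  here measure the pipeline's logic, not assembler robustness.
- **Peak lists**: one [M+H]+ peak per peptide with Gaussian relative
  mass error (default σ 50 ppm), a single-oxidation satellite at
  intensity ratio f/(1−f) (default f = 0.27, a typical partial
  Met-oxidation level arising during extraction), and uniform noise
  peaks in 2–5 kDa at 2% relative intensity. Not emulated: isotope
  envelopes, adducts, detector saturation, baseline.
- **Quantification matrices**: per-protein log2 baselines
  ~ N(20, 2), replicate noise N(0, 0.1), defaults of 2465 proteins
  with 151 planted 4-fold enrichments in 3 vs 3 — the scale of a
  typical pull-down screen, at which the planted effect is recovered
  completely. Not emulated: missing-value mechanisms,
  intensity-dependent variance, batch effects.

Every generator is a pure function of its config including the seed;
identical configs reproduce outputs byte-for-byte.

## Numerical and edge-case conventions

- Coordinates: 0-based half-open internally, 1-based inclusive in all
  human-readable output.
- `X` is accepted in protein sequences; framework matches whose loops
  contain `X` are flagged low-confidence rather than dropped.
- Degenerate t-tests (zero variance in both groups): p = 1 when the
  means agree, p → 0 (capped at 10⁻³⁰⁰) when they differ.
- Zero-total-intensity oxoform ladders raise rather than return NaN.
- Empty FASTA / peak lists parse to empty collections with a logged
  warning; malformed lines fail loudly with line numbers.

## Problem sizes

The shipped tests and the acceptance script use 50–62 contig
transcriptomes with 12 planted precursors, 20-replicate spectrum
simulations, and quantification matrices up to 2465 × 6 (1000 × 6 for
null calibration), sizes at which every stochastic check is stable
across seeds while the whole suite stays fast.

## Known limitations

- Homology search, profile HMMs and structure prediction are not
  included; the scanner is purely pattern-based and will miss
  frameworks with unusual loop lengths outside the configured bounds.
- The significance score approximates proprietary search-engine
  scores only in scale, not in value.
- Identity, not similarity, is reported; figures quoted as
  "similarity" elsewhere may exceed it.
- Site-level PTM localization, MS2 scoring and isotope-envelope
  processing are out of scope.
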