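# Methods

This note documents the models and procedures `complexdyn` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions the implementation commits to.

## The formability model

The central object is the *possible formable protein complex* (PFPC): a
complex is called possibly formable in a sample when every subunit protein
has at least one of its associated features detected there. Two modelling
choices deserve emphasis:

- **Existential subunit expression.** A subunit counts as expressed when
  *any* of its associated transcripts (or genes, at gene level) is detected.
  Requiring all isoforms would leave multi-isoform subunits almost never
  expressed and formability counts near zero; a single encoding transcript
  suffices for the protein to be producible.
- **PFPC is a presence proxy, not assembly evidence.** The call says the
  transcriptional prerequisites for assembly are met in that sample; it says
  nothing about translation efficiency, localisation or binding.

Subunits sharing a gene are tested independently through their own
transcript sets (the shared gene can satisfy both), and proteins encoded by
several genes are supported (a protein's gene set is the image of its
transcript set under the transcript→gene map).

Under rolled-up gene detection (gene detected iff ≥1 transcript detected),
the transcript-level PFPC set is provably contained in the gene-level set in
every sample: any detected transcript that makes a subunit expressed at
transcript level also makes its gene detected. The gene-level excess is
exactly the overestimation isoform resolution removes, and the containment
is asserted as a test invariant on every random universe.

## Detection

Detection consumes MMSEQ-style per-sample tables (feature, log-scale
estimate, posterior SD). A feature is detected when it is present in the
sample's file and its posterior SD ≤ `sd_max` (default 1.5, boundary
inclusive: the convention is that values *greater than* 1.5 are excluded).
The estimate itself is never thresholded by default; an optional estimate
floor exists (`min_estimate`, off by default) for sensitivity analyses.
Missing cells (feature absent from one sample's file) are distinct from
SD-filtered cells and are never detected. Gene-level analysis supports both
a native gene-level matrix and rollup from transcript calls; rollup is the
default in tests because it makes the containment theorem exact rather than
approximate.

## Major isoforms and switching

The major (dominant) isoform of a gene in a sample is the detected
transcript with the maximal expression estimate; ties break to the
lexicographically smallest transcript id, which makes assignments
deterministic and invariant under any uniform monotone rescaling of one
sample's estimates. Genes with no detected transcript are out of domain.

Involvement is reported two ways per sample: (a) the fraction of PFPCs with
at least one subunit whose transcript set contains a gene's major isoform,
and (b) the fraction of expressed subunit proteins whose transcript set
contains the major isoform of one of their genes. Reading (a) requires only
that the subunit's gene's dominant product encodes the subunit — it does not
additionally require the major isoform to be the specific detected
transcript that made the subunit expressed.

Switching is evaluated over *eligible* constituents: proteins with ≥2
associated transcripts from a single gene (if several genes qualify, the
lexicographically smallest is the evaluation gene). For a sample pair, the
switch fraction is the share of eligible constituents whose evaluation
gene's major isoform differs, among constituents whose gene has a defined
major isoform in *both* samples. Denominators are pair-specific and
reported next to each fraction; an empty denominator yields a missing
(NaN) entry, never 0. The overall switch fraction is the share of eligible
constituents whose major isoform takes ≥2 distinct values across the
samples where it is defined.

## The (M, D) differential-expression probability

For each transcript, with case/control group means computed on normalized
abundances (group summary = arithmetic mean):

- M = log2(mean_case / mean_control), with a pseudo-count of 0.5 substituted
  for zero values before the ratio (configurable);
- D = |mean_case − mean_control| on the normalized scale (no pseudo-count).

The noise distribution pools (M\*, D\*) pairs from all within-group
sample-pair comparisons across both groups. When no group has replicates,
technical replicates are simulated: each observed sample is multinomially
resampled at its observed depth (5 replicates per sample by default) and
noise pairs are drawn among the simulated replicates; signal values still
come from the observed samples. The probability is

q = fraction of noise pairs with |M\*| < |M| and D\* < D

with strict inequalities (boundary pairs do not count), so a transcript
with identical group means has q = 0 exactly. DE sets are `{t : q > q_min}`
with per-dataset defaults reflecting replication strength: breast 0.9,
colon 0.9, lung 0.99 (no replicates), prostate 0.8.

Normalization follows the median-deviation-from-the-mean convention: per
sample, the offset is the median natural-log abundance over its nonzero
transcripts minus the mean of those medians across samples, and the sample
is rescaled by exp(−offset). Offsets sum to zero, zeros stay zero, and a
single-sample matrix is unchanged.

**Abundance-dependence.** Because D is an *absolute* difference and the
noise pool is shared across all transcripts, weakly expressed transcripts
compete against noise pairs from strongly expressed ones and their q
saturates below strict thresholds. Sensitivity for planted 4-fold changes
at q > 0.9 is therefore high (≈0.9) for low-dispersion, moderately spread
abundances and degrades as dispersion and abundance spread grow (≈0.5 at
negative-binomial dispersion 0.1 with log-normal σ = 1), while the
false-positive rate stays near zero throughout. This is a property of the
statistic itself — q values agree with a brute-force recomputation from the
explicit noise pool in all regimes — and is the reason the recovery
demonstration in the test suite uses the low-dispersion regime.

## Impact propagation

A DE transcript impacts a complex when some subunit carries it; a complex is
affected when it has ≥1 impacting transcript. Direction of change is
recorded but does not enter membership. Overlaps across datasets are
reported as intersection counts (not Jaccard): a transcript-overlap matrix,
a complex-overlap matrix, and a combined matrix with shared affected
complexes in the upper triangle and shared in-complex DE transcripts in the
lower. Two structural facts are asserted as invariants: the complex image
of the shared DE transcripts is contained in the shared affected complexes
(which is why complex-level overlaps amplify transcript-level ones), and
growing a DE set never shrinks its affected set.

## The synthetic-data generator

The generator emulates the statistical structure of a curated complex
resource profiled across tissues and cohorts. Defaults are the study
conditions; each is a documented emulation target, not a reproduction:

| parameter | default | what it encodes |
| --- | --- | --- |
| `n_complexes` | 500 | universe size (desk-scale) |
| `complex_size_probs` | mass on 2–4 (mean ≈ 2.9) | observed complex-size histogram shape |
| `sharing_rate` | 0.49 | fraction of subunits in ≥2 complexes; realized *exactly* up to rounding |
| `tx_per_gene_mean` | 2.26 | transcripts per complex subunit |
| `decoy_tx_per_gene_mean` | 1.35 | proteome-wide transcripts per protein |
| `n_samples` | 16 | tissue panel size |
| `coexpression` | 0.94 | co-detection of complex-member transcripts |
| `absent_rate` | 0.06 | marginal per-sample subunit absence |
| `variable_subunit_fraction` | 0.21 | tissue-variable subset absences concentrate in |
| `involvement_rate` | 0.8 | subunits whose gene's dominant isoform encodes them |
| `switch_rate` | 0.11 | planted pairwise switch fraction |
| `switch_pool_fraction` | 0.35 | switch-prone subpool; bounds the ever-switched fraction |
| `dominance_margin` | 1.0 (log units) | planted gap between dominant and runner-up isoforms |
| `noise_sd` | 0.1 | Gaussian noise on log estimates |
| `nb_dispersion` | 0.1 | negative-binomial dispersion of count datasets |

Construction details that matter for interpretation:

- **Sharing is exact by construction**: shared proteins occupy exactly two
  complex slots, private ones one, with the protein count chosen as
  slots/(1+rate); the realized sharing fraction equals the target up to
  rounding, at the cost of capping complexes-per-protein at 2.
- **One gene per protein** in generated universes; multi-gene proteins and
  complexes whose subunits share a gene are supported by the analysis code
  and exercised by handcrafted fixtures instead.
- **Non-involved subunits** get an extra transcript on their gene, mapped to
  a non-complex protein, planted as the constant dominant isoform — so the
  gene is detectable while its dominant product does not encode the subunit.
- **Absences are correlated across tissues**: they are confined to the
  tissue-variable subunit subset (the rest is a constitutive core), with the
  conditional rate derived so the marginal stays `absent_rate`. Independent
  absences would drive the cross-tissue common-PFPC fraction far below what
  tissue panels show.
- **Dropout spares dominant isoforms** (the highest-expressed transcript is
  the one reliably quantified), so co-detection noise does not manufacture
  incidental switches.
- **Switches are exact-count flips** relative to the first sample, drawn
  from the switch-prone subpool; with `noise_sd` below half the dominance
  margin the analysis recovers every planted assignment exactly, and the
  first-sample pair fractions equal round(rate·n_eligible)/n_eligible.
- **Tissue matrices are log-scale Gaussian with bimodal SDs** (well below
  vs well above the 1.5 threshold), matching what the detection filter
  consumes; **count datasets are negative-binomial** with per-sample
  library-size factors (log-normal σ = 0.1) so normalization does real work.
  Default replicate structure: breast 2v2, colon 2v2, lung 1v1, prostate
  12 cases vs 9 controls.

Everything planted is recorded in a ground-truth ledger derived from the
same matrices the files are written from, and identical configurations
(including the seed) produce byte-identical files.

**What passing tests do not show.** The generator draws independent
Gaussian/negative-binomial noise and plants clean margins; real
quantifications have correlated uncertainty across isoforms of a gene
(multi-mapping reads), abundance-dependent posterior SDs, batch structure,
and isoform-level correlation within conditions. Exact-recovery results are
statements about the implementation's correctness, not about expected
performance on real tissue panels.

## Numerical conventions and degenerate inputs

- SD threshold boundary inclusive (1.5 detected, 1.6 not).
- Major-isoform ties → lexicographically smallest transcript id.
- Duplicate complex records → first in file order wins.
- Empty subunit lists and ambiguous subunit tokens are collected into a
  rejects report, never fatal; malformed rows and missing columns are fatal
  with the offending line or column named.
- Single-sample normalization is the identity; an all-zero sample is an
  error.
- q thresholds validated to (0, 1); `sd_max` must be positive.
- Pairwise switch entries with empty denominators are missing, not 0.
- An empty DE set propagates to an empty impact, and datasets with
  mismatched complex universes cannot be overlapped.
- All randomness flows from a single integer seed through per-stage
  `numpy` generator streams; reported tables are rounded to 6 decimals
  before writing so reruns are byte-identical.

## Problem sizes

Default analyses run 500 complexes (~1,000 subunit proteins, ~3,300
transcripts including decoys), 16 tissues and four count datasets; the
whole pipeline completes in seconds on one CPU. The test suite's
randomized-oracle checks use 100 seeds of ~25-complex universes, and the
DE recovery run uses 2,000 transcripts at 5v5 — sizes chosen so the full
suite stays fast while every code path is exercised.
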