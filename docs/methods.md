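# Methods

`epiphos` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the statistical core of a TMT phosphoproteomics
analysis of early epileptogenesis: two 11-channel plexes (hippocampus at
4 h and 24 h after pilocarpine-induced status epilepticus, with mock and
untreated controls), phosphopeptide-level differential testing, and
kinase-activity inference from substrate motifs.

## Experimental design and contrasts

Each plex carries 3 untreated + 4 mock-injected + 4 pilocarpine-injected
channels.  Plexes are always analyzed separately; no ratio bridging or
IRS normalization across plexes is attempted.  The four contrasts are
pilocarpine vs mock within each plex — P/M(4 h), P/M(24 h) — and mock
(which includes diazepam) vs untreated — D/U(4 h), D/U(24 h).  Log2 fold
changes are treatment minus control.

## Ingest

Phosphosite rows are re-annotated against the search FASTA: every ±7
sequence window is recomputed from the stated protein position, with `_`
padding at protein termini and a hard error on residue disagreement.

Localization filtering: the primary (first-listed) site of a
multi-phosphorylated peptide must exceed probability 0.5, with supporting
evidence of another site above 0.75 in at least one experimental group.
Singly phosphorylated peptides must exceed 0.75 in at least one group.
The 0.75 single-site convention is our choice — the source rule is stated
only for multi-phosphopeptides — and mirrors the secondary-evidence
threshold; it is recorded in the run manifest.

Peptide forms sharing (gene, site set, multiplicity) across charge and
modification variants collapse to one phosphopeptide feature whose
per-sample value is the median of the log2 intensities over non-missing
duplicates.  Zero reporter intensity is treated as missing (standard TMT
convention).  For all sequence matching of multi-phosphopeptides the
first site's window represents the feature.

## Preprocessing (per plex)

Order: group-missingness filter → quantile normalization → kNN
imputation → surrogate-variable correction → outlier screen.  Whether the
original filtered before or after normalizing is not stated; filtering
first avoids letting mostly-missing features shape the reference
distribution, and the order is recorded in the manifest.

* **Missingness filter.** A feature is kept iff every group required by
  the requested contrasts has at most 25% missing values
  (`missing.max_group_frac`).
* **Quantile normalization.** With complete data every column's sorted
  values become the across-column mean of order statistics.  With
  missing data, ranks are computed on observed values only and mapped
  through a pooled reference by interpolated rank, which reduces to the
  complete-data definition when nothing is missing.
* **kNN imputation** (`impute.k = 10`, the classical default for this
  method; the source does not state k).  A missing entry is the
  unweighted mean, over the k nearest feature rows by Euclidean distance
  on co-observed samples, of their values at that sample; neighbours
  must be observed there.  With no eligible neighbour the feature's row
  mean is used.  Observed entries are never altered.  This row-wise
  scheme is implemented directly because the scikit-learn imputer falls
  back to column means, a different contract.
* **Surrogate variables.** The number of surrogates comes from a
  permutation test on residual eigenvalues (rows of the residual matrix
  independently permuted, 25 permutations, threshold 0.10).  Estimation
  is two-step: candidate directions are right singular vectors of the
  residual matrix (hence orthogonal to the design — a factor fully
  aligned with the design is never proposed and cannot be absorbed);
  each candidate is then re-estimated from the raw, row-centered
  sub-matrix of the features most associated with it (top decile of
  residual correlation).  Raw re-estimation lets a *partially*
  design-aligned technical factor be recovered in full, so the joint
  regression can de-bias the design coefficients.  Correction by default
  regresses the surrogate components out after a joint fit on
  [design | surrogates] (`sva.mode = regress`); covariate mode is the
  more faithful alternative and is supported by passing surrogates into
  a covariate-aware fit, at the cost of carrying them through every
  downstream call.  Regress-out does not charge degrees of freedom for
  the removed components, which makes the corrected test slightly
  anti-conservative when surrogates are strong.
* **Outlier screen.** Samples are projected onto the first two principal
  components and flagged when their squared Mahalanobis distance exceeds
  the chi-square(2) quantile at 1 − 10⁻⁴.  With ~11 samples, a
  covariance that includes the candidate caps the classical distance at
  (n−1)²/n ≈ 9.1, below the 18.4 threshold — no sample could ever be
  flagged (masking).  Each sample is therefore screened against the
  leave-one-out mean and covariance of the others, which preserves the
  stated threshold rule and flags a grossly displaced sample.  Flagged
  samples are removed and the chain re-runs exactly once.

## Differential testing

Per feature, a group-means linear model is fit over all groups of the
plex; the residual variance s²_g (d_g df) is shrunk toward a prior
(d₀, s₀²) estimated across features by moment matching on log s²_g
(digamma/trigamma moments; trigamma inverted by Newton iteration).  The
moderated statistic is

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
    t_g  = (x̄_treat − x̄_ctrl) / (s̃_g·√(1/n_t + 1/n_c)),

with p-values from a t distribution on d₀ + d_g df, capped at the pooled
residual df across features (the prior cannot carry more information
than the data it was fit on; this matches the reference implementation's
behaviour when d₀ → ∞, where the prior variance is the pooled arithmetic
mean).  Exact-zero variances are offset to 10⁻⁵ of the median before the
prior fit.  d₀ = 0 recovers the ordinary t-test; d₀ = ∞ the fully pooled
test.

Benjamini–Hochberg adjustment is applied per contrast within each plex;
adjusted p < 0.05 is significant.  Significant phosphopeptides whose
gene's protein is significant in the matching comparison at either
timepoint are excluded from downstream significant sets; features with
no protein record are kept.

**Power at the study's design point.** With log2FC = 1.0, within-group
SD 0.5 and 4 vs 4 replicates, the noncentrality is
1.0/(0.5·√(1/4+1/4)) ≈ 2.83, which caps two-sided power at unadjusted
α = 0.05 near 0.81; any multiplicity adjustment lowers it further (BH
over thousands of mostly-null features reaches roughly 0.35–0.40
sensitivity).  Detection-rate expectations at these settings must be set
against this ceiling; the median *estimated* effect remains essentially
unbiased.

## Kinase activity (swing statistic)

For each kinase, a position weight matrix over the 15 window positions is
built from its curated substrate windows with pseudocount 0.01 and a
uniform background; `_` contributes no count, and kinases with both
Ser/Thr and Tyr specificity are modeled once per residue class.  A
window scores Σ_j log2(f_{a_j,j}/b_{a_j}) (padded positions add 0); the
center position is scored like any other.  Scores calibrate to empirical
p-values against 1,000 windows sampled (seeded) from all detected
windows of the same residue class, with add-one counting; matches at
p ≤ 0.05 become network edges.

Per kinase, with p⁺ and p⁻ the proportions of its substrates
significantly up / down (raw differential p ≤ 0.05, per the source's
stated rule),

    swing_raw = (p⁺ − p⁻) · ln(n_edges + 1) · ln(n_seqs + 1),

z-transformed across kinases.  The exact weighting function of the
original package is not printed anywhere we could verify; this form is a
direct reading of "weighted by the number of edges and the number of
substrate sequences" with logarithmic damping so high-degree kinases do
not dominate, and it is the pluggable default, not a claim of
bit-compatibility.  Significance comes from a degree-preserving
permutation: each kinase's edge endpoints are resampled without
replacement from the network's substrate pool (implemented exactly as a
multivariate hypergeometric draw over up/down/other substrate counts),
permuted swings are z-transformed within each permutation, and one
add-one p-value is reported per tail over 1,000 permutations.

Known-substrate validation: kinase–substrate pairs match detected
features on identical gene name and identical ±4-residue window core;
duplicate (gene, window) database pairs count once; a kinase needs at
least four matched significant substrates to receive an average
significant log2FC.

## Regulatory sites, ranked lists, enrichment, clustering

Regulatory-site matching uses the same gene + ±4-core convention; on
redundant matches the value with the largest magnitude is kept
(deterministic tie-break by feature id).  Per (function, direction) the
median significant log2FC and the perturbed percentage of detected
matched sites are reported.

Ranked gene lists per contrast and direction: significant features are
ranked by ascending adjusted p and by descending |log2FC|; the two ranks
are summed, the list sorted by the combined rank (ties broken by the
significance rank, then gene symbol — the source is silent, and this is
deterministic and order-independent), and duplicate genes keep their
best entry.  The background is the genes detected in both the proteome
and the phosphoproteome.

The ordered enrichment is a deliberate minimal stand-in for external
ordered-query services: per term, the minimum over all ranked-list
prefixes of the hypergeometric upper tail, BH-corrected across terms,
with an optional term-size cap.  Being an uncorrected minimum it is
anti-conservative under the null (measured KS ≈ 0.38 from uniform for
100-gene lists over a 400-gene background) and is suitable for ranking
terms, not for calibrated inference.  Heatmap ordering uses
complete-linkage agglomeration on Euclidean distance.

## Synthetic data

The generator emulates the processed-table structure of the study: two
11-channel plexes; log2-normal baselines (mean 20, SD 1.5) with
within-group SD 0.5; ~25% missing values imposed by a logistic function
of standardized intensity (left-censoring, as in real TMT phospho data;
an MCAR mode exists for imputation tests); one batch vector per plex,
centered within groups so it is identifiable and orthogonal to the
design; 15% doubly phosphorylated features; 10% duplicate peptide forms
(charge variants with ±0.05 log2 jitter); 10% of features constructed to
fail the localization rule; and per-group localization probabilities.
Planted truth covers feature-level effects (defaults: +1.0 at 4 h on 250
features, −1.0 on 200, a 120-feature persistent subset, +0.8 at 24 h on
100), kinase activations (one up at 4 h and one down at 24 h, 40
substrates each, windows drawn from the kinase's consensus with 20%
per-position noise), and 30 protein-level confounds that shift a gene's
protein feature together with all of its phosphopeptides, exercising the
protein-exclusion filter.  Protein sequences are built so that every
window is literally a substring of the FASTA — re-annotation is exact by
construction.

What the generator does **not** emulate: spectrum-level identification
noise, isotope impurity and ratio compression, peptide-specific
ionization effects, correlated missingness across co-eluting peptides,
and real motif distributions (synthetic consensus motifs are random
15-mers).  Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated generative model, not
end-to-end performance on real spectra.

## Numerical and degenerate-input conventions

Site positions are 1-based within the protein.  Quantile normalization
of a single-sample matrix warns and returns the input.  An all-missing
duplicate set stays missing.  Features with zero residual df are
skipped.  A swing SD of zero across kinases is an error (z undefined).
Singular leave-one-out covariance in the outlier screen warns and flags
nothing.  All randomness flows through explicit integer seeds
(numpy `SeedSequence` spawning), and reruns with identical inputs and
seeds are byte-identical, which the test suite asserts end to end.

## Problem sizes used in the shipped studies

The calibration, recovery and determinism studies run at 5,000 features,
1,200 proteins and 30 kinases (50 for the null-uniformity study) with
1,000 permutations — the scale at which the moment-matching prior, the
permutation nulls and the missingness mechanics are all well exercised
while a full study completes in seconds on one CPU.
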