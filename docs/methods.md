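# Methods

## Deconvolution model

Each feature × replicate profile `x` (relative abundance across `F = 8`
gradient fractions, row-normalized to sum 1) is modeled as a non-negative
linear combination of per-localization marker mean profiles plus a sign-free
intercept:

```
min_{p ≥ 0, c}  || x − Σ_l p_l b_l − c·1 ||²
```

The intercept is realized inside the non-negative solver (scipy NNLS) by
augmenting the design with a `+1` and a `−1` column, so `c = c⁺ − c⁻` is free
in sign while proportions stay non-negative. `R²` uses the total sum of
squares about the profile mean, so "explains 90% of the variance" is read as
a variance statement. Proportions are *not* constrained to sum to 1 during
fitting; a normalized view is provided for ternary-style displays. QC keeps a
fit iff `R² ≥ 0.90` and `|c| ≤ 0.05`; a feature × condition is reported when
at least 2 of 3 replicates pass, as the mean over passing replicates.

The point estimate reported is the full-marker fit; the bootstrap (B = 100)
resamples each marker class independently with replacement at its own size
(preserving class balance), rebuilds the basis and refits, and reports
per-localization means and 2.5/97.5 percentiles.

Basis modes: in the **density** design the ER class is excluded (its members
relocalize under stress) and the mitochondrial class — the 13 mitochondrially
encoded mRNAs, which have no cytosolic copies — is relabeled `membrane`,
anchoring 100% membrane localization. In the **sedimentation** design
mitochondria and ER are separate basis rows summed downstream into a membrane
proportion. Relocalization deltas are computed on raw (unnormalized)
proportions; a normalized view can be substituted by the caller.

## Spike-in normalization

Spike-ins enter every fraction at the same absolute amount, so
`content_f ∝ (endogenous_f / spikein_f) / proportion_used_f` recovers the
per-fraction RNA content up to scale (normalized to sum 1; only relative
content matters downstream, and a fixed scale aids testing). Because TPM
denominators include the spike-ins themselves, quantifications are first
re-expressed on endogenous features (`rescale_to_endogenous`); content
multiplication then recovers absolute per-fraction abundances exactly rather
than up to the per-library spike-in share — this is what makes the noiseless
end-to-end identity hold to machine precision.

## What the simulator emulates — and what it does not

The generator reproduces the *measurement process*: unimodal compartment
archetype profiles over the gradient; transcripts mixing compartments through
ground-truth proportion vectors; absolute amounts diluted per fraction;
spike-ins at fixed absolute amounts; fraction libraries sequenced to fixed
depth with Gamma–Poisson (negative-binomial) counting noise; and an
unfolded-protein-response condition in which mRNAs shift mass toward the
granule compartment with gain `expit(b0 + b1·log10 L + b2·AU + b3·p_mem)`
(defaults −8, 1.5, 3, −2: longer and AU-rich transcripts relocalize more,
membrane-anchored ones resist). lncRNAs do not relocalize.

Deliberate design choices, with rationale:

- **Archetypes** are triangular bumps with evenly spaced peaks and
  heterogeneous half-widths (0.35–1.0 × peak spacing, seeded). Near-equal
  widths would tile the gradient like a partition of unity, putting the flat
  (all-ones) direction inside the basis span and making the deconvolution
  intercept unidentifiable — its QC filter would then reject fits at random.
  The draw is therefore required to leave the ones vector at relative
  residual ≥ 0.2 from the row span (rejection-sampled, deterministic;
  geometries that cannot satisfy the bound keep the best draw). Real marker
  profiles are heterogeneous in spread, so this is also the realistic case.
- **Truth proportions are support-sparse**: each transcript occupies 1–3
  compartments (weights per biotype; lncRNAs skew nuclear/cytosolic), the
  rest exactly zero. Real transcripts do not populate every compartment, and
  dense Dirichlet truth makes rank-based recovery metrics degenerate (a
  majority tie block of near-zero truths).
- **Per-fraction RNA content** is produced by unprofiled background RNA
  (an rRNA-like carrier, 30% of endogenous mass by default, distributed per
  the config's content vector). Content differences in a real gradient are
  emergent from where RNA sits; an exogenous multiplier on the profiled
  transcripts would distort the mixture identity the deconvolution relies on.
- **Depth 5×10⁶ counts per fraction library** reproduces the per-feature
  coverage of a ~30M-read library over a full transcriptome at the simulated
  3,000-transcript scale; **dispersion 0.01** reflects largely technical
  within-gradient noise between replicate gradients.
- **PSM tables**: archetype profiles with a 2% reporter-channel noise floor
  (no real TMT channel is exactly zero), log-normal PSM intensities,
  multiplicative channel noise (sd 0.1), missingness with probability
  decreasing in intensity rank (linear in rank — equivalently logistic in
  logit-rank — so the realized rate equals the configured rate exactly in
  expectation), planted cRAP-style contaminants plus shadow proteins sharing
  one observed peptide, and outlier PSMs displaced onto the most distant
  archetype. Outliers are planted only in proteins keeping ≥ 4 PSMs after
  the unique-master and missingness filters, so every plant is recoverable
  by the median-distance rule (a displaced PSM among < 3 concordant siblings
  removes its siblings too, making exact recovery impossible by
  construction).

Passing tests on this generator show the estimators recover a *known
mixture-of-archetypes truth under the stated noise*; they do not certify
behavior under features real data add — fraction-specific extraction biases,
correlated technical artifacts across fractions, archetype misspecification
(compartments whose profiles drift between conditions), or annotation error.

## Marker discovery

NNMF uses multiplicative updates on a masked Frobenius objective, seeded
uniform initialization, a relative-change stopping rule, and a small ridge
term (1e-2 × mean observed entry) in the update denominators — factor
directions touched only by masked entries are otherwise unconstrained and
can diverge. Rank selection masks 5% of entries at random, fits, and scores
held-out mean squared reconstruction error, averaged over 5 independent
masks (shared across candidate ranks) to stabilize the curve; the arg-min
rank is refit on the full matrix. Cluster assignment is arg-max over the
feature-loading factor. On mixture data the MSE curve flattens once the
generating structure is captured, so the arg-min can sit anywhere on the
plateau; the informative feature is the elbow. Outlier curation is an
explicit blacklist file, keeping irreproducible judgment auditable.

## Proteomics processing

Contaminant propagation is single-hop: proteins sharing an observed peptide
with a listed contaminant are removed, but not proteins sharing peptides
with those shadows. knn imputation (k = 10) works in sum-normalized space;
distances between a target and candidate neighbors are Euclidean on the
*shared observed support with both rows renormalized over that support*
(rescaled by shared-channel count). Observed-sum normalization alone is not
comparable across missingness patterns: a row overlapping the target only on
uninformative channels can sit at exact distance 0 while a truly identical
complete row sits at ~1e-16, so distances are quantized at 1e-9 and ties
broken toward neighbors with larger shared support. The fill is the mean of
the k nearest neighbors' values renormalized to the target's observed
channel set; de-normalization restores observed entries exactly. Median
centering is divisive (all channel medians equalized to their median);
divisive vs subtractive is nearly immaterial because profiles are
subsequently row-sum normalized. The outlier rule (median Euclidean distance
to protein siblings > 0.2 on row-normalized profiles) is applied literally,
including to 2-PSM proteins (both removed; the protein then fails the
≥2-PSM aggregation rule). Nuclear group splitting applies its three printed
thresholds in order, first match wins. The marker SVM is RBF with a
log-spaced C/γ grid (3-fold grid search per iteration, 50 stratified 80:20
iterations by default). Differential-localization posteriors are consumed
from a table; their Bayesian inference is out of scope.

## Penalized-regression protocol

The elastic-net protocol fixes: an 80:20 train/test split; 10 CV folds
precomputed once and reused for every α ∈ {0, 0.1, …, 1} (verified by fold
checksums); per-α geometric λ paths of 20 values spanning a 100× range below
the smallest all-zero λ (with α floored at 0.001 in the λ-max formula, as is
conventional for the ridge end); CV error = mean binomial deviance
(logistic) or MSE (linear); α chosen at the minimum mean CV error; λ by the
one-SE rule — the largest λ whose mean CV error is within one standard error
of the minimum. Predictors are standardized internally; coefficients are
returned on the original scale. Held-out performance is ROC AUC (logistic)
or MSE (linear). Gaussian paths use coordinate descent (scikit-learn
`enet_path`); binomial paths use warm-started saga at tolerance 1e-3 —
selection operates on CV-error differences well above that resolution. The
path length and tolerance are chosen so a full protocol run on a
2,000 × 50 problem completes in seconds-to-tens-of-seconds on one core.

## GAM and the stratified comparison

The membrane-retention smooth is a penalized cubic B-spline (12 basis
functions, knots at predictor quantiles) with a second-order difference
penalty plus a small identity share (1e-3 of the penalty trace) that also
shrinks the penalty null space — the "with shrinkage" behavior. λ is chosen
by GCV = n·RSS/(n − edf)² over a 41-point log grid spanning 1e-4–1e6.
Residuals (observed − fitted) measure stress-resistant membrane retention; a
planted retention offset is partially absorbed by the smooth (a 0.15 offset
on 10% of points recovers ≈ 0.13), which is inherent to residual-based
measures. The stratified comparison refits at the base fit's λ with an
unpenalized group column and forms an approximate F test on effective
degrees of freedom; its null p-values are approximately uniform (checked by
Kolmogorov–Smirnov over 200 null simulations).

## Feature construction

k-mer frequencies divide overlapping counts by the window count (len−k+1).
Upstream-AUG frame is measured from the annotated CDS start (distance
divisible by 3 ⇒ in frame). Codon, dinucleotide and wobble-base frequencies
come from the in-frame CDS; the codon-optimality column is a pluggable
per-transcript scalar, with a self-contained MILC implementation
(within-amino-acid log-ratio statistic with the (Σ(r_a−1))/L − 0.5 length
correction) as the default. Transcripts with cytosol proportion in
[1/3, 2/3) are excluded from the binary cytosolic model rather than coded 0
— only the two bands are defined. RBP columns keep binders with strictly
more targets than the cutoff, counted within the modeled universe. The
packaged default k-mer range for the assembled matrices is k ≤ 3; the
k-mer machinery itself supports any k, and the full k = 1–7 range is a
config choice that grows the design into the thousands of columns.

## Numerical conventions and degenerate inputs

Neighbor exclusion for lncRNAs uses the gap between nearest gene edges,
0-based half-open intervals, orientation from the lncRNA's strand; overlap
counts as distance 0. The refractive-index → iodixanol conversion implements
the instrument calibration `RI/0.83 − 10.111` exactly as printed; it zeroes
near a scale reading of 8.39, not near the physical refractive index of
water, i.e. RI is a refractometer scale value. Zero spike-in signal in a
fraction, all-zero profiles, empty marker classes, constant regression
responses, and constant group indicators raise informative errors; all-zero
profile rows are dropped with a logged count.

## Known limitations

- The deconvolution assumes marker mean profiles are condition-appropriate;
  compartments whose profile shifts between conditions (ER under UPR) must
  be excluded or re-anchored, as the density mode does.
- The intercept QC is only meaningful when the basis cannot nearly
  synthesize a flat profile; the simulator guarantees this, real bases
  should be checked (the basis reports its condition number).
- NNMF rank selection is reliable for cluster-structured matrices; on heavy
  mixtures the imputation-MSE curve plateaus and the arg-min is weakly
  determined beyond the elbow.
- Bootstrap intervals reflect marker-sampling uncertainty only, not counting
  noise in the transcript's own profile.
- The proteomics SVM and the differential-localization tiering operate on
  the supplied probability tables and marker sets; no attempt is made to
  model co-fractionating complexes.
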