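# subloc

Proportional subcellular localization of transcripts and proteins from
density-gradient fractionation profiles.

Cells distribute each RNA species across compartments — nucleus, nucleolus,
cytosol, RNP granules, ER/mitochondrial membranes — and most transcripts live
in several at once. After equilibrium density centrifugation, a molecule's
relative abundance across the gradient fractions (its *profile*) is a
signature of where it resides. `subloc` turns such profiles into per-molecule
**localization proportions**, and models what drives their redistribution
under stress (the unfolded protein response, UPR).

## The model

Let `x ∈ R^F` be a transcript's row-normalized profile over `F` gradient
fractions, and `b_l` the mean row-normalized profile of the marker
transcripts of localization `l`. The proportions `p_l` are estimated by
non-negative least squares with a sign-free intercept:

```
x ≈ Σ_l p_l · b_l + c · 1,     p_l ≥ 0
```

A fit is kept when `R² ≥ 0.90` and `|c| ≤ 0.05`; passing replicates are
averaged when at least 2 of 3 agree to report a feature, and marker-resampling
bootstrap intervals (B = 100) quantify uncertainty. The 13 mitochondrially
encoded mRNAs never leave the mitochondrion, so their mean profile anchors
100% membrane localization. Before fitting, raw TPMs are converted to
absolute per-fraction abundances using spike-ins added at a fixed amount per
fraction: `content_f ∝ (endogenous_f / spikein_f) / proportion_used_f`.

Around this core the package provides:

- a **synthetic fractionation simulator** (`subloc.synthetic`) with known
  ground-truth proportions, negative-binomial counting noise, spike-ins,
  per-fraction RNA content differences, UPR granule relocalization, and
  PSM-level TMT tables with planted contaminants, outliers and missingness;
- **marker discovery** (`subloc.markers`): a priori evidence rules plus
  semi-supervised NNMF whose rank is selected by held-out-entry imputation
  error, cluster→marker expansion, and the novel-cluster route by which an
  unanticipated profile class ("cytosol light" / granules) is found;
- **proteomics processing** (`subloc.proteomics`): contaminant propagation
  through shared peptides, PSM filters, knn imputation in sum-normalized
  space, median-distance outlier removal, median centering, ≥2-PSM protein
  aggregation, marker-trained SVM classification, and tiered
  differential-localization calls from posterior probability tables;
- **feature models** (`subloc.features`, `subloc.glmnet`, `subloc.gam`):
  k-mer/codon/length/RBP feature construction, the elastic-net protocol
  (α grid 0–1 in steps of 0.1, shared precomputed folds, one-standard-error
  λ), and a penalized cubic-spline GAM whose residuals measure UPR-resistant
  membrane retention.

## Worked example

```python
import numpy as np
from subloc import (SimulationConfig, simulate_rna_experiment,
                    estimate_content_by_sample, rescale_to_endogenous,
                    normalize_profiles, build_marker_basis,
                    estimate_proportions)

cfg = SimulationConfig(n_transcripts=600, seed=1)
ds = simulate_rna_experiment(cfg)
content = estimate_content_by_sample(ds.rna_profiles, ds.spikeins)
endo = rescale_to_endogenous(ds.rna_profiles, ds.spikeins)
norm = normalize_profiles(endo, content)
basis = build_marker_basis(norm.data[norm.data.condition == "control"],
                           ds.marker_sets, mode="sedimentation")

fid = "t_155"
row = norm.data.query("feature_id == @fid and condition == 'control' "
                      "and replicate == 1")
est = estimate_proportions(row[norm.fraction_cols].to_numpy()[0], basis,
                           feature_id=fid)
print({k: round(v, 3) for k, v in est.proportions.items()},
      round(est.r_squared, 4))
```

prints

```
{'nucleus': 0.666, 'nucleolus': 0.0, 'cytosol': 0.0, 'cytosol_light': 0.0,
 'membrane': 0.007, 'er': 0.327} 1.0
```

— transcript `t_155` is about two-thirds nuclear and one-third ER-associated,
and the mixture explains essentially all of its profile variance (its
simulated truth is nucleus 0.673, er 0.318, membrane 0.009).

The numbered drivers under `analysis/` run the full study on simulated data:
`01_simulate` → `02_normalize` → `03_markers` → `04_deconvolve` →
`05_proteomics` → `06_feature_models`, writing summary tables under
`results/` (bulky raw tables go to `scratch/`).

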