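#!/usr/bin/env python
"""Semi-supervised marker discovery on the normalized profiles.

Runs imputation-based NNMF rank selection on the control-condition profiles,
maps clusters to a priori marker seeds (a subset of the simulator's marker
transcripts, mimicking independently derived evidence), expands each seed set
to its best-overlap cluster, and reports any unclaimed cluster — the route by
which a novel profile class (cytosol light / granule) is discovered.
"""

from pathlib import Path

import pandas as pd

from subloc import (
    MarkerSet,
    SimulationConfig,
    estimate_content_by_sample,
    map_clusters_to_apriori,
    normalize_profiles,
    rescale_to_endogenous,
    select_k_by_imputation,
    simulate_rna_experiment,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    cfg = SimulationConfig(n_transcripts=1200, seed=SEED)
    ds = simulate_rna_experiment(cfg)
    content = estimate_content_by_sample(ds.rna_profiles, ds.spikeins)
    endo = rescale_to_endogenous(ds.rna_profiles, ds.spikeins)
    norm = normalize_profiles(endo, content)

    ctrl = norm.data[(norm.data.condition == "control")
                     & (norm.data.replicate == 1)
                     & (norm.data.biotype != "background")]
    frac = [c for c in ctrl.columns if c.startswith("fraction_")]
    X = ctrl[frac].to_numpy()
    ids = list(ctrl.feature_id)

    n_loc = len(cfg.localizations)
    model = select_k_by_imputation(
        X, k_candidates=list(range(2, n_loc + 3)), seed=SEED,
        feature_ids=ids,
    )
    print("imputation MSE per candidate rank:")
    for k, mse in sorted(model.imputation_mse.items()):
        marker = " <- selected" if k == model.rank else ""
        print(f"  k={k}: {mse:.3e}{marker}")

    # a priori seeds: half of each simulated marker class, cytosol-light
    # deliberately left unseeded so it must surface as a novel cluster
    apriori = MarkerSet("transcript", {
        loc: members[:10]
        for loc, members in ds.marker_sets.items()
        if loc != cfg.granule_localization
    })
    expanded, novel = map_clusters_to_apriori(model, apriori)
    print("(the MSE curve flattens once the generating structure is "
          "captured; the arg-min can sit anywhere on that plateau)")
    print(f"expanded marker classes: "
          f"{ {loc: len(m) for loc, m in expanded.members.items()} }")
    print(f"novel (unclaimed) clusters: "
          f"{ {c: len(m) for c, m in novel.items()} }")
    granule_markers = set(ds.marker_sets[cfg.granule_localization])
    best_novel = {c: len(granule_markers & set(m)) for c, m in novel.items()}
    if best_novel:
        c = max(best_novel, key=best_novel.get)
        print(f"novel cluster {c} holds {best_novel[c]}/"
              f"{len(granule_markers)} of the unseeded granule markers — "
              "the cytosol-light discovery route")

    RESULTS.mkdir(exist_ok=True)
    expanded.to_frame().to_csv(RESULTS / "markers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"cluster": c, "member_id": m} for c, ms in novel.items()
         for m in ms]
    ).to_csv(RESULTS / "novel_clusters.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
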