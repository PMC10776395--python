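"""PSM processing rules, marker SVM, and differential-localization tiers."""

import numpy as np
import pandas as pd
import pytest

from subloc import (
    aggregate_proteins,
    assign_localization,
    call_differential_localization,
    classify_markers_svm,
    filter_psms,
    impute_knn,
    median_center,
    remove_contaminants,
    remove_outlier_psms,
    select_exclusive_nuclear,
    split_nuclear_groups,
)
from subloc.proteomics import channel_columns


def _psm_frame(rows):
    recs = []
    for psm_id, prot, pep, unique, channels in rows:
        recs.append({"psm_id": psm_id, "master_protein": prot,
                     "peptide_seq": pep, "unique_flag": unique,
                     **{f"channel_{i+1}": float(v)
                        for i, v in enumerate(channels)}})
    return pd.DataFrame(recs)


class TestContaminantRemoval:
    TABLE = _psm_frame([
        ("p1", "CRAP_1", "PEPX", True, [1, 1, 1, 1]),
        ("p2", "protA", "PEPX", True, [2, 2, 2, 2]),   # shares PEPX
        ("p3", "protA", "PEPY", True, [2, 2, 2, 2]),   # same protein
        ("p4", "protB", "PEPZ", True, [3, 3, 3, 3]),
    ])

    def test_listed_and_shadow_proteins_removed(self):
        out, report = remove_contaminants(self.TABLE, {"CRAP_1"})
        assert set(out.master_protein) == {"protB"}
        assert report.set_index("reason").loc["listed_contaminant",
                                              "n_psms_removed"] == 1
        assert report.set_index("reason").loc["shared_peptide",
                                              "n_psms_removed"] == 2

    def test_protein_sharing_no_peptides_retained(self):
        out, _ = remove_contaminants(self.TABLE, {"CRAP_1"})
        assert "p4" in set(out.psm_id)


class TestPsmFilter:
    def test_missing_share_rules(self):
        nan = np.nan
        table = _psm_frame([
            ("a", "p", "x", True, [1, 1, 1, 1, 1, 1, 1, nan, nan, nan]),
            ("b", "p", "y", True, [1, 1, 1, 1, 1, 1, 1, 1, nan, nan]),
            ("c", "p", "z", False, [1] * 10),
        ])
        out = filter_psms(table)
        assert set(out.psm_id) == {"b"}  # 30% removed, 20% kept, non-unique out


class TestKnnImputation:
    def test_identical_neighbors_reproduce_value(self):
        rows = [(f"n{i}", f"p{i}", f"x{i}", True, [9, 1]) for i in range(10)]
        rows.append(("t", "pt", "xt", True, [9, np.nan]))
        out = impute_knn(_psm_frame(rows), k=10)
        target = out[out.psm_id == "t"]
        # normalized profile of neighbors is (0.9, 0.1); in the target's
        # renormalized full profile the imputed channel reads 0.1
        full = target[["channel_1", "channel_2"]].to_numpy()[0]
        assert full[1] / full.sum() == pytest.approx(0.1)

    def test_complete_rows_unchanged(self):
        table = _psm_frame([("a", "p", "x", True, [1, 2, 3, 4]),
                            ("b", "q", "y", True, [4, 3, 2, 1])])
        out = impute_knn(table, k=1)
        pd.testing.assert_frame_equal(out, table)

    def test_two_row_toy_matches_hand_computation(self):
        # neighbor (2, 6, 2) normalized (0.2, 0.6, 0.2); target observes
        # (3, nan, 3) with observed total 6; neighbor's value renormalized to
        # the target's observed set is 6/4 = 1.5 -> de-normalized 1.5*6 = 9
        table = _psm_frame([("n", "p", "x", True, [2, 6, 2]),
                            ("t", "q", "y", True, [3, np.nan, 3])])
        with pytest.warns(UserWarning):  # fewer than k neighbors
            out = impute_knn(table, k=10)
        got = out.loc[out.psm_id == "t", "channel_2"].iloc[0]
        assert got == pytest.approx(9.0)

    def test_observed_entries_restored_exactly(self):
        rng = np.random.default_rng(0)
        rows = [(f"r{i}", f"p{i % 4}", f"x{i}", True,
                 list(rng.uniform(1, 10, 6))) for i in range(30)]
        table = _psm_frame(rows)
        cols = channel_columns(table)
        holed = table.copy()
        holed.loc[3, "channel_2"] = np.nan
        holed.loc[7, "channel_5"] = np.nan
        out = impute_knn(holed, k=5)
        mask = ~holed[cols].isna()
        np.testing.assert_array_equal(out[cols].to_numpy()[mask.to_numpy()],
                                      table[cols].to_numpy()[mask.to_numpy()])


class TestOutlierRemoval:
    def test_displaced_psm_removed(self):
        base = [1, 1, 1, 1]
        far = [4, 0, 0, 0]
        table = _psm_frame(
            [(f"a{i}", "p", f"x{i}", True, base) for i in range(4)]
            + [("out", "p", "xo", True, far)]
        )
        out, removed = remove_outlier_psms(table)
        assert set(removed.psm_id) == {"out"}

    def test_tight_cluster_untouched(self):
        rng = np.random.default_rng(1)
        table = _psm_frame([
            (f"a{i}", "p", f"x{i}", True,
             list(np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.005, 4)))
            for i in range(5)
        ])
        out, removed = remove_outlier_psms(table)
        assert removed.empty

    def test_two_mutually_distant_psms_both_removed(self):
        table = _psm_frame([("a", "p", "x", True, [1, 0, 0, 0]),
                            ("b", "p", "y", True, [0.7, 0.3, 0, 0])])
        # normalized distance = ||(1,0)-(0.7,0.3)||*sqrt(2) ... > 0.2
        out, removed = remove_outlier_psms(table)
        assert set(removed.psm_id) == {"a", "b"}
        assert out.empty


class TestMedianCentering:
    def test_channel_medians_equalized(self):
        rng = np.random.default_rng(0)
        table = _psm_frame([
            (f"a{i}", "p", f"x{i}", True, list(rng.uniform(1, 5, 3)
                                               * [1, 2, 4]))
            for i in range(9)
        ])
        out = median_center(table)
        med = out[channel_columns(out)].median()
        assert med.max() - med.min() < 1e-9

    def test_already_equal_medians_unchanged(self):
        table = _psm_frame([("a", "p", "x", True, [1, 2, 3]),
                            ("b", "q", "y", True, [3, 2, 1]),
                            ("c", "r", "z", True, [2, 2, 2])])
        out = median_center(table)
        cols = channel_columns(table)
        np.testing.assert_allclose(out[cols].to_numpy(),
                                   table[cols].to_numpy(), atol=1e-12)

    def test_single_psm_table(self):
        table = _psm_frame([("a", "p", "x", True, [1.0, 2.0, 4.0])])
        out = median_center(table)
        med = out[channel_columns(out)].median()
        assert med.max() - med.min() < 1e-12

    def test_zero_median_rejected(self):
        table = _psm_frame([("a", "p", "x", True, [0.0, 2.0]),
                            ("b", "q", "y", True, [0.0, 2.0])])
        with pytest.raises(ValueError):
            median_center(table)


class TestProteinAggregation:
    def test_single_psm_protein_absent(self):
        table = _psm_frame([("a", "p1", "x", True, [1, 1]),
                            ("b", "p2", "y", True, [1, 1]),
                            ("c", "p2", "z", True, [1, 1])])
        out = aggregate_proteins(table)
        assert set(out.protein_id) == {"p2"}

    def test_two_identical_psms_give_psm_profile(self):
        table = _psm_frame([("a", "p", "x", True, [2, 6, 2]),
                            ("b", "p", "y", True, [2, 6, 2])])
        out = aggregate_proteins(table)
        np.testing.assert_allclose(
            out[channel_columns(out)].to_numpy()[0], [0.2, 0.6, 0.2]
        )

    def test_complementary_psms_sum_then_normalize(self):
        table = _psm_frame([("a", "p", "x", True, [1, 1, 0, 0]),
                            ("b", "p", "y", True, [0, 0, 1, 1])])
        out = aggregate_proteins(table)
        np.testing.assert_allclose(
            out[channel_columns(out)].to_numpy()[0], [0.25] * 4
        )

    def test_scale_invariance_of_normalized_profiles(self):
        table = _psm_frame([("a", "p", "x", True, [1, 2, 3, 4]),
                            ("b", "p", "y", True, [2, 4, 6, 8])])
        scaled = table.copy()
        cols = channel_columns(table)
        scaled.loc[0, cols] = scaled.loc[0, cols] * 13.7
        a = aggregate_proteins(impute_knn(table, k=1))
        b = aggregate_proteins(impute_knn(scaled, k=1))
        # both PSMs share one profile; scaling one by a constant shifts the
        # weighting but the normalized protein profile stays the same shape
        np.testing.assert_allclose(a[cols].to_numpy(), b[cols].to_numpy(),
                                   atol=1e-12)


class TestSvmClassification:
    @staticmethod
    def _profiles(n_per_class, classes, noise, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for ci, cls in enumerate(classes):
            center = np.zeros(len(classes))
            center[ci] = 1.0
            for i in range(n_per_class):
                prof = np.abs(center + rng.normal(0, noise, len(classes)))
                prof = prof / prof.sum()
                recs.append({"protein_id": f"{cls}_{i}",
                             **{f"channel_{j+1}": v
                                for j, v in enumerate(prof)}})
        return pd.DataFrame(recs)

    def test_separable_classes_give_perfect_f1(self):
        classes = ["a", "b", "c"]
        prof = self._profiles(10, classes, noise=0.01)
        markers = {c: [f"{c}_{i}" for i in range(8)] for c in classes}
        res = classify_markers_svm(prof, markers, iterations=5, seed=0)
        assert (res.f1_scores[classes].to_numpy() == 1.0).all()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        classes = ["a", "b", "c", "d", "e"]
        prof = self._profiles(12, classes, noise=0.01)
        ids = list(prof.protein_id)
        shuffled = rng.permutation(ids)
        markers = {c: [shuffled[i] for i in range(ci * 12, ci * 12 + 12)]
                   for ci, c in enumerate(classes)}
        res = classify_markers_svm(prof, markers, iterations=10, seed=1)
        mean_f1 = res.f1_scores[classes].to_numpy().mean()
        assert mean_f1 < 0.4  # chance is 0.2 for five balanced classes

    def test_seed_reproducibility(self):
        classes = ["a", "b"]
        prof = self._profiles(10, classes, noise=0.1)
        markers = {c: [f"{c}_{i}" for i in range(10)] for c in classes}
        r1 = classify_markers_svm(prof, markers, iterations=5, seed=4)
        r2 = classify_markers_svm(prof, markers, iterations=5, seed=4)
        pd.testing.assert_frame_equal(r1.f1_scores, r2.f1_scores)

    def test_small_class_rejected(self):
        prof = self._profiles(3, ["a", "b"], noise=0.01)
        markers = {"a": ["a_0", "a_1", "a_2"], "b": ["b_0", "b_1", "b_2"]}
        with pytest.raises(ValueError, match="a"):
            classify_markers_svm(prof, markers)


class TestNuclearSelection:
    SCORES = pd.DataFrame({
        "protein_id": ["n1", "n2", "n3"],
        "Nucleus": [5, 5, 4],
        "Cytosol": [2, 3, 0],
        "ER": [0, 0, 0],
    })

    def test_exclusive_rule(self):
        assert select_exclusive_nuclear(self.SCORES) == ["n1"]

    def test_group_split_first_match_wins(self):
        prof = pd.DataFrame({
            "protein_id": ["g1", "g2", "g3", "g4"],
            **{f"channel_{i+1}": [0.05] * 4 for i in range(8)},
        })
        prof.loc[0, "channel_4"] = 0.35                  # group 1
        prof.loc[1, ["channel_4", "channel_5"]] = [0.1, 0.25]  # group 2
        prof.loc[2, "channel_8"] = 0.45                  # group 3
        groups = split_nuclear_groups(prof, ["g1", "g2", "g3", "g4"])
        assert groups["group_1"] == ["g1"]
        assert groups["group_2"] == ["g2"]
        assert groups["group_3"] == ["g3"]
        assert groups["unassigned"] == ["g4"]


class TestDifferentialLocalization:
    @pytest.mark.parametrize(
        "p_loc, p_out, expected",
        [
            (0.99, 0.0, "assigned"),
            (0.98, 0.04, "undefined"),  # 0.9408 <= 0.95
            (1.0, 0.0, "assigned"),
            (0.96, 0.0, "assigned"),
            (0.95, 0.0, "undefined"),   # strict inequality
        ],
    )
    def test_assignment_product_rule(self, p_loc, p_out, expected):
        got = assign_localization(p_loc, p_out, "ER")
        assert got == ("ER" if expected == "assigned" else "undefined")

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            assign_localization(1.2, 0.0, "ER")

    @staticmethod
    def _calls(p_dl, loc_a="ER", loc_b="Golgi"):
        rows = []
        for rep, p in enumerate(p_dl, start=1):
            for cond, loc in (("control", loc_a), ("upr", loc_b)):
                rows.append({"protein": "P", "replicate": rep,
                             "condition": cond, "localization": loc,
                             "p_loc": 1.0, "p_out": 0.0, "p_dl": p})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "p_dl, tier",
        [
            ((0.991, 0.992, 0.80), "highly_confident"),
            ((0.96, 0.96, 0.10), "confident"),
            ((0.86, 0.86, 0.10), "candidate"),
            ((0.86, 0.10, 0.10), "none"),
        ],
    )
    def test_tiering_two_thirds_rule(self, p_dl, tier):
        out = call_differential_localization(self._calls(p_dl))
        assert out.loc[0, "tier"] == tier

    def test_same_localization_in_both_conditions_blocks_call(self):
        out = call_differential_localization(
            self._calls((0.999, 0.999, 0.999), loc_a="ER", loc_b="ER")
        )
        assert out.loc[0, "tier"] == "none"
        assert not out.loc[0, "never_same_localization"]


class TestSvmOnSimulatedProteins:
    def test_macro_f1_high_at_default_noise(self, ):
        from subloc import SimulationConfig, simulate_psm_table
        from subloc.proteomics import process_psm_pipeline

        cfg = SimulationConfig(n_proteins=400, seed=7)  # default psm noise
        psm, truth, psm_truth = simulate_psm_table(cfg)
        proteins = process_psm_pipeline(
            psm, psm_truth["contaminant_ids"]
        )["proteins"]
        t = truth.set_index("protein_id")
        markers = {
            loc: [p for p in sub.index if p in set(proteins.protein_id)]
            for loc, sub in t[t.is_marker & ~t.is_contaminant]
            .groupby("localization")
        }
        res = classify_markers_svm(proteins, markers, iterations=10, seed=0)
        classes = [c for c in res.f1_scores.columns if c != "iteration"]
        assert res.f1_scores[classes].to_numpy().mean() >= 0.9
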