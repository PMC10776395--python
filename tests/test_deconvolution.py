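"""NNLS deconvolution: exact mixtures, QC, bootstrap, enrichment conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subloc import (
    MarkerBasis,
    ProfileTable,
    average_replicates,
    bootstrap_proportions,
    build_marker_basis,
    deconvolve_table,
    estimate_proportions,
    normalize_proportions,
    proportion_to_enrichment,
    relocalization_delta,
)


def _profiles_frame(rows: dict[str, list[float]]):
    n_frac = len(next(iter(rows.values())))
    recs = []
    for fid, vals in rows.items():
        recs.append({"feature_id": fid, "biotype": "protein_coding",
                     "condition": "control", "replicate": 1,
                     **{f"fraction_{i+1}": v for i, v in enumerate(vals)}})
    return pd.DataFrame(recs)


class TestMarkerBasis:
    def test_single_marker_class_rows_equal_profiles(self):
        df = _profiles_frame({"m1": [1, 0, 0, 0], "m2": [0, 0, 0.5, 0.5]})
        basis = build_marker_basis(df, {"A": ["m1"], "B": ["m2"]},
                                   mode="sedimentation")
        np.testing.assert_allclose(basis.matrix,
                                   [[1, 0, 0, 0], [0, 0, 0.5, 0.5]])

    def test_identical_markers_mean_is_either(self):
        df = _profiles_frame({"m1": [0.5, 0.5, 0, 0], "m2": [0.5, 0.5, 0, 0]})
        basis = build_marker_basis(df, {"A": ["m1", "m2"]},
                                   mode="sedimentation")
        np.testing.assert_allclose(basis.matrix, [[0.5, 0.5, 0, 0]])

    def test_mean_of_two_profiles(self):
        df = _profiles_frame({"m1": [1, 0, 0, 0], "m2": [0.8, 0.2, 0, 0]})
        basis = build_marker_basis(df, {"A": ["m1", "m2"]},
                                   mode="sedimentation")
        np.testing.assert_allclose(basis.matrix, [[0.9, 0.1, 0, 0]])

    def test_density_mode_drops_er_and_relabels_mitochondria(self):
        df = _profiles_frame({
            "m1": [1, 0, 0, 0], "e1": [0, 1, 0, 0], "c1": [0, 0, 1, 0],
        })
        basis = build_marker_basis(
            df, {"mitochondria": ["m1"], "er": ["e1"], "cytosol": ["c1"]},
            mode="density",
        )
        assert "er" not in basis.localizations
        assert "membrane" in basis.localizations
        assert basis.membrane_reference == "membrane"

    def test_empty_class_rejected(self):
        df = _profiles_frame({"m1": [1, 0, 0, 0]})
        with pytest.raises(ValueError, match="empty"):
            build_marker_basis(df, {"A": []}, mode="sedimentation")


class TestEstimateProportions:
    BASIS = MarkerBasis(["A", "B"],
                        np.array([[1, 0, 0, 0], [0, 0, 0.5, 0.5]]))

    def test_exact_mixture_recovered(self):
        profile = 0.4 * np.array([1, 0, 0, 0]) + 0.6 * np.array([0, 0, .5, .5])
        est = estimate_proportions(profile, self.BASIS)
        assert est.proportions["A"] == pytest.approx(0.4, abs=1e-9)
        assert est.proportions["B"] == pytest.approx(0.6, abs=1e-9)
        assert est.intercept == pytest.approx(0.0, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-9)
        assert est.qc_pass

    def test_pure_basis_row_gives_proportion_one(self):
        est = estimate_proportions(np.array([0, 0, 0.5, 0.5]), self.BASIS)
        assert est.proportions == pytest.approx({"A": 0.0, "B": 1.0},
                                                abs=1e-9)

    def test_off_basis_profile_fails_qc_and_matches_grid_oracle(self):
        profile = np.array([0.0, 1.0, 0.0, 0.0])
        est = estimate_proportions(profile, self.BASIS)
        assert not est.qc_pass and est.r_squared < 0.90
        # brute-force oracle over (p_A, p_B, c)
        grid = np.linspace(0, 1.5, 151)
        cgrid = np.linspace(-0.5, 0.5, 201)
        best = None
        B = self.BASIS.matrix
        for pa in grid:
            for pb in grid:
                resid = profile - pa * B[0] - pb * B[1]
                # optimal c in closed form given (pa, pb)
                c = resid.mean()
                rss = np.sum((resid - c) ** 2)
                if best is None or rss < best[0]:
                    best = (rss, pa, pb, c)
        _, pa, pb, c = best
        assert est.proportions["A"] == pytest.approx(pa, abs=0.01)
        assert est.proportions["B"] == pytest.approx(pb, abs=0.01)
        assert est.intercept == pytest.approx(c, abs=0.01)

    def test_random_mixtures_match_grid_oracle_three_classes(self):
        rng = np.random.default_rng(0)
        basis = MarkerBasis(
            ["A", "B", "C"],
            np.array([[0.7, 0.3, 0, 0], [0, 0.2, 0.8, 0], [0, 0, 0.1, 0.9]]),
        )
        grid = np.linspace(0, 1.2, 61)  # resolution 0.02
        for _ in range(5):
            w = rng.dirichlet([1, 1, 1])
            profile = w @ basis.matrix + rng.normal(0, 0.02, 4)
            profile = np.clip(profile, 0, None)
            est = estimate_proportions(profile, basis)
            best = None
            for pa in grid:
                for pb in grid:
                    for pc in grid:
                        resid = (profile - pa * basis.matrix[0]
                                 - pb * basis.matrix[1] - pc * basis.matrix[2])
                        c = resid.mean()
                        rss = np.sum((resid - c) ** 2)
                        if best is None or rss < best[0]:
                            best = (rss, pa, pb, pc)
            best_rss, pa, pb, pc = best
            got = est.proportions
            # the NNLS solution must be at least as good as the best grid
            # point, and agree with it to within the grid resolution
            resid = (profile
                     - got["A"] * basis.matrix[0]
                     - got["B"] * basis.matrix[1]
                     - got["C"] * basis.matrix[2] - est.intercept)
            assert np.sum(resid ** 2) <= best_rss + 1e-9
            assert got["A"] == pytest.approx(pa, abs=0.04)
            assert got["B"] == pytest.approx(pb, abs=0.04)
            assert got["C"] == pytest.approx(pc, abs=0.04)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            estimate_proportions(np.zeros(4), self.BASIS)


class TestMitochondrialReference:
    def test_membrane_marker_mean_deconvolves_to_one(self, noisy_dataset,
                                                     normalized_noisy):
        ds = noisy_dataset
        df = normalized_noisy.data
        basis = build_marker_basis(df[df.condition == "control"],
                                   ds.marker_sets, mode="sedimentation")
        i = basis.localizations.index("membrane")
        est = estimate_proportions(basis.matrix[i], basis)
        assert est.proportions["membrane"] == pytest.approx(1.0, abs=1e-6)
        for loc, p in est.proportions.items():
            if loc != "membrane":
                assert p == pytest.approx(0.0, abs=1e-6)


class TestBootstrap:
    def test_identical_markers_give_zero_width(self):
        df = _profiles_frame({
            "a1": [1, 0, 0, 0], "a2": [1, 0, 0, 0],
            "b1": [0, 0, 0.5, 0.5], "b2": [0, 0, 0.5, 0.5],
        })
        markers = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        out = bootstrap_proportions(np.array([0.5, 0, 0.25, 0.25]), df,
                                    markers, B=25, seed=0,
                                    mode="sedimentation")
        assert (out.boot_upper - out.boot_lower).abs().max() < 1e-12

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        rows = {f"a{i}": list(np.abs(rng.normal(1, 0.1, 4))) for i in range(4)}
        rows.update({f"b{i}": list(np.abs(rng.normal([0, 0, 1, 1], 0.1)))
                     for i in range(4)})
        df = _profiles_frame(rows)
        markers = {"A": [f"a{i}" for i in range(4)],
                   "B": [f"b{i}" for i in range(4)]}
        x = np.array([0.4, 0.1, 0.25, 0.25])
        a = bootstrap_proportions(x, df, markers, B=50, seed=3,
                                  mode="sedimentation")
        b = bootstrap_proportions(x, df, markers, B=50, seed=3,
                                  mode="sedimentation")
        pd.testing.assert_frame_equal(a, b)

    def test_interval_covers_point_estimate(self, noisy_dataset,
                                            normalized_noisy):
        ds = noisy_dataset
        df = normalized_noisy.data
        ctrl = df[df.condition == "control"]
        basis = build_marker_basis(ctrl, ds.marker_sets, mode="sedimentation")
        frac = [c for c in ctrl.columns if c.startswith("fraction_")]
        rng = np.random.default_rng(0)
        rows = ctrl[ctrl.biotype == "protein_coding"].sample(
            20, random_state=7
        )
        covered = 0
        total = 0
        for _, row in rows.iterrows():
            x = row[frac].to_numpy(dtype=float)
            est = estimate_proportions(x, basis)
            boot = bootstrap_proportions(x, ctrl, ds.marker_sets, B=100,
                                         seed=11, mode="sedimentation")
            boot = boot.set_index("localization")
            for loc, p in est.proportions.items():
                total += 1
                lo = boot.loc[loc, "boot_lower"] - 1e-9
                hi = boot.loc[loc, "boot_upper"] + 1e-9
                covered += lo <= p <= hi
        assert covered / total >= 0.95

    def test_invalid_b_rejected(self):
        df = _profiles_frame({"a": [1, 0, 0, 0]})
        with pytest.raises(ValueError):
            bootstrap_proportions(np.array([1, 0, 0, 0]), df, {"A": ["a"]},
                                  B=0)


class TestReplicateAveraging:
    @staticmethod
    def _estimates(qc, values):
        return pd.DataFrame({
            "feature_id": ["t"] * 3,
            "condition": ["control"] * 3,
            "replicate": [1, 2, 3],
            "qc_pass": qc,
            "A": values,
        })

    def test_two_of_three_passing_averaged(self):
        out = average_replicates(
            self._estimates([True, True, False], [0.2, 0.4, 0.9]), ["A"]
        )
        assert out.loc[0, "A"] == pytest.approx(0.3)
        assert out.loc[0, "replicates_used"] == 2

    def test_single_passing_replicate_dropped(self):
        out = average_replicates(
            self._estimates([True, False, False], [0.2, 0.4, 0.9]), ["A"]
        )
        assert out.empty

    def test_normalized_view_sums_to_one(self):
        table = pd.DataFrame({"feature_id": ["t"], "condition": ["control"],
                              "A": [0.3], "B": [0.2]})
        out = normalize_proportions(table, ["A", "B"])
        assert out[["A", "B"]].sum(axis=1).iloc[0] == pytest.approx(1.0)


class TestRelocalizationDelta:
    def test_gain_and_loss(self):
        a = pd.DataFrame({"feature_id": ["t1", "t2", "t3"],
                          "granule": [0.1, 0.5, 0.9]})
        b = pd.DataFrame({"feature_id": ["t1", "t2", "t3"],
                          "granule": [0.4, 0.5, 0.2]})
        delta = relocalization_delta(a, b, "granule")
        assert delta["t1"] == pytest.approx(0.3)
        assert delta["t2"] == pytest.approx(0.0)
        assert delta["t3"] == pytest.approx(-0.7)

    def test_features_missing_in_one_condition_excluded(self):
        a = pd.DataFrame({"feature_id": ["t1", "t2"], "m": [0.9, 0.5]})
        b = pd.DataFrame({"feature_id": ["t1"], "m": [0.2]})
        delta = relocalization_delta(a, b, "m")
        assert list(delta.index) == ["t1"]
        assert delta["t1"] == pytest.approx(-0.7)


class TestEnrichmentConversion:
    @pytest.mark.parametrize("p, expected", [(0.5, 0.0), (0.8, 2.0),
                                             (0.2, -2.0)])
    def test_log2_odds(self, p, expected):
        assert proportion_to_enrichment(p) == pytest.approx(expected)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_about_half(self, p):
        assert proportion_to_enrichment(p) == pytest.approx(
            -proportion_to_enrichment(1 - p), rel=1e-9, abs=1e-9
        )

    @pytest.mark.parametrize("bad", [1.0, -0.1, 1.5])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            proportion_to_enrichment(bad)


class TestEndToEndIdentity:
    def test_noiseless_pipeline_returns_truth(self, noiseless_dataset,
                                              normalized_noiseless):
        ds = noiseless_dataset
        df = normalized_noiseless.data
        ctrl = df[(df.condition == "control") & (df.biotype != "background")]
        basis = build_marker_basis(ctrl, ds.marker_sets, mode="sedimentation")
        table = deconvolve_table(
            ProfileTable(ctrl.reset_index(drop=True), state="row_normalized"),
            basis,
        )
        truth = ds.true_proportions.query("condition == 'control'") \
            .set_index("feature_id")
        locs = basis.localizations
        merged = table.merge(truth[locs], left_on="feature_id",
                             right_index=True, suffixes=("", "_true"))
        err = np.abs(merged[locs].to_numpy()
                     - merged[[f"{l}_true" for l in locs]].to_numpy())
        assert err.max() < 1e-6
        assert merged.qc_pass.all()
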