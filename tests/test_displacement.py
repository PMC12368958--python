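import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from soilmerge import displacement as dis

from conftest import make_metadata


class TestComparisonPairs:
    def test_within_four_replicates_gives_six_pairs(self, two_condition_metadata):
        pairs = dis.build_comparison_pairs(two_condition_metadata, "A", mode="within")
        assert len(pairs) == 6
        assert len({p.label for p in pairs}) == 6

    def test_between_four_replicates_gives_four_pairs(self, two_condition_metadata):
        pairs = dis.build_comparison_pairs(
            two_condition_metadata, "A", "B", mode="between", seed=3
        )
        assert len(pairs) == 4
        # a bijection: each replicate used exactly once on each side
        assert sorted(p.replicate_a for p in pairs) == [1, 2, 3, 4]
        assert sorted(p.replicate_b for p in pairs) == [1, 2, 3, 4]

    def test_within_two_replicates_gives_one_pair(self):
        meta = make_metadata(["A"], n_replicates=2)
        assert len(dis.build_comparison_pairs(meta, "A", mode="within")) == 1

    def test_between_pairing_is_seeded(self, two_condition_metadata):
        p1 = dis.build_comparison_pairs(two_condition_metadata, "A", "B", "between", seed=1)
        p2 = dis.build_comparison_pairs(two_condition_metadata, "A", "B", "between", seed=1)
        assert p1 == p2

    def test_missing_condition_rejected(self, two_condition_metadata):
        with pytest.raises(ValueError, match="absent"):
            dis.build_comparison_pairs(two_condition_metadata, "Z", mode="within")


def _fit_with_sigma(n=100, sigma_resid=0.1, slope=1.0, intercept=0.0):
    """Fit a detector on a crafted cloud with known residual dispersion."""
    x = np.linspace(1, 4, n)
    resid = np.where(np.arange(n) % 2 == 0, 1.0, -1.0) * sigma_resid * np.sqrt((n - 2) / n)
    y = intercept + slope * x + resid
    model = dis.BaselineOutlierDetector().fit(np.column_stack([x, y]))
    return model


class TestBaselineOutlierDetector:
    def test_perfect_line_recovered_exactly(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        model = dis.BaselineOutlierDetector().fit(np.column_stack([x, x]))
        assert model.slope_ == pytest.approx(1.0)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-12)
        assert model.sigma_ == pytest.approx(0.0, abs=1e-12)

    def test_ols_matches_statsmodels(self):
        sm_api = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, 60)
        y = 2.0 + 1.3 * x + rng.normal(0, 0.3, 60)
        y[10] += 0.3  # a deliberate perturbation
        model = dis.BaselineOutlierDetector().fit(np.column_stack([x, y]))
        fit = sm_api.OLS(y, sm_api.add_constant(x)).fit()
        assert model.intercept_ == pytest.approx(fit.params[0])
        assert model.slope_ == pytest.approx(fit.params[1])
        assert model.sigma_ == pytest.approx(np.sqrt(fit.ssr / (60 - 2)))

    def test_monte_carlo_sigma_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 4, 500)
        y = 0.5 + x + rng.normal(0, 0.2, 500)
        model = dis.BaselineOutlierDetector().fit(np.column_stack([x, y]))
        assert model.sigma_ == pytest.approx(0.2, rel=0.1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            dis.BaselineOutlierDetector().fit(np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]]))
        with pytest.raises(ValueError):
            dis.BaselineOutlierDetector().fit(np.array([[1.0, 1.0], [2.0, 2.0]]))

    def test_sklearn_estimator_api(self):
        model = _fit_with_sigma()
        params = model.get_params()
        assert params == {"k_sigma": 3.0, "threshold_basis": "residual_sd"}
        clone(model)  # must not raise
        X = np.array([[2.0, 2.0], [2.0, 2.0 + 10 * model.sigma_]])
        assert model.predict(X).tolist() == [1, -1]
        assert model.decision_function(X)[0] > 0 > model.decision_function(X)[1]

    def test_prediction_se_band_widens_away_from_centre(self):
        model = dis.BaselineOutlierDetector(threshold_basis="prediction_se").fit(
            np.column_stack([np.linspace(0, 4, 50), np.linspace(0, 4, 50) + np.resize([0.1, -0.1], 50)])
        )
        t_centre = model.threshold(np.array([[2.0, 0.0]]))[0]
        t_edge = model.threshold(np.array([[6.0, 0.0]]))[0]
        assert t_edge > t_centre > 0


class TestDetectOutliers:
    def _pairs(self, model, residual_multiples):
        x = np.full(len(residual_multiples), 2.0)
        y = model.intercept_ + model.slope_ * x + model.sigma_ * np.asarray(
            residual_multiples
        )
        return pd.DataFrame(
            {
                "asv_id": [f"a{i}" for i in range(len(x))],
                "count_a": 10.0**x,
                "count_b": 10.0**y,
                "x": x,
                "y": y,
            }
        )

    def test_threshold_rule_and_direction(self):
        model = _fit_with_sigma(sigma_resid=0.1)
        pairs = self._pairs(model, [4.0, 2.0, -4.0, 0.0])
        out = dis.detect_outliers(pairs, model)
        assert out["asv_id"].tolist() == ["a0", "a2"]
        assert out["direction"].tolist() == ["enriched", "depleted"]
        # log2 fold change is the paired log10 difference rescaled to base 2
        assert out["log2_fold_change"].iloc[0] == pytest.approx(
            (out["y"].iloc[0] - out["x"].iloc[0]) / np.log10(2), rel=1e-6
        )

    def test_zero_sigma_flags_every_nonzero_residual_with_warning(self):
        x = np.linspace(1, 3, 10)
        model = dis.BaselineOutlierDetector().fit(np.column_stack([x, x]))
        pairs = self._pairs(model, [0.0])
        pairs.loc[0, "y"] += 0.01
        with pytest.warns(UserWarning, match="dispersion is 0"):
            out = dis.detect_outliers(pairs, model)
        assert len(out) == 1

    def test_null_flag_rate_near_three_sigma_expectation(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0.5, 4.5, 50_000)
        y = 0.1 + 0.95 * x + rng.normal(0, 0.25, len(x))
        model = dis.BaselineOutlierDetector().fit(np.column_stack([x, y])[:10_000])
        flagged = model.predict(np.column_stack([x, y])[10_000:]) == -1
        assert 0.001 < flagged.mean() < 0.005  # about 0.27% two-sided


class TestPairCommonASVs:
    def _counts_meta(self):
        meta = make_metadata(["A", "B"], n_replicates=2, days=(0,))
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(5, 50, size=(len(meta), 6)),
            index=meta.index,
            columns=[f"t{i}" for i in range(6)],
        )
        return counts, meta

    def test_identical_samples_fall_on_identity_line(self):
        counts, meta = self._counts_meta()
        counts.loc["B.r1.d0"] = counts.loc["A.r1.d0"]
        pair = dis.ReplicatePair("A", 1, "B", 1)
        depth = int(counts.loc["A.r1.d0"].sum())
        cfg = dis.DisplacementConfig(depth=depth)
        out = dis.pair_common_asvs(counts, meta, pair, 0, config=cfg)
        assert np.allclose(out["x"], out["y"])

    def test_asv_missing_on_one_side_is_excluded(self):
        counts, meta = self._counts_meta()
        counts.loc["A.r1.d0", "t0"] = 0
        pair = dis.ReplicatePair("A", 1, "B", 1)
        cfg = dis.DisplacementConfig(depth=int(counts.loc[["A.r1.d0", "B.r1.d0"]].sum(axis=1).min()))
        out = dis.pair_common_asvs(counts, meta, pair, 0, config=cfg)
        assert "t0" not in set(out["asv_id"])
        assert (out[["count_a", "count_b"]] >= 1).all().all()

    def test_exclusion_removes_only_member_asvs(self):
        counts, meta = self._counts_meta()
        pair = dis.ReplicatePair("A", 1, "B", 1)
        sub = counts.loc[["A.r1.d0", "B.r1.d0"]].drop(columns=["t5"])
        cfg = dis.DisplacementConfig(depth=int(sub.sum(axis=1).min()))
        out = dis.pair_common_asvs(counts, meta, pair, 0, exclude={"t5"}, config=cfg)
        assert "t5" not in set(out["asv_id"])
        # the min-depth sample is drawn exhaustively: its non-member counts
        # match the exclusion-free table exactly
        got = out.set_index("asv_id")
        if got["count_a"].sum() == sub.loc["A.r1.d0"].sum():
            side, sid = "count_a", "A.r1.d0"
        else:
            side, sid = "count_b", "B.r1.d0"
        for asv in got.index:
            assert got.loc[asv, side] == sub.loc[sid, asv]

    def test_too_few_common_asvs_rejected(self):
        counts, meta = self._counts_meta()
        counts.loc["A.r1.d0", ["t0", "t1", "t2", "t3"]] = 0
        pair = dis.ReplicatePair("A", 1, "B", 1)
        cfg = dis.DisplacementConfig(depth=int(counts.loc[["A.r1.d0", "B.r1.d0"]].sum(axis=1).min()))
        with pytest.raises(ValueError, match="common ASVs"):
            dis.pair_common_asvs(counts, meta, pair, 0, config=cfg)


class TestSummedDistance:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["comparison", "pair", "residual"])

    def test_absolute_sum_within_pair(self):
        rec = self._records(
            [("m", "p1", 0.5), ("m", "p1", -0.3), ("m", "p2", 0.1)]
        )
        out = dis.summed_outlier_distance(rec)
        d = out.set_index("pair")["distance"]
        assert d["p1"] == pytest.approx(0.8)
        assert d["p2"] == pytest.approx(0.1)

    def test_pairs_without_outliers_report_zero_and_medians(self):
        rec = self._records([("m", "p1", 0.5)])
        out = dis.summed_outlier_distance(rec, [("m", "p1"), ("m", "p2"), ("w", "q1")])
        d = out.set_index(["comparison", "pair"])["distance"]
        assert d[("m", "p2")] == 0.0 and d[("w", "q1")] == 0.0
        assert out.attrs["medians"]["m"] == pytest.approx(0.25)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        rows = [
            ("m", f"p{rng.integers(3)}", float(rng.normal()))
            for _ in range(30)
        ]
        a = dis.summed_outlier_distance(self._records(rows))
        b = dis.summed_outlier_distance(self._records(rows[::-1]))
        pd.testing.assert_frame_equal(
            a.sort_values("pair").reset_index(drop=True),
            b.sort_values("pair").reset_index(drop=True),
        )


class TestPhylumProfile:
    def _taxonomy(self):
        return pd.DataFrame(
            {"genus": ["g"] * 4, "phylum": ["P1", "P1", "P2", "P2"]},
            index=pd.Index(["a0", "a1", "a2", "a3"], name="asv_id"),
        )

    def test_mean_log2fc_per_phylum(self):
        rec = pd.DataFrame(
            {
                "asv_id": ["a0", "a1", "a2"],
                "day": [3.0, 3.0, 3.0],
                "log2_fold_change": [1.0, 3.0, -2.0],
                "direction": ["enriched", "enriched", "depleted"],
                "rel_abundance_b": [0.1, 0.2, 0.01],
            }
        )
        out = dis.outlier_phylum_profile(rec, self._taxonomy())
        by = out.set_index("phylum")
        assert by.loc["P1", "mean_log2_fold_change"] == pytest.approx(2.0)
        assert by.loc["P2", "mean_log2_fold_change"] == pytest.approx(-2.0)
        assert by.loc["P2", "n_depleted"] == 1 and by.loc["P2", "n_enriched"] == 0

    def test_depleted_only_phylum_is_all_negative(self):
        rec = pd.DataFrame(
            {
                "asv_id": ["a2", "a3", "a3"],
                "day": [3.0, 3.0, 7.0],
                "log2_fold_change": [-1.0, -4.0, -2.5],
                "direction": ["depleted"] * 3,
                "rel_abundance_b": [0.1, 0.2, 0.01],
            }
        )
        out = dis.outlier_phylum_profile(rec, self._taxonomy())
        assert (out["mean_log2_fold_change"] < 0).all()
        assert (out["n_enriched"] == 0).all()

    def test_missing_taxonomy_rejected(self):
        rec = pd.DataFrame(
            {
                "asv_id": ["zz"],
                "day": [3.0],
                "log2_fold_change": [1.0],
                "direction": ["enriched"],
                "rel_abundance_b": [0.1],
            }
        )
        with pytest.raises(KeyError, match="zz"):
            dis.outlier_phylum_profile(rec, self._taxonomy())
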