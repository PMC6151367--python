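"""The statistical battery: Friedman, COV classes, ICC, Mann-Whitney,
H_GS correlation, sphericity agreement and the report funnel."""

import numpy as np
import pandas as pd
import pytest

from petphantom.evaluation import (
    benjamini_hochberg,
    build_report,
    classify_cov,
    cov_stability,
    friedman_stability,
    heterogeneity_discrimination,
    hgs_correlation,
    icc_1_1,
    icc_3_1,
    icc_reproducibility,
    sphericity_agreement,
)


def _frame(arr, prefix="f"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"L{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestFriedman:
    def test_identical_values_stable(self):
        rng = np.random.default_rng(0)
        a = _frame(rng.random((10, 4)))
        p = friedman_stability({"adaptive": a, "fixed60": a.copy()})
        assert (p >= 0.05).all()

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        a = _frame(rng.standard_normal((12, 3)))
        b = a + 10.0  # ten standard deviations
        p = friedman_stability({"adaptive": a, "fixed60": b})
        assert (p < 0.05).all()

    def test_invariant_to_consistent_lesion_permutation(self):
        rng = np.random.default_rng(2)
        a = _frame(rng.random((8, 3)))
        b = _frame(rng.random((8, 3)))
        p1 = friedman_stability({"m1": a, "m2": b})
        perm = rng.permutation(8)
        p2 = friedman_stability({"m1": a.iloc[perm], "m2": b.iloc[perm]})
        assert np.allclose(p1.to_numpy(), p2.to_numpy())

    def test_three_methods_use_friedman_chi2(self):
        rng = np.random.default_rng(3)
        frames = {m: _frame(rng.random((10, 2))) for m in ("a", "b", "c")}
        p = friedman_stability(frames)
        assert ((p > 0) & (p <= 1)).all()

    def test_mismatched_lesions_rejected(self):
        a = _frame(np.random.default_rng(0).random((6, 2)))
        b = a.iloc[:5]
        with pytest.raises(ValueError, match="mismatched"):
            friedman_stability({"a": a, "b": b})


class TestCovStability:
    def test_class_boundaries_partition(self):
        assert classify_cov(0.0) == "stable"
        assert classify_cov(5.0) == "stable"
        assert classify_cov(5.0001) == "quite_stable"
        assert classify_cov(10.0) == "quite_stable"
        assert classify_cov(10.0001) == "poorly_stable"
        assert classify_cov(20.0) == "poorly_stable"
        assert classify_cov(20.0001) == "unstable"
        assert classify_cov(1e6) == "unstable"

    def test_reference_covs_map_to_the_four_classes(self):
        assert [classify_cov(c) for c in (4, 7, 15, 25)] == [
            "stable", "quite_stable", "poorly_stable", "unstable"
        ]

    def test_constant_feature_cov_zero(self):
        base = _frame(np.full((6, 2), 3.0))
        res = cov_stability({"matrix": {"a": base, "b": base.copy()}})
        assert (res.representative == 0).all()
        assert (res.stability_class == "stable").all()

    def test_representative_is_worst_family(self):
        rng = np.random.default_rng(4)
        lesions = np.abs(rng.random((5, 1))) + 1.0

        def family(rel_sd):
            return {
                "s1": _frame(lesions * (1 + rel_sd)),
                "s2": _frame(lesions * (1 - rel_sd)),
            }

        res = cov_stability({"fwhm": family(0.03), "matrix": family(0.09)})
        # population sd of {1+r, 1-r} is r: COVs 3% and ~9%
        assert res.per_family["fwhm"].iloc[0] == pytest.approx(3.0, abs=0.2)
        assert res.per_family["matrix"].iloc[0] == pytest.approx(9.0, abs=0.5)
        assert res.representative.iloc[0] == pytest.approx(
            res.per_family["matrix"].iloc[0]
        )
        assert res.quite_stable.iloc[0]

    def test_negative_mean_flagged_not_dropped(self):
        vals = np.full((4, 1), -2.0)
        fam = {"s1": _frame(vals * 1.05), "s2": _frame(vals * 0.95)}
        res = cov_stability({"alg": fam})
        assert res.negative_mean_flag.iloc[0]
        assert np.isfinite(res.representative.iloc[0])


class TestICC:
    def test_duplicated_data_gives_one(self):
        rng = np.random.default_rng(5)
        t = _frame(rng.random((10, 3)))
        out = icc_reproducibility([(t, t.copy()), (t, t.copy())])
        assert np.allclose(out[["icc_test1", "icc_test2"]].to_numpy(), 1.0)
        assert out["reproducible"].all()

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        t = _frame(rng.standard_normal((38, 5)))
        r = _frame(rng.standard_normal((38, 5)))
        out = icc_reproducibility([(t, r)])
        # null ICC scatters around zero with sd ~ 1/sqrt(n): centred and
        # nowhere near the 0.6 reproducibility cut
        assert abs(out["icc_test1"].mean()) < 0.2
        assert (out["icc_test1"] < 0.6).all()
        assert not out["reproducible"].any()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.random(15)
        y = x + rng.normal(0, 0.05, 15)
        assert icc_1_1(3 * x + 2, 3 * y + 2) == pytest.approx(icc_1_1(x, y))

    def test_constant_shift_of_retest_reduces_agreement_form(self):
        """ICC(1,1) is an absolute-agreement form: adding a constant to every
        retest value lowers it; the consistency form ICC(3,1) is unchanged."""
        rng = np.random.default_rng(8)
        x = rng.random(30)
        y = x + rng.normal(0, 0.02, 30)
        assert icc_1_1(x, y + 0.5) < icc_1_1(x, y)
        assert icc_3_1(x, y + 0.5) == pytest.approx(icc_3_1(x, y), abs=1e-9)

    def test_matches_independent_anova_oracle(self):
        """Cross-check ICC(1,1) against pingouin on the same pairs."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        x = rng.random(20)
        y = x + rng.normal(0, 0.1, 20)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(20), 2),
            "raters": np.repeat(["t", "r"], 20),
            "score": np.concatenate([x, y]),
        })
        ref = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="score"
        ).set_index("Type").loc["ICC(1,1)", "ICC"]
        assert icc_1_1(x, y) == pytest.approx(float(ref), abs=1e-9)

    def test_zero_variance_flagged_nonreproducible(self):
        t = _frame(np.full((8, 1), 2.0))
        out = icc_reproducibility([(t, t.copy())])
        assert not out["reproducible"].iloc[0]


class TestMannWhitney:
    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(10)
        a = _frame(rng.random((12, 3)))
        b = _frame(rng.random((9, 3)))
        assert np.allclose(
            heterogeneity_discrimination(a, b).to_numpy(),
            heterogeneity_discrimination(b, a).to_numpy(),
        )

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(11)
        a = _frame(rng.standard_normal((20, 2)))
        b = _frame(rng.standard_normal((18, 2)) + 5.0)
        assert (heterogeneity_discrimination(a, b) < 0.05).all()

    def test_all_tied_values_give_p_one(self):
        a = _frame(np.full((6, 1), 1.0))
        b = _frame(np.full((5, 1), 1.0))
        assert heterogeneity_discrimination(a, b).iloc[0] == 1.0

    def test_empty_group_rejected(self):
        a = _frame(np.random.default_rng(0).random((5, 1)))
        with pytest.raises(ValueError):
            heterogeneity_discrimination(a, a.iloc[:0])


class TestHgsCorrelation:
    def test_perfect_monotone_correlations(self):
        h = np.array([1.0, 5.0, 9.0, 13.0, 20.0, 31.0])
        feats = pd.DataFrame({"pos": h**2, "neg": -h})  # monotone transforms
        out = hgs_correlation(feats, h)
        assert out.loc["pos", "hgs_rho"] == pytest.approx(1.0)
        assert out.loc["neg", "hgs_rho"] == pytest.approx(-1.0)
        assert (out["hgs_corr_p"] < 0.05).all()

    def test_independent_feature_not_significant_in_expectation(self):
        rng = np.random.default_rng(12)
        h = rng.random(30) * 60
        feats = pd.DataFrame({"noise": rng.random(30)})
        out = hgs_correlation(feats, h)
        assert abs(out.loc["noise", "hgs_rho"]) < 0.5

    def test_constant_feature_flagged(self):
        h = np.arange(6, dtype=float)
        out = hgs_correlation(pd.DataFrame({"const": np.ones(6)}), h)
        assert out.loc["const", "hgs_undefined"]

    def test_pearson_flag(self):
        h = np.arange(1.0, 9.0)
        out = hgs_correlation(pd.DataFrame({"lin": 2 * h + 1}), h, method="pearson")
        assert out.loc["lin", "hgs_rho"] == pytest.approx(1.0)


class TestSphericityAgreement:
    def test_exact_agreement_zero_bias(self):
        s = np.array([0.5, 0.6, 0.7, 0.65])
        p, bias = sphericity_agreement(s, s.copy())
        assert bias == 0.0
        assert p == 1.0

    def test_unbiased_noise_not_significant_typically(self):
        rng = np.random.default_rng(13)
        hits = 0
        for rep in range(20):
            s = rng.uniform(0.5, 0.8, 30)
            p, _ = sphericity_agreement(s + rng.normal(0, 0.01, 30), s)
            hits += p >= 0.05
        assert hits >= 16  # ~alpha = 0.05 under the null

    def test_constant_bias_detected(self):
        rng = np.random.default_rng(14)
        s = rng.uniform(0.5, 0.8, 30)
        p, bias = sphericity_agreement(s + 0.2, s)
        assert p < 0.05
        assert bias == pytest.approx(0.2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sphericity_agreement(np.ones(2), np.ones(2))


class TestReport:
    def _inputs(self, n_feat=6):
        rng = np.random.default_rng(15)
        idx = pd.Index([f"f{i}" for i in range(n_feat)])
        friedman = pd.Series(rng.uniform(0.01, 0.99, n_feat), index=idx)
        fam = {"matrix": {"a": _frame(rng.random((6, n_feat)) + 1),
                          "b": _frame(rng.random((6, n_feat)) + 1)}}
        for d in fam["matrix"].values():
            d.columns = idx
        cov = cov_stability(fam)
        t = _frame(rng.random((8, n_feat)))
        t.columns = idx
        icc = icc_reproducibility([(t, t.copy())])
        mw = pd.Series(rng.uniform(0, 1, n_feat), index=idx)
        hgs = pd.DataFrame({"hgs_rho": rng.uniform(-1, 1, n_feat),
                            "hgs_corr_p": rng.uniform(0, 1, n_feat),
                            "hgs_undefined": False}, index=idx)
        return friedman, cov, icc, mw, hgs

    def test_row_count_and_funnel_consistency(self):
        friedman, cov, icc, mw, hgs = self._inputs()
        rep = build_report(friedman, cov, icc, mw, hgs)
        assert len(rep.table) == 6
        f = rep.summary["funnel"]
        assert f["reproducible"] >= f["reproducible_and_discriminative"]
        assert (f["reproducible_and_discriminative"]
                >= f["reproducible_discriminative_correlated"])

    def test_deterministic_copies_fully_reproducible(self):
        friedman, cov, icc, mw, hgs = self._inputs()
        rep = build_report(friedman, cov, icc, mw, hgs)
        # icc built from duplicated data: everything reproducible
        assert rep.summary["fraction_reproducible"] == 1.0

    def test_registry_mismatch_rejected(self):
        friedman, cov, icc, mw, hgs = self._inputs()
        with pytest.raises(ValueError, match="registries"):
            build_report(friedman.iloc[:3], cov, icc, mw, hgs)

    def test_report_is_pure_function_of_inputs(self):
        args = self._inputs()
        a = build_report(*args).table.to_csv()
        b = build_report(*args).table.to_csv()
        assert a == b


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.04])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all()
    assert (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
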