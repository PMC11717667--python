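import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xtrait.mr import (
    HarmonisedInstrument,
    cochran_q,
    egger,
    f_statistic,
    harmonise,
    instruments_frame,
    ivw,
    leave_one_out,
    mr_presso,
    mvmr_ivw,
    select_instruments,
    weighted_median,
    weighted_mode,
)
from xtrait.synthetic import gen_mr_dataset


def make_instruments(bx, by, se_y, se_x=0.01):
    return pd.DataFrame({
        "snp": [f"s{i}" for i in range(len(bx))],
        "beta_x": bx, "se_x": se_x, "beta_y": by, "se_y": se_y,
    })


def gwas_frame(snps, a1, a2, beta, se, eaf=None, p=None):
    n = len(snps)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    return pd.DataFrame({
        "snp": snps, "chr": "1", "bp": np.arange(n) * 10_000,
        "a1": a1, "a2": a2, "beta": beta, "se": se,
        "p": p if p is not None else 2 * stats.norm.sf(np.abs(beta / se)),
        "eaf": eaf if eaf is not None else np.nan, "n": 10_000,
    })


class TestSelectInstruments:
    def test_strict_threshold(self):
        df = gwas_frame(["a", "b"], "A", "G", [0.1, 0.1], [0.01, 0.01],
                        p=[4.9e-8, 5e-8])
        with pytest.warns(UserWarning, match="p-filtered"):
            out = select_instruments(df)
        assert list(out["snp"]) == ["a"]

    def test_clump_keeps_lower_p(self):
        df = gwas_frame(["a", "b"], "A", "G", [0.1, 0.1], [0.01, 0.01],
                        p=[1e-10, 1e-9])
        out = select_instruments(df, r2_lookup={frozenset(("a", "b")): 0.5})
        assert list(out["snp"]) == ["a"]

    def test_no_instruments_errors(self):
        df = gwas_frame(["a"], "A", "G", [0.01], [0.01], p=[0.5])
        with pytest.raises(ValueError, match="no instruments"):
            select_instruments(df)


class TestHarmonise:
    def test_swapped_alleles_flip_beta(self):
        exp = gwas_frame(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = gwas_frame(["rs1"], ["G"], ["A"], [0.2], [0.02])
        (h,) = harmonise(exp, out)
        assert h.action == "flipped" and h.beta_y == pytest.approx(-0.2)

    def test_strand_flip_resolved(self):
        exp = gwas_frame(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = gwas_frame(["rs1"], ["T"], ["C"], [0.2], [0.02])
        (h,) = harmonise(exp, out)
        assert h.action == "kept" and h.beta_y == pytest.approx(0.2)

    def test_palindromic_dropped(self):
        exp = gwas_frame(["rs1"], ["A"], ["T"], [0.1], [0.01])
        out = gwas_frame(["rs1"], ["A"], ["T"], [0.2], [0.02])
        (h,) = harmonise(exp, out)
        assert h.action == "dropped_palindromic"

    def test_palindromic_gc_dropped(self):
        exp = gwas_frame(["rs1"], ["G"], ["C"], [0.1], [0.01])
        out = gwas_frame(["rs1"], ["G"], ["C"], [0.2], [0.02])
        assert harmonise(exp, out)[0].action == "dropped_palindromic"

    def test_palindromic_inferable_from_eaf(self):
        exp = gwas_frame(["rs1"], ["A"], ["T"], [0.1], [0.01], eaf=[0.10])
        out = gwas_frame(["rs1"], ["A"], ["T"], [0.2], [0.02], eaf=[0.12])
        (h,) = harmonise(exp, out)
        assert h.action == "kept" and h.beta_y == pytest.approx(0.2)

    def test_palindromic_eaf_disagreement_flips(self):
        exp = gwas_frame(["rs1"], ["A"], ["T"], [0.1], [0.01], eaf=[0.10])
        out = gwas_frame(["rs1"], ["A"], ["T"], [0.2], [0.02], eaf=[0.88])
        (h,) = harmonise(exp, out)
        assert h.action == "flipped" and h.beta_y == pytest.approx(-0.2)

    def test_allele_mismatch_dropped(self):
        exp = gwas_frame(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = gwas_frame(["rs1"], ["A"], ["C"], [0.2], [0.02])
        assert harmonise(exp, out)[0].action == "dropped_missing"

    def test_empty_join_errors(self):
        exp = gwas_frame(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = gwas_frame(["rs2"], ["A"], ["G"], [0.2], [0.02])
        with pytest.raises(ValueError, match="no SNPs"):
            harmonise(exp, out)

    def test_palindromic_fraction_dropped_in_generator(self):
        exp, out, truth = gen_mr_dataset(j=20, palindromic_frac=0.2, seed=8)
        inst = harmonise(exp, out)
        dropped = [i.snp for i in inst if i.action == "dropped_palindromic"]
        assert sorted(dropped) == truth.palindromic_ids
        assert len(dropped) == 4


class TestIvw:
    def test_wald_ratio_single_snp(self):
        inst = make_instruments([0.5], [0.15], [0.05])
        with pytest.warns(UserWarning, match="single instrument"):
            fit = ivw(inst)
        assert fit.estimate == pytest.approx(0.3)
        assert fit.se == pytest.approx(0.1)

    def test_perfect_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_instruments(bx, 0.3 * bx, np.full(4, 0.05))
        fit = ivw(inst)
        assert fit.estimate == pytest.approx(0.3, abs=1e-12)
        assert fit.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(100):
            j = int(rng.integers(3, 30))
            bx = rng.normal(0.1, 0.05, j)
            sy = rng.uniform(0.01, 0.1, j)
            by = rng.normal(0.3 * bx, sy)
            inst = make_instruments(bx, by, sy)
            fit = ivw(inst, random_effects="never")
            m = sm.WLS(by, bx, weights=1 / sy**2).fit()
            assert fit.estimate == pytest.approx(m.params[0], abs=1e-10)
            se_unscaled = float(m.bse[0]) / np.sqrt(m.scale)
            assert fit.se == pytest.approx(se_unscaled, abs=1e-10)

    def test_reorder_invariance_and_or(self):
        rng = np.random.default_rng(1)
        bx = rng.normal(0.1, 0.05, 10)
        sy = np.full(10, 0.05)
        by = rng.normal(0.3 * bx, sy)
        inst = make_instruments(bx, by, sy)
        fit = ivw(inst)
        perm = inst.sample(frac=1.0, random_state=2)
        assert ivw(perm).estimate == pytest.approx(fit.estimate, abs=1e-12)
        assert fit.or_estimate == pytest.approx(np.exp(fit.estimate))
        lo, hi = fit.or_ci
        assert lo == pytest.approx(np.exp(fit.ci_low))
        assert fit.ci_low < fit.estimate < fit.ci_high

    def test_random_effects_switch_on_heterogeneity(self):
        bx = np.linspace(0.1, 0.5, 10)
        by = np.array([0.0, 0.5, -0.2, 0.8, 0.1, 0.9, -0.3, 0.7, 0.2, 1.0])
        inst = make_instruments(bx, by, np.full(10, 0.02))
        fit = ivw(inst)
        assert fit.q_p < 0.05 and fit.model == "random"
        fe = ivw(inst, random_effects="never")
        assert fit.se > fe.se

    def test_recovery_bias_and_coverage(self):
        ests, cover = [], 0
        n_sims = 500
        for s in range(n_sims):
            exp, out, _ = gen_mr_dataset(j=50, theta=0.3, seed=s)
            fit = ivw(harmonise(exp, out))
            ests.append(fit.estimate)
            cover += fit.ci_low <= 0.3 <= fit.ci_high
        assert abs(np.mean(ests) - 0.3) < 0.02
        assert 0.92 <= cover / n_sims <= 0.97


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.1 + 0.4 * bx
        fit = egger(make_instruments(bx, by, np.full(5, 0.05)))
        assert fit.estimate == pytest.approx(0.4, abs=1e-10)
        assert fit.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_matches_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for _ in range(100):
            j = int(rng.integers(4, 30))
            bx = np.abs(rng.normal(0.1, 0.05, j)) + 0.01
            sy = rng.uniform(0.01, 0.1, j)
            by = rng.normal(0.05 + 0.3 * bx, sy)
            fit = egger(make_instruments(bx, by, sy))
            x = sm.add_constant(bx)
            m = sm.WLS(by, x, weights=1 / sy**2).fit()
            assert fit.egger_intercept == pytest.approx(m.params[0], abs=1e-10)
            assert fit.estimate == pytest.approx(m.params[1], abs=1e-10)
            assert fit.egger_intercept_se == pytest.approx(m.bse[0], abs=1e-10)
            assert fit.se == pytest.approx(m.bse[1], abs=1e-10)

    def test_intercept_p_calibrated_under_balanced_pleiotropy(self):
        rng = np.random.default_rng(3)
        ps = []
        for s in range(300):
            j = 20
            bx = np.abs(rng.normal(0.1, 0.05, j)) + 0.02
            sy = np.full(j, 0.05)
            by = rng.normal(0.3 * bx, sy)  # intercept 0
            ps.append(egger(make_instruments(bx, by, sy, se_x=1e-8)).egger_intercept_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_intercept_recovers_planted_pleiotropy(self):
        ints = []
        for s in range(200):
            exp, out, _ = gen_mr_dataset(j=50, theta=0.3, intercept=0.05, seed=s)
            ints.append(egger(harmonise(exp, out)).egger_intercept)
        mc_se = np.std(ints) / np.sqrt(len(ints))
        assert abs(np.mean(ints) - 0.05) < 2 * mc_se + 1e-9

    def test_needs_three(self):
        with pytest.raises(ValueError):
            egger(make_instruments([0.1, 0.2], [0.03, 0.06], [0.05, 0.05]))


class TestWeightedMedian:
    def test_midpoint_interpolation(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.3, 0.5])
        fit = weighted_median(make_instruments(bx, by, np.full(3, 0.05)), n_boot=100, seed=0)
        assert fit.estimate == pytest.approx(0.3)

    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        fit = weighted_median(
            make_instruments(bx, 0.4 * bx, np.full(3, 1e-6), se_x=1e-9),
            n_boot=100, seed=0,
        )
        assert fit.estimate == pytest.approx(0.4, abs=1e-3)
        assert fit.se < 1e-3

    def test_robust_to_invalid_instruments(self):
        # 30% of instruments pleiotropic: median stays closer to truth than IVW
        rng = np.random.default_rng(4)
        med_err, ivw_err = [], []
        for s in range(100):
            j = 20
            bx = np.abs(rng.normal(0.15, 0.03, j))
            sy = np.full(j, 0.02)
            by = rng.normal(0.3 * bx, sy)
            by[:6] += 0.5 * bx[:6]  # invalid instruments inflate the ratio
            inst = make_instruments(bx, by, sy)
            med_err.append(abs(weighted_median(inst, n_boot=10, seed=s).estimate - 0.3))
            ivw_err.append(abs(ivw(inst, random_effects="never").estimate - 0.3))
        assert np.mean(med_err) < np.mean(ivw_err)

    def test_zero_beta_x_dropped(self):
        inst = make_instruments([0.0, 0.2, 0.3, 0.4], [0.1, 0.06, 0.09, 0.12],
                                np.full(4, 0.05))
        with pytest.warns(UserWarning, match="beta_x = 0"):
            fit = weighted_median(inst, n_boot=50, seed=1)
        assert fit.n_snps == 3


class TestWeightedMode:
    def test_mode_ignores_outlier(self):
        bx = np.ones(4)
        by = np.array([0.3, 0.3, 0.3, 2.0])
        fit = weighted_mode(make_instruments(bx, by, np.full(4, 0.05)), n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.3, abs=0.1)

    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        fit = weighted_mode(make_instruments(bx, 0.25 * bx, np.full(3, 1e-6)), n_boot=50, seed=0)
        assert fit.estimate == pytest.approx(0.25, abs=1e-6)

    def test_consistent_with_ivw_on_unimodal_data(self):
        exp, out, _ = gen_mr_dataset(j=50, theta=0.3, seed=21)
        inst = harmonise(exp, out)
        wm = weighted_mode(inst, n_boot=200, seed=1)
        iv = ivw(inst)
        assert abs(wm.estimate - iv.estimate) < 2 * (wm.se + iv.se)


class TestCochranQ:
    def test_perfect_fit_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        q, df, p = cochran_q(make_instruments(bx, 0.3 * bx, np.full(3, 0.05)), 0.3)
        assert q == pytest.approx(0.0, abs=1e-20) and df == 2 and p == pytest.approx(1.0)

    def test_chi2_tail(self):
        bx = np.array([1.0, 1.0])
        by = np.array([0.0, 0.0])
        # craft Q = 3.84 with df = 1: residuals split evenly
        inst = make_instruments(bx, by + np.array([np.sqrt(3.84 / 2), -np.sqrt(3.84 / 2)]), np.full(2, 1.0))
        q, df, p = cochran_q(inst, 0.0)
        assert q == pytest.approx(3.84)
        assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        ratios = []
        for _ in range(200):
            j = 30
            bx = np.abs(rng.normal(0.1, 0.03, j)) + 0.02
            sy = np.full(j, 0.05)
            by = rng.normal(0.25 * bx, sy)
            inst = make_instruments(bx, by, sy)
            est = ivw(inst, random_effects="never").estimate
            q, df, _ = cochran_q(inst, est)
            ratios.append(q / df)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestMrPresso:
    def test_outlier_detection_and_distortion(self):
        exp, out, truth = gen_mr_dataset(
            j=50, theta=0.3, outlier_frac=0.06, outlier_shift=1.0, seed=5
        )
        res = mr_presso(harmonise(exp, out), seed=7)
        assert set(map(str, res.outlier_snps)) == set(truth.outlier_ids)
        assert res.global_rss_p < 0.05
        assert abs(res.estimate_after - 0.3) < abs(res.estimate_before - 0.3)
        assert 0 < res.distortion_p <= 1

    def test_no_outliers_under_null(self):
        exp, out, _ = gen_mr_dataset(j=50, theta=0.3, seed=123)
        res = mr_presso(harmonise(exp, out), seed=9)
        assert res.estimate_after == res.estimate_before
        assert np.isnan(res.distortion_p) or res.distortion_p > 0.05

    def test_needs_four(self):
        inst = make_instruments([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], np.full(3, 0.05))
        with pytest.raises(ValueError):
            mr_presso(inst)


class TestLeaveOneOut:
    def test_row_count(self):
        bx = np.array([0.1, 0.2, 0.3])
        df = leave_one_out(make_instruments(bx, 0.3 * bx, np.full(3, 0.05)))
        assert len(df) == 3

    def test_homogeneous_estimates_within_full_ci(self):
        exp, out, _ = gen_mr_dataset(j=30, theta=0.3, seed=33)
        inst = harmonise(exp, out)
        full = ivw(inst)
        loo = leave_one_out(inst)
        assert ((loo["estimate"] >= full.ci_low) & (loo["estimate"] <= full.ci_high)).all()

    def test_dominant_outlier_shifts_most(self):
        exp, out, truth = gen_mr_dataset(
            j=20, theta=0.3, outlier_frac=0.05, outlier_shift=2.0, seed=44
        )
        inst = harmonise(exp, out)
        loo = leave_one_out(inst)
        full = ivw(instruments_frame(inst), random_effects="never").estimate
        shifts = (loo["estimate"] - full).abs()
        assert loo.loc[shifts.idxmax(), "dropped_snp"] == truth.outlier_ids[0]


class TestMvmr:
    def _mv_tables(self, rng, j=40, theta=(0.25, 0.0)):
        snps = [f"rs{i}" for i in range(j)]
        bx1 = rng.normal(0.1, 0.05, j)
        bx2 = rng.normal(0.1, 0.05, j)
        sy = np.full(j, 0.05)
        by = rng.normal(theta[0] * bx1 + theta[1] * bx2, sy)
        e1 = gwas_frame(snps, "A", "G", bx1, np.full(j, 0.01))
        e2 = gwas_frame(snps, "A", "G", bx2, np.full(j, 0.01))
        out = gwas_frame(snps, "A", "G", by, sy)
        return {"x1": e1, "x2": e2}, out

    def test_conditional_effect_recovery(self):
        rng = np.random.default_rng(6)
        ok = 0
        for _ in range(100):
            tabs, out = self._mv_tables(rng)
            f1, f2 = mvmr_ivw(tabs, out)
            if abs(f1.estimate - 0.25) < 2 * f1.se and abs(f2.estimate - 0.0) < 2 * f2.se:
                ok += 1
        assert ok >= 93

    def test_single_exposure_reduces_to_ivw(self):
        rng = np.random.default_rng(7)
        tabs, out = self._mv_tables(rng)
        (fit,) = mvmr_ivw({"x1": tabs["x1"]}, out)
        inst = harmonise(tabs["x1"], out)
        uni = ivw(inst)
        assert fit.estimate == pytest.approx(uni.estimate, abs=1e-12)
        assert fit.se == pytest.approx(uni.se, abs=1e-12)

    def test_duplicated_exposure_rank_deficient(self):
        rng = np.random.default_rng(8)
        tabs, out = self._mv_tables(rng)
        with pytest.raises(ValueError, match="collinear"):
            mvmr_ivw({"x1": tabs["x1"], "x1b": tabs["x1"].copy()}, out)

    def test_allele_flip_harmonised(self):
        rng = np.random.default_rng(9)
        tabs, out = self._mv_tables(rng)
        flipped = tabs["x1"].copy()
        flipped["a1"], flipped["a2"] = "G", "A"
        flipped["beta"] = -flipped["beta"]
        f_orig = mvmr_ivw(tabs, out)
        f_flip = mvmr_ivw({"x1": flipped, "x2": tabs["x2"]}, out)
        assert f_flip[0].estimate == pytest.approx(f_orig[0].estimate, abs=1e-12)


class TestFStatistic:
    def test_closed_form(self):
        inst = make_instruments([0.5], [0.1], [0.05], se_x=0.1)
        f, mean_f = f_statistic(inst)
        assert f[0] == pytest.approx(25.0) and mean_f == pytest.approx(25.0)

    def test_weak_instrument_warning(self):
        inst = make_instruments([0.01, 0.02], [0.0, 0.0], [0.05, 0.05], se_x=0.05)
        with pytest.warns(UserWarning, match="weak"):
            _, mean_f = f_statistic(inst)
        assert mean_f < 10

    def test_sign_invariance(self):
        a = f_statistic(make_instruments([0.3], [0.1], [0.05]))[1]
        b = f_statistic(make_instruments([-0.3], [0.1], [0.05]))[1]
        assert a == b
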