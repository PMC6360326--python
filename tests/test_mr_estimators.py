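"""Core estimators: Wald, IVW, heterogeneity, Egger, weighted median, units."""

import math

import numpy as np
import pytest

from lipidmr import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    heterogeneity,
    ivw,
    to_or_per_unit,
    wald_ratio,
    weighted_median,
)
from conftest import make_instrument, make_set, random_set


# ---------------------------------------------------------------- oracles
def wls_origin_oracle(bx, by, sy):
    """Weighted least squares of by on bx through the origin, weights 1/sy²."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx), np.asarray(by)
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = 1.0 / np.sqrt(np.sum(w * bx**2))
    return beta, se


def egger_normal_equations_oracle(bx, by, sy):
    """Weighted regression with intercept via explicit normal equations."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    W = np.diag(1.0 / np.asarray(sy, float) ** 2)
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    coef = xtwx_inv @ X.T @ W @ by
    resid = by - X @ coef
    rss_w = float(resid @ W @ resid)
    scale = math.sqrt(max(1.0, rss_w / (len(bx) - 2)))
    se = np.sqrt(np.diag(xtwx_inv)) * scale
    return coef, se  # (intercept, slope), (se_int, se_slope)


def weighted_median_bruteforce(ratios, weights):
    """Direct evaluation of the interpolated weighted-median definition."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return r[0]
    if 0.5 >= s[-1]:
        return r[-1]
    j = np.searchsorted(s, 0.5)
    return r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1])


# ------------------------------------------------------------- Wald ratio
class TestWaldRatio:
    def test_null_outcome_effect(self):
        est = wald_ratio(make_instrument(bx=0.5, by=0.0, sy=0.05))
        assert est.beta == 0.0 and est.se == pytest.approx(0.1)

    def test_direct_division(self):
        est = wald_ratio(make_instrument(bx=0.5, by=0.1, sy=0.05))
        assert est.beta == pytest.approx(0.2) and est.se == pytest.approx(0.1)

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(make_instrument(bx=0.5, by=0.1, sy=0.05))
        b = wald_ratio(make_instrument(bx=-0.5, by=-0.1, sy=0.05))
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(make_instrument(bx=0.0))


# -------------------------------------------------------------------- IVW
class TestIVW:
    def test_two_instrument_hand_example(self):
        # ratios 0.2, 0.1; weights 400, 100 -> beta 0.18, se 1/sqrt(500)
        iset = make_set([0.2, 0.1], [0.04, 0.01], [0.01, 0.01])
        est = ivw(iset, "fixed")
        assert est.beta == pytest.approx(0.18, abs=1e-12)
        assert est.se == pytest.approx(1 / math.sqrt(500), rel=1e-12)

    def test_matches_wls_origin_oracle_on_random_sets(self, rng):
        for _ in range(100):
            iset = random_set(rng, k=int(rng.integers(2, 15)), het=0.05)
            bx = [i.beta_exposure for i in iset]
            by = [i.beta_outcome for i in iset]
            sy = [i.se_outcome for i in iset]
            beta, se = wls_origin_oracle(bx, by, sy)
            est = ivw(iset, "fixed")
            assert est.beta == pytest.approx(beta, abs=1e-9)
            assert est.se == pytest.approx(se, abs=1e-9)

    def test_homogeneous_ratios_make_random_equal_fixed(self, homogeneous_set):
        f = ivw(homogeneous_set, "fixed")
        r = ivw(homogeneous_set, "random")
        assert f.beta == r.beta and f.se == r.se

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            iset = random_set(rng, k=8, het=0.2)
            assert ivw(iset, "random").se >= ivw(iset, "fixed").se

    def test_k1_equals_wald(self):
        inst = make_instrument(bx=0.3, by=0.06, sy=0.02)
        iset = make_set([0.3], [0.06], [0.02])
        assert ivw(iset, "fixed").beta == wald_ratio(inst).beta
        assert ivw(iset, "fixed").se == wald_ratio(inst).se
        with pytest.raises(InsufficientInstrumentsError):
            ivw(iset, "random")

    def test_subset_sign_flip_invariance(self, rng):
        iset = random_set(rng, k=10, het=0.05)
        flipped = make_set(
            [-i.beta_exposure if j < 5 else i.beta_exposure for j, i in enumerate(iset)],
            [-i.beta_outcome if j < 5 else i.beta_outcome for j, i in enumerate(iset)],
            [i.se_outcome for i in iset],
        )
        assert ivw(iset, "fixed").beta == pytest.approx(ivw(flipped, "fixed").beta, rel=1e-12)

    def test_estimate_fields_are_consistent(self, rng):
        est = ivw(random_set(rng, k=6), "fixed")
        assert est.ci_low == pytest.approx(est.beta - 1.959964 * est.se, abs=1e-9)
        assert est.ci_high == pytest.approx(est.beta + 1.959964 * est.se, abs=1e-9)
        assert est.odds_ratio == pytest.approx(math.exp(est.beta))
        assert est.or_ci_low == pytest.approx(math.exp(est.ci_low))


# ---------------------------------------------------------- heterogeneity
class TestHeterogeneity:
    def test_identical_ratios_give_null_q(self, homogeneous_set):
        het = heterogeneity(homogeneous_set)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0 and het.pvalue == 1.0
        assert het.df == 4

    def test_i2_truncated_at_zero_when_q_below_df(self):
        # mild spread: Q positive but below df
        iset = make_set([0.1, 0.2, 0.3, 0.15, 0.25],
                        [0.0101, 0.0200, 0.0299, 0.0150, 0.0250],
                        [0.02] * 5)
        het = heterogeneity(iset)
        assert 0 < het.q < het.df
        assert het.i2 == 0.0

    def test_mean_q_matches_chisq_expectation_under_null(self):
        """With no pleiotropy the Q statistic is ~chi-square(k-1)."""
        from lipidmr import preset, simulate_pair, harmonize
        qs = []
        for rep in range(200):
            exp, out, _ = simulate_pair(preset("null", seed=900 + rep))
            qs.append(heterogeneity(harmonize(exp, out)).q)
        df = 77
        # mean of chi2(df) over 200 reps: sd = sqrt(2*df/200) ~ 0.88
        assert abs(np.mean(qs) - df) < 3 * math.sqrt(2 * df / 200)

    def test_k1_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            heterogeneity(make_set([0.1], [0.01], [0.02]))


# -------------------------------------------------------------- MR-Egger
class TestEgger:
    def test_collinear_through_origin(self):
        bx = [0.1, 0.2, 0.3]
        iset = make_set(bx, [0.05 * b for b in bx], [0.02] * 3)
        res = egger(iset)
        assert res.slope.beta == pytest.approx(0.05, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data(self):
        bx = [0.1, 0.2, 0.3, 0.4]
        iset = make_set(bx, [0.02 + 0.5 * b for b in bx], [0.02] * 4)
        res = egger(iset)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.02, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            iset = random_set(rng, k=int(rng.integers(3, 12)), het=0.05)
            # the oracle needs positively-oriented exposure effects too
            bx = np.abs([i.beta_exposure for i in iset])
            by = [i.beta_outcome * (1 if i.beta_exposure > 0 else -1) for i in iset]
            sy = [i.se_outcome for i in iset]
            coef, se = egger_normal_equations_oracle(bx, by, sy)
            res = egger(iset)
            assert res.intercept == pytest.approx(coef[0], abs=1e-9)
            assert res.slope.beta == pytest.approx(coef[1], abs=1e-9)
            assert res.intercept_se == pytest.approx(se[0], abs=1e-9)
            assert res.slope.se == pytest.approx(se[1], abs=1e-9)

    def test_orientation_invariance_under_sign_flips(self, rng):
        iset = random_set(rng, k=8, het=0.05)
        flipped = make_set(
            [-i.beta_exposure for i in iset],
            [-i.beta_outcome for i in iset],
            [i.se_outcome for i in iset],
        )
        a, b = egger(iset), egger(flipped)
        assert a.slope.beta == pytest.approx(b.slope.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_unscaled_se_never_exceeds_scaled(self, rng):
        res = egger(random_set(rng, k=10, het=0.3))
        assert res.slope_se_unscaled <= res.slope.se

    def test_k2_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_set([0.1, 0.2], [0.01, 0.02], [0.02, 0.02]))

    def test_intercept_recovers_directional_pleiotropy(self):
        """With many strong instruments of heterogeneous strength the
        intercept converges to the mean pleiotropic effect. Instrument
        strength matters: exposure-side sampling noise attenuates the slope
        (regression dilution) and leaks into the intercept, so the panel
        uses a large exposure GWAS and a wide spread of effect sizes."""
        from lipidmr import preset, simulate_pair, harmonize
        ints = []
        for rep in range(30):
            cfg = preset("directional_pleiotropy", seed=1200 + rep, n_snps=500,
                         n_exposure=1_000_000,
                         effect_distribution="exponential")
            exp, out, _ = simulate_pair(cfg)
            ints.append(egger(harmonize(exp, out)).intercept)
        mcse = np.std(ints, ddof=1) / math.sqrt(len(ints))
        assert abs(np.mean(ints) - 0.03) < 2 * mcse + 1e-4


# -------------------------------------------------------- weighted median
class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        iset = make_set([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.02] * 3)
        est = weighted_median(iset, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_degenerate_spread_gives_small_se(self):
        # all ratios exactly 0.25 with tiny sampling noise
        iset = make_set([0.1, 0.2, 0.3], [0.025, 0.05, 0.075],
                        [1e-4] * 3, sx=[1e-4] * 3)
        est = weighted_median(iset, n_boot=500, seed=1)
        assert est.beta == pytest.approx(0.25, abs=1e-12)
        assert est.se < 0.01

    def test_matches_bruteforce_interpolation(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 12))
            iset = random_set(rng, k=k, het=0.1)
            bx = np.array([i.beta_exposure for i in iset])
            by = np.array([i.beta_outcome for i in iset])
            sy = np.array([i.se_outcome for i in iset])
            expected = weighted_median_bruteforce(by / bx, (bx / sy) ** 2)
            est = weighted_median(iset, n_boot=10, seed=3)
            assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_seed_reproducibility(self, rng):
        iset = random_set(rng, k=6)
        a = weighted_median(iset, n_boot=300, seed=42)
        b = weighted_median(iset, n_boot=300, seed=42)
        c = weighted_median(iset, n_boot=300, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_missing_seed_raises(self, rng):
        with pytest.raises(ValueError):
            weighted_median(random_set(rng, k=5))


# ------------------------------------------------------------------ units
class TestUnitConversion:
    def test_identity_scaling(self, rng):
        est = ivw(random_set(rng, k=5), "fixed")
        same = to_or_per_unit(est, sd_unit=39.0, target_unit=39.0)
        assert same.beta == est.beta and same.se == est.se

    def test_per_mg_dl_rescaling(self):
        iset = make_set([1.0], [0.13103], [0.03])
        est = ivw(iset, "fixed")
        scaled = to_or_per_unit(est, sd_unit=39.0, target_unit=1.0)
        assert scaled.beta == pytest.approx(0.13103 / 39.0, rel=1e-9)
        assert scaled.odds_ratio == pytest.approx(math.exp(0.0033598), rel=1e-4)

    def test_pvalue_invariant_under_rescaling(self, rng):
        est = ivw(random_set(rng, k=5), "fixed")
        assert to_or_per_unit(est, 39.0, 7.7).pvalue == est.pvalue
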