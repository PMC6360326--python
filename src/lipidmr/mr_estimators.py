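"""Core two-sample Mendelian randomization estimators and heterogeneity.

All estimators consume an :class:`~lipidmr.summary_data.InstrumentSet` and
return a causal log-odds-ratio of the outcome per 1 SD of the exposure.

The per-SNP building block is the Wald ratio r_j = beta_Y_j / beta_X_j with
first-order standard error se_Y_j / |beta_X_j| (outcome noise only, the
standard two-sample approximation). The inverse-variance weighted (IVW)
estimate is the precision-weighted mean of the ratios with weights
w_j = (beta_X_j / se_Y_j)^2 — algebraically a weighted regression of
beta_Y on beta_X through the origin. The random-effects variant inflates the
fixed-effects SE by the multiplicative overdispersion factor
sqrt(max(1, Q/(k-1))). MR-Egger adds an intercept to that regression: the
slope is a pleiotropy-robust causal estimate under InSIDE and a nonzero
intercept indicates directional horizontal pleiotropy. The weighted median
is the interpolated 50%-weight quantile of the ratio distribution,
consistent when valid instruments carry at least half of the weight; its SE
comes from a parametric bootstrap.

P-values are two-sided from the standard normal throughout, matching
large-sample GWAS practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2, norm
import statsmodels.api as sm

from .exceptions import (
    DomainError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .summary_data import HarmonizedInstrument, InstrumentSet

logger = logging.getLogger(__name__)

#: standard normal 97.5% quantile used for all 95% intervals
Z_95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-OR-per-SD scale, with OR versions."""

    method: str
    beta: float
    se: float
    k: int
    ci_low: float = 0.0
    ci_high: float = 0.0
    pvalue: float = 1.0
    odds_ratio: float = 1.0
    or_ci_low: float = 1.0
    or_ci_high: float = 1.0

    @classmethod
    def from_beta_se(
        cls, method: str, beta: float, se: float, k: int, pvalue: float | None = None
    ) -> "MREstimate":
        """Build an estimate, deriving CI, OR and (unless given) the p-value."""
        if not se > 0:
            raise DomainError(f"standard error must be positive, got {se}")
        ci_low = beta - Z_95 * se
        ci_high = beta + Z_95 * se
        if pvalue is None:
            pvalue = float(2.0 * norm.sf(abs(beta) / se))
            pvalue = max(pvalue, np.finfo(float).tiny)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            k=k,
            ci_low=ci_low,
            ci_high=ci_high,
            pvalue=pvalue,
            odds_ratio=float(np.exp(beta)),
            or_ci_low=float(np.exp(ci_low)),
            or_ci_high=float(np.exp(ci_high)),
        )


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran Q heterogeneity of the per-SNP ratios around the IVW estimate."""

    q: float
    df: int
    pvalue: float
    i2: float  # percent, truncated at 0


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal estimate) and intercept (directional pleiotropy)."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    slope_se_unscaled: float  # SE without the overdispersion factor
    scale: float  # applied multiplicative overdispersion factor


def _arrays(iset: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exposure for i in iset], dtype=float)
    sx = np.array([i.se_exposure for i in iset], dtype=float)
    by = np.array([i.beta_outcome for i in iset], dtype=float)
    sy = np.array([i.se_outcome for i in iset], dtype=float)
    return bx, sx, by, sy


def _require_nonzero_bx(bx: np.ndarray, iset: InstrumentSet) -> None:
    if np.any(bx == 0):
        bad = [i.snp_id for i, b in zip(iset, bx) if b == 0]
        raise UndefinedRatioError(f"zero exposure beta for {', '.join(bad)}")


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate beta_Y / beta_X with first-order SE."""
    if inst.beta_exposure == 0:
        raise UndefinedRatioError(f"zero exposure beta for {inst.snp_id}")
    beta = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    return MREstimate.from_beta_se("wald", beta, se, k=1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Return (beta_ivw, fixed se, Q) for ratio-based IVW."""
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se_fixed = float(1.0 / np.sqrt(np.sum(weights)))
    q = float(np.sum(weights * (ratios - beta) ** 2))
    return beta, se_fixed, q


def ivw(iset: InstrumentSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted estimate.

    ``model='fixed'`` needs k >= 1; ``model='random'`` (multiplicative
    overdispersion) needs k >= 2 and inflates the SE by
    sqrt(max(1, Q/(k-1))); it never reports a smaller SE than fixed.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(iset)
    kmin = 1 if model == "fixed" else 2
    if k < kmin:
        raise InsufficientInstrumentsError(f"IVW {model} needs k >= {kmin}, got {k}")
    bx, _, by, sy = _arrays(iset)
    _require_nonzero_bx(bx, iset)
    beta, se, q = _ivw_core(bx, by, sy)
    method = "ivw_fixed"
    if model == "random":
        se *= float(np.sqrt(max(1.0, q / (k - 1))))
        method = "ivw_random"
    return MREstimate.from_beta_se(method, beta, se, k=k)


def heterogeneity(iset: InstrumentSet) -> HeterogeneityStats:
    """Cochran Q and I² of the per-SNP ratios around the fixed-effects IVW."""
    k = len(iset)
    if k < 2:
        raise InsufficientInstrumentsError(f"heterogeneity needs k >= 2, got {k}")
    bx, _, by, sy = _arrays(iset)
    _require_nonzero_bx(bx, iset)
    _, _, q = _ivw_core(bx, by, sy)
    df = k - 1
    pvalue = float(chi2.sf(q, df)) if q > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, pvalue=pvalue, i2=i2)


def _orient_positive(iset: InstrumentSet) -> InstrumentSet:
    """Negate both betas of instruments with negative exposure effect.

    MR-Egger is not invariant to allele recoding; the convention is to code
    every instrument so its exposure effect is positive.
    """
    oriented = []
    for inst in iset:
        if inst.beta_exposure < 0:
            inst = replace(
                inst, beta_exposure=-inst.beta_exposure, beta_outcome=-inst.beta_outcome
            )
        oriented.append(inst)
    return replace(iset, instruments=oriented)


def egger(iset: InstrumentSet) -> EggerResult:
    """MR-Egger regression: weighted fit of beta_Y on beta_X with intercept.

    Weights are 1/se_Y²; both SEs carry the multiplicative overdispersion
    factor sqrt(max(1, RSS_w/(k-2))), floored at 1 so precision is never
    overstated on under-dispersed data. The SE without the factor is reported
    alongside as ``slope_se_unscaled``.
    """
    k = len(iset)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs k >= 3, got {k}")
    iset = _orient_positive(iset)
    bx, _, by, sy = _arrays(iset)
    _require_nonzero_bx(bx, iset)
    w = 1.0 / sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = fit.params
    # statsmodels scales the covariance by sigma2_hat = RSS_w/(k-2); recover
    # the unscaled (sigma=1) SEs and apply the floored factor ourselves.
    sigma2_hat = fit.scale
    se_unscaled = fit.bse / np.sqrt(sigma2_hat)
    scale = float(np.sqrt(max(1.0, sigma2_hat)))
    se_int, se_slope = se_unscaled * scale
    slope_est = MREstimate.from_beta_se("egger_slope", float(slope), float(se_slope), k=k)
    intercept_p = float(2.0 * norm.sf(abs(intercept) / se_int))
    return EggerResult(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=intercept_p,
        slope_se_unscaled=float(se_unscaled[1]),
        scale=scale,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` with the given weights."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0  # cumulative midpoints
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    iset: InstrumentSet, n_boot: int = 10_000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the per-SNP Wald ratios at cumulative
    weight 0.5 using IVW weights. The SE is the standard deviation of the
    estimate over ``n_boot`` parametric resamples of (beta_X, beta_Y) from
    normals centred on the observed values; ``seed`` is mandatory so results
    are reproducible.
    """
    k = len(iset)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs k >= 3, got {k}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(iset)
    _require_nonzero_bx(bx, iset)
    ratios = by / bx
    weights = (bx / sy) ** 2
    point = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    # guard against resampled exposure betas crossing zero
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _weighted_median_point(by_b[b] / bx_b[b], (bx_b[b] / sy) ** 2)
    se = float(np.std(boot, ddof=1))
    if se == 0:  # degenerate spread (all ratios identical, tiny SEs)
        se = np.finfo(float).tiny
    return MREstimate.from_beta_se("weighted_median", point, se, k=k)


def to_or_per_unit(
    est: MREstimate, sd_unit: float, target_unit: float
) -> MREstimate:
    """Rescale an estimate from per-SD units to per ``target_unit`` mg/dL.

    beta and se are multiplied by target_unit/sd_unit; CI and OR follow; the
    p-value is scale-invariant and kept.
    """
    if sd_unit <= 0 or target_unit <= 0:
        raise DomainError("units must be positive")
    factor = target_unit / sd_unit
    return MREstimate.from_beta_se(
        est.method, est.beta * factor, est.se * factor, k=est.k, pvalue=est.pvalue
    )
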