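"""Multivariable Mendelian randomization (MVMR).

Estimates the direct effect of one exposure on the outcome while controlling
for correlated exposures (e.g. LDL controlling for HDL and TG), using only
summary statistics across a shared instrument panel. Two routes:

* residual-based — regress the target exposure's per-SNP effects on the
  covariate exposures' effects (OLS with intercept), replace the target
  effects by the residuals, then run fixed-effects IVW of the outcome on the
  residualized effects;
* joint — weighted multiple regression of the outcome effects on all
  exposure effect columns simultaneously (no intercept, weights 1/se_Y²);
  each coefficient is that exposure's direct effect.

LDL, HDL, TG and TC cannot all enter jointly: total cholesterol is (almost
exactly) a linear combination of the other three, so the design is singular
by construction and the package refuses it up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .mr_estimators import MREstimate

logger = logging.getLogger(__name__)

#: requesting all four of these as joint exposures is refused proactively
_FORBIDDEN_JOINT = frozenset({"HDL", "LDL", "TC", "TG"})


@dataclass
class MultiExposurePanel:
    """Per-SNP effects for m exposures and one outcome over k shared SNPs."""

    snp_ids: list[str]
    exposure_beta: np.ndarray  # (k, m)
    exposure_se: np.ndarray  # (k, m)
    outcome_beta: np.ndarray  # (k,)
    outcome_se: np.ndarray  # (k,)
    exposure_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_beta = np.asarray(self.exposure_beta, dtype=float)
        self.exposure_se = np.asarray(self.exposure_se, dtype=float)
        self.outcome_beta = np.asarray(self.outcome_beta, dtype=float)
        self.outcome_se = np.asarray(self.outcome_se, dtype=float)
        k, m = self.exposure_beta.shape
        if len(self.snp_ids) != k or self.exposure_se.shape != (k, m):
            raise ValueError("inconsistent panel dimensions")
        if self.outcome_beta.shape != (k,) or self.outcome_se.shape != (k,):
            raise ValueError("inconsistent outcome dimensions")
        if not self.exposure_names:
            self.exposure_names = [f"X{j + 1}" for j in range(m)]
        if len(self.exposure_names) != m:
            raise ValueError("exposure_names length mismatch")
        if np.any(self.exposure_se <= 0) or np.any(self.outcome_se <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def k(self) -> int:
        return self.exposure_beta.shape[0]

    @property
    def m(self) -> int:
        return self.exposure_beta.shape[1]


def _check_forbidden(names: list[str]) -> None:
    upper = {n.upper() for n in names}
    if _FORBIDDEN_JOINT <= upper:
        raise CollinearityError(
            "HDL, LDL, TC and TG cannot all be joint exposures: TC is a "
            "linear combination of the other three lipids"
        )


def residual_mvmr(panel: MultiExposurePanel, target: str) -> MREstimate:
    """Residual-based MVMR estimate of the direct effect of ``target``.

    The target exposure's beta column is regressed on all other exposure
    columns (unweighted OLS with intercept); the residuals replace the
    target betas and a fixed-effects IVW of the outcome on the residualized
    betas gives the estimate. Covariate columns that are identically zero
    are ignored (they carry no signal to remove).
    """
    if target not in panel.exposure_names:
        raise ValueError(f"target {target!r} not among exposures {panel.exposure_names}")
    _check_forbidden(panel.exposure_names)
    if panel.k < panel.m + 2:
        raise InsufficientInstrumentsError(
            f"residual MVMR needs k >= m + 2, got k={panel.k}, m={panel.m}"
        )
    t = panel.exposure_names.index(target)
    y = panel.exposure_beta[:, t]
    cov_idx = [j for j in range(panel.m) if j != t]
    covs = panel.exposure_beta[:, cov_idx]
    nonzero = [j for j in range(covs.shape[1]) if np.any(covs[:, j] != 0)]
    X = np.column_stack([np.ones(panel.k)] + [covs[:, j] for j in nonzero])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = [panel.exposure_names[cov_idx[j]] for j in nonzero]
        raise CollinearityError(f"covariate exposures are collinear: {names}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(y), 1e-300):
        raise UndefinedRatioError(
            f"{target} effects are fully explained by the covariates; "
            "residual instrument strengths are degenerate"
        )
    w = 1.0 / panel.outcome_se**2
    num = float(np.sum(w * resid * panel.outcome_beta))
    den = float(np.sum(w * resid**2))
    beta = num / den
    se = float(1.0 / np.sqrt(den))
    return MREstimate.from_beta_se("mvmr_residual", beta, se, k=panel.k)


def joint_mvmr(panel: MultiExposurePanel) -> list[MREstimate]:
    """Joint MVMR: weighted multiple regression of outcome on all exposures.

    No intercept; weights 1/se_Y². SEs carry the multiplicative
    overdispersion factor sqrt(max(1, RSS_w/(k-m))), floored at 1. With a
    single exposure the coefficient reduces exactly to fixed-effects IVW.
    """
    _check_forbidden(panel.exposure_names)
    if panel.k <= panel.m:
        raise InsufficientInstrumentsError(
            f"joint MVMR needs k > m, got k={panel.k}, m={panel.m}"
        )
    X = panel.exposure_beta
    if np.linalg.matrix_rank(X) < panel.m:
        raise CollinearityError(
            f"exposure effect matrix is rank deficient: {panel.exposure_names}"
        )
    w = 1.0 / panel.outcome_se**2
    fit = sm.WLS(panel.outcome_beta, X, weights=w).fit()
    se_unscaled = fit.bse / np.sqrt(fit.scale)  # statsmodels always applies sigma_hat
    scale = float(np.sqrt(max(1.0, fit.scale)))
    estimates = []
    for j in range(panel.m):
        estimates.append(
            MREstimate.from_beta_se(
                "mvmr_joint",
                float(fit.params[j]),
                float(se_unscaled[j] * scale),
                k=panel.k,
            )
        )
    return estimates
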