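"""Cross-population meta-analysis and analytic power for binary-outcome MR.

When the causal effect is assumed identical across populations, per-
population IVW estimates are pooled by a fixed-effect inverse-variance
meta-analysis; a z-test on the difference of the two log-OR estimates checks
that assumption. Power for a two-sample MR with a binary outcome follows
the noncentral chi-square approximation: with case fraction K = n_cases/N,
alternative odds ratio OR per exposure SD and instrument strength R²_xz,

    b   = K * (OR / (1 + K*(OR - 1)) - 1)
    v   = (K*(1 - K) - b²) / (N * R²_xz)
    NCP = b² / v

and power is the probability that a noncentral chi-square(1, NCP) exceeds
the central chi-square(1) quantile at 1 - alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, ncx2, norm

from .exceptions import DomainError
from .mr_estimators import MREstimate, Z_95

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the binary-outcome MR power calculation."""

    n: int  # outcome GWAS total sample size
    n_cases: int
    r2: float  # instrument R² on the exposure
    or_alt: float  # alternative OR per exposure SD
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n):
            raise DomainError(f"need 0 < n_cases < n, got {self.n_cases}/{self.n}")
        if not (0 < self.r2 < 1):
            raise DomainError(f"r2 must lie in (0, 1), got {self.r2}")
        if self.or_alt <= 0:
            raise DomainError(f"or_alt must be positive, got {self.or_alt}")
        if not (0 < self.alpha < 1):
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n


def estimate_from_or_ci(
    odds_ratio: float, ci_low: float, ci_high: float, method: str = "ivw_fixed", k: int = 0
) -> MREstimate:
    """Recover (beta, se) from a printed OR with 95% CI.

    se = (ln(hi) - ln(lo)) / (2 * 1.959964); useful for pooling published
    estimates whose underlying SEs are not reported.
    """
    if min(odds_ratio, ci_low, ci_high) <= 0 or ci_high <= ci_low:
        raise DomainError("OR and CI bounds must be positive with ci_low < ci_high")
    beta = math.log(odds_ratio)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return MREstimate.from_beta_se(method, beta, se, k=k)


def meta_fixed(estimates: Sequence[MREstimate]) -> MREstimate:
    """Fixed-effect inverse-variance meta-analysis of causal estimates."""
    if len(estimates) == 0:
        raise ValueError("meta_fixed needs at least one estimate")
    if len(estimates) == 1:
        logger.warning("meta_fixed called with a single estimate; passing it through")
        e = estimates[0]
        return MREstimate.from_beta_se("meta_fixed", e.beta, e.se, k=e.k)
    betas = np.array([e.beta for e in estimates])
    ws = np.array([1.0 / e.se**2 for e in estimates])
    beta = float(np.sum(ws * betas) / np.sum(ws))
    se = float(1.0 / np.sqrt(np.sum(ws)))
    k = sum(e.k for e in estimates)
    return MREstimate.from_beta_se("meta_fixed", beta, se, k=k)


def between_population_z(a: MREstimate, b: MREstimate) -> tuple[float, float]:
    """z-test for a difference between two independent causal estimates."""
    z = (a.beta - b.beta) / math.sqrt(a.se**2 + b.se**2)
    pvalue = float(2.0 * norm.sf(abs(z)))
    return z, pvalue


def mr_power_binary(spec: PowerSpec) -> float:
    """Analytic power of the two-sample MR test for a binary outcome."""
    K = spec.case_fraction
    orr = spec.or_alt
    b = K * (orr / (1.0 + K * (orr - 1.0)) - 1.0)
    v = (K * (1.0 - K) - b * b) / (spec.n * spec.r2)
    if v <= 0:
        raise DomainError(
            f"degenerate variance v={v:g}; inputs incompatible with K(1-K)={K * (1 - K):g}"
        )
    ncp = b * b / v
    crit = chi2.ppf(1.0 - spec.alpha, df=1)
    return float(ncx2.sf(crit, df=1, nc=ncp))


def round_percent(power: float) -> int:
    """Half-up rounding of a power to whole percent, for reporting."""
    return int(math.floor(power * 100.0 + 0.5))
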