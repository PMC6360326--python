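"""Synthetic paired GWAS summary statistics with known causal structure.

The generator emulates the statistical structure of a two-sample summary-data
MR study: per-SNP true exposure effects gamma_j (per-SD units) whose summed
variance contribution equals a configured instrument R²; pleiotropic outcome
effects alpha_j ~ Normal(mean, sd²); true outcome effects
Gamma_j = theta * gamma_j + alpha_j on the log-odds scale; and observed
effects drawn around the truth with the standard GWAS sampling variances

    se_X_j = sqrt( 1 / (2 f_j (1 - f_j) n_exposure) )
    se_Y_j = sqrt( 1 / (2 f_j (1 - f_j) n_outcome K (1 - K)) )

where f_j is the minor-allele frequency and K the outcome case fraction
(the K(1-K) factor is the effective-sample-size deflation of a binary
trait, consistent with the power module's variance algebra).

Defaults emulate the European LDL arm of the study design this package
reproduces: 78 instruments explaining 8.75% of exposure variance, exposure
GWAS n = 188,577, outcome GWAS n = 41,689 with 14,791 cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigurationError, DomainError
from .summary_data import GwasRecord

logger = logging.getLogger(__name__)

_EUR_N_EXPOSURE = 188_577
_EUR_N_OUTCOME = 41_689
_EUR_CASES = 14_791
_LDL_N_SNPS = 78
_LDL_TOTAL_R2 = 0.0875


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one paired exposure/outcome simulation."""

    seed: int
    n_snps: int = _LDL_N_SNPS
    n_exposure: int = _EUR_N_EXPOSURE
    n_outcome: int = _EUR_N_OUTCOME
    case_fraction: float = _EUR_CASES / _EUR_N_OUTCOME
    theta: float = 0.0  # true causal log-OR per exposure SD
    total_r2: float = _LDL_TOTAL_R2  # summed instrument PVE on the exposure
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 0  # adjacent SNPs sharing a clump window
    effect_distribution: str = "equal"  # or "exponential" decay of PVE shares
    effect_sign: str = "positive"  # or "random" per-SNP sign of gamma
    inside_rho: float = 0.0  # corr(alpha, gamma): InSIDE violation knob

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_exposure < 3 or self.n_outcome < 3:
            raise DomainError("n_snps, n_exposure, n_outcome must be positive (n > 2)")
        if not (0 < self.case_fraction < 1):
            raise DomainError(f"case_fraction must lie in (0,1), got {self.case_fraction}")
        if not (0 <= self.total_r2 < 1):
            raise DomainError(f"total_r2 must lie in [0,1), got {self.total_r2}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DomainError(f"maf_range must be ordered within (0, 0.5], got {self.maf_range}")
        if self.pleiotropy_sd < 0:
            raise DomainError("pleiotropy_sd must be nonnegative")
        if self.effect_distribution not in ("equal", "exponential"):
            raise ConfigurationError(f"unknown effect_distribution {self.effect_distribution!r}")
        if self.effect_sign not in ("positive", "random"):
            raise ConfigurationError(f"unknown effect_sign {self.effect_sign!r}")
        if not (-1 <= self.inside_rho <= 1):
            raise DomainError("inside_rho must lie in [-1, 1]")


def _positions(n_snps: int, ld_block_size: int) -> tuple[list[str], list[int]]:
    """Lay loci 10 Mb apart cycling over 22 chromosomes; LD blocks share a locus."""
    chroms, positions = [], []
    block = max(1, ld_block_size)
    locus = 0
    for j in range(n_snps):
        if ld_block_size > 0:
            locus = j // block
            offset = (j % block) * 10_000  # within the 1 Mb clump window
        else:
            locus = j
            offset = 0
        chroms.append(str(locus % 22 + 1))
        positions.append(1_000_000 + (locus // 22) * 10_000_000 + offset)
    return chroms, positions


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[list[GwasRecord], list[GwasRecord], pd.DataFrame]:
    """Draw one paired exposure/outcome summary-statistics table.

    Returns ``(exposure_records, outcome_records, truth)`` where ``truth``
    is a per-SNP table of the generating quantities (maf, gamma, alpha,
    Gamma, sampling SEs). Identical configs give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    het = 2.0 * maf * (1.0 - maf)  # per-SNP genotypic variance

    if cfg.effect_distribution == "equal":
        shares = np.full(n, 1.0 / n)
    else:  # exponential decay of PVE shares
        shares = np.exp(-np.arange(n) / max(n / 5.0, 1.0))
        shares /= shares.sum()
    var_contrib = cfg.total_r2 * shares
    if np.any(var_contrib >= 1.0):
        raise DomainError("per-SNP variance contribution reaches 1; lower total_r2")
    gamma = np.sqrt(var_contrib / het)
    if cfg.effect_sign == "random":
        gamma *= rng.choice([-1.0, 1.0], size=n)

    if cfg.pleiotropy_sd > 0 and cfg.inside_rho != 0 and np.std(gamma) > 0:
        g_std = (gamma - gamma.mean()) / gamma.std()
        z = rng.standard_normal(n)
        mix = cfg.inside_rho * g_std + np.sqrt(1 - cfg.inside_rho**2) * z
        alpha = cfg.pleiotropy_mean + cfg.pleiotropy_sd * mix
    else:
        alpha = cfg.pleiotropy_mean + cfg.pleiotropy_sd * rng.standard_normal(n)
    big_gamma = cfg.theta * gamma + alpha

    K = cfg.case_fraction
    se_x = np.sqrt(1.0 / (het * cfg.n_exposure))
    se_y = np.sqrt(1.0 / (het * cfg.n_outcome * K * (1.0 - K)))
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(big_gamma, se_y)
    p_x = _pvalues(beta_x, se_x)
    p_y = _pvalues(beta_y, se_y)

    chroms, positions = _positions(n, cfg.ld_block_size)
    snp_ids = [f"rs{j + 1:06d}" for j in range(n)]
    exposure, outcome = [], []
    for j in range(n):
        common = dict(
            snp_id=snp_ids[j],
            chrom=chroms[j],
            pos=positions[j],
            effect_allele="A",
            other_allele="G",
            eaf=float(maf[j]),
        )
        exposure.append(
            GwasRecord(
                beta=float(beta_x[j]), se=float(se_x[j]), pvalue=float(p_x[j]),
                n=cfg.n_exposure, **common,
            )
        )
        outcome.append(
            GwasRecord(
                beta=float(beta_y[j]), se=float(se_y[j]), pvalue=float(p_y[j]),
                n=cfg.n_outcome, **common,
            )
        )
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "maf": maf,
            "gamma": gamma,
            "alpha": alpha,
            "big_gamma": big_gamma,
            "se_exposure": se_x,
            "se_outcome": se_y,
        }
    )
    return exposure, outcome, truth


#: scenario presets; each exercises one pipeline behaviour
_PRESETS: dict[str, dict] = {
    # no causal effect, no pleiotropy: type-I error calibration
    "null": dict(theta=0.0),
    # moderate positive causal effect: bias/coverage calibration
    "causal": dict(theta=0.1),
    # directional pleiotropy (mean alpha > 0): exercises the Egger intercept
    # test; 0.03 log-odds is a ~3-sigma signal against the analytic intercept
    # SE at the default design
    "directional_pleiotropy": dict(theta=0.1, pleiotropy_mean=0.03, pleiotropy_sd=0.01),
    # zero-mean pleiotropy: IVW stays unbiased but Q inflates
    "balanced_pleiotropy": dict(theta=0.1, pleiotropy_sd=0.02),
    # strong effect heterogeneity across instruments
    "heterogeneous": dict(theta=0.1, pleiotropy_sd=0.05),
    # per-SNP noncentrality near 10, straddling the F > 10 screen
    "weak_instruments": dict(
        theta=0.1, n_exposure=20_000, n_snps=50, total_r2=50 * 10 / 20_000
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A documented scenario configuration; override any field by keyword."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; known: {sorted(_PRESETS)}"
        )
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


def preset_names() -> list[str]:
    return sorted(_PRESETS)
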