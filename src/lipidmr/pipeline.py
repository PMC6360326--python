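"""Config-driven analysis pipeline: one exposure at a time against one outcome.

Mirrors the full study workflow per exposure — instrument selection,
harmonization, exclusion of outcome-associated instruments, instrument
strength screening, the estimator suite, heterogeneity, and the sensitivity
battery — and consolidates everything into a single report table. All
filtering counts are logged as machine-parseable key=value events and every
intermediate table is written to the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import sensitivity as sens
from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .instrument_selection import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW_BP,
    GENOME_WIDE_P,
    compute_strengths,
    exclude_outcome_associated,
    select_instruments,
)
from .mr_estimators import MREstimate, egger, heterogeneity, ivw, weighted_median
from .summary_data import harmonize, read_summary_table

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("ivw_fixed", "ivw_random", "egger", "weighted_median")


@dataclass(frozen=True)
class ExposureSpec:
    name: str
    path: str
    sd_unit: float | None = None  # exposure SD in mg/dL


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    path: str
    n: int | None = None
    n_cases: int | None = None


@dataclass
class AnalysisConfig:
    """Everything needed to run the per-exposure MR workflow."""

    exposures: list[ExposureSpec]
    outcome: OutcomeSpec
    output_dir: str
    population: str = ""
    p_threshold: float = GENOME_WIDE_P
    alpha: float = 0.05
    window_bp: int = DEFAULT_WINDOW_BP
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    methods: tuple[str, ...] = ("ivw_fixed", "ivw_random")
    seed: int | None = None
    n_boot: int = 10_000
    outlier_beta_x: float = sens.DEFAULT_OUTLIER_BETA_X
    run_sensitivity: bool = True

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ConfigurationError(f"unknown method {m!r}; known: {KNOWN_METHODS}")
        if "weighted_median" in self.methods and self.seed is None:
            raise ConfigurationError("weighted_median requested but no seed given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
        outcome = OutcomeSpec(**raw.pop("outcome"))
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(exposures=exposures, outcome=outcome, **raw)


def _event(**kv) -> None:
    logger.info(" ".join(f"{k}={v}" for k, v in kv.items()))


def _report_row(
    cfg: AnalysisConfig,
    exposure: str,
    est: MREstimate,
    het,
    n_exposures: int,
    notes: str = "",
) -> dict:
    bonf = cfg.alpha / n_exposures
    return {
        "population": cfg.population,
        "exposure": exposure,
        "method": est.method,
        "k": est.k,
        "beta": est.beta,
        "se": est.se,
        "odds_ratio": est.odds_ratio,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "pvalue": est.pvalue,
        "q": het.q if het is not None else float("nan"),
        "q_pvalue": het.pvalue if het is not None else float("nan"),
        "i2": het.i2 if het is not None else float("nan"),
        "sig_nominal": est.pvalue < cfg.alpha,
        "sig_bonferroni": est.pvalue < bonf,
        "notes": notes,
    }


def run_analysis(cfg: AnalysisConfig) -> pd.DataFrame:
    """Run the full per-exposure workflow and return the report table.

    Also writes, under ``cfg.output_dir``: per-exposure harmonized
    instrument tables, strength tables, leave-one-out and funnel tables,
    and the consolidated ``report.tsv``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_report = read_summary_table(cfg.outcome.path)
    rows: list[dict] = []
    m = len(cfg.exposures)
    for exp_spec in cfg.exposures:
        exp_report = read_summary_table(exp_spec.path)
        _event(stage="read", exposure=exp_spec.name,
               rows=len(exp_report.records), rejected=len(exp_report.rejected))
        selected = select_instruments(
            exp_report.records,
            p_threshold=cfg.p_threshold,
            window_bp=cfg.window_bp,
            r2_threshold=cfg.r2_threshold,
        )
        _event(stage="select", exposure=exp_spec.name, selected=len(selected))
        iset = harmonize(
            selected,
            out_report.records,
            exposure_name=exp_spec.name,
            outcome_name=cfg.outcome.name,
            population=cfg.population,
            sd_unit=exp_spec.sd_unit,
        )
        dropped = len(selected) - len(iset)
        _event(stage="harmonize", exposure=exp_spec.name,
               harmonized=len(iset), dropped=dropped)
        pre_k = len(iset)
        iset = exclude_outcome_associated(iset, alpha=cfg.alpha)
        excluded = pre_k - len(iset)
        _event(stage="exclude_outcome", exposure=exp_spec.name,
               excluded=excluded, k=len(iset))
        assert len(selected) - dropped - excluded == len(iset)

        kept_ids = set(iset.snp_ids)
        strengths = compute_strengths([r for r in selected if r.snp_id in kept_ids])
        weak = sum(1 for s in strengths if s.f_stat <= 10)
        _event(stage="strength", exposure=exp_spec.name,
               total_pve=f"{sum(s.pve for s in strengths):.6g}", weak_f=weak)
        pd.DataFrame([dataclasses.asdict(s) for s in strengths]).to_csv(
            outdir / f"{exp_spec.name}_strength.tsv", sep="\t", index=False
        )
        pd.DataFrame([dataclasses.asdict(i) for i in iset]).to_csv(
            outdir / f"{exp_spec.name}_instruments.tsv", sep="\t", index=False
        )

        het = heterogeneity(iset) if len(iset) >= 2 else None
        for method in cfg.methods:
            notes = ""
            try:
                if method == "ivw_fixed":
                    est = ivw(iset, model="fixed")
                    if len(iset) == 1:
                        notes = "k=1: estimate is the single-instrument Wald ratio"
                elif method == "ivw_random":
                    est = ivw(iset, model="random")
                elif method == "egger":
                    est = egger(iset).slope
                else:
                    est = weighted_median(iset, n_boot=cfg.n_boot, seed=cfg.seed)
            except InsufficientInstrumentsError as exc:
                _event(stage="estimate", exposure=exp_spec.name,
                       method=method, skipped=f'"{exc}"')
                continue
            rows.append(_report_row(cfg, exp_spec.name, est, het, m, notes))

        if cfg.run_sensitivity and len(iset) >= 3:
            loo = sens.leave_one_out(iset)
            pd.DataFrame(
                {
                    "left_out_snp": [r.left_out_snp for r in loo],
                    "beta": [r.estimate.beta for r in loo],
                    "se": [r.estimate.se for r in loo],
                    "pvalue": [r.estimate.pvalue for r in loo],
                    "influential": [r.influential for r in loo],
                }
            ).to_csv(outdir / f"{exp_spec.name}_loo.tsv", sep="\t", index=False)
            points, ref = sens.funnel_data(iset)
            pd.DataFrame([dataclasses.asdict(p) for p in points]).assign(
                reference=ref
            ).to_csv(outdir / f"{exp_spec.name}_funnel.tsv", sep="\t", index=False)
            outliers = sens.flag_effect_outliers(iset, cfg.outlier_beta_x)
            _event(stage="sensitivity", exposure=exp_spec.name,
                   loo_flagged=sum(r.influential for r in loo),
                   effect_outliers=len(outliers))

    report = pd.DataFrame(rows)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    return report
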