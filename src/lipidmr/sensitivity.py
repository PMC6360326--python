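"""Sensitivity analyses: leave-one-out, outlier screens, funnel data,
lipid-specific instrument filtering and reverse-direction MR.

These diagnostics probe the robustness of an IVW causal estimate: LOO checks
that no single instrument drives the result; the effect-size screen flags
instruments with unusually large exposure effects (often variants of large
phenotypic consequence whose pleiotropy risk is elevated); funnel data
expose small-instrument asymmetry; lipid-specific filtering removes
instruments shared with other exposures; and reverse MR swaps the roles of
exposure and outcome to rule out reverse causation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .instrument_selection import exclude_outcome_associated, select_instruments
from .mr_estimators import MREstimate, ivw
from .summary_data import GwasRecord, InstrumentSet, harmonize

logger = logging.getLogger(__name__)

DEFAULT_LOO_CHANGE_FRACTION = 0.30
DEFAULT_OUTLIER_BETA_X = 0.40


@dataclass(frozen=True)
class LooRecord:
    """One leave-one-out replicate: the estimate without ``left_out_snp``."""

    left_out_snp: str
    estimate: MREstimate
    influential: bool = False


@dataclass(frozen=True)
class FunnelPoint:
    """Per-SNP Wald ratio against its precision (1/ratio SE)."""

    snp_id: str
    ratio: float
    precision: float


def leave_one_out(
    iset: InstrumentSet,
    change_fraction: float = DEFAULT_LOO_CHANGE_FRACTION,
    alpha: float = 0.05,
) -> list[LooRecord]:
    """Fixed-effects IVW excluding each instrument in turn.

    A left-out SNP is flagged influential when its exclusion moves the
    estimate by more than ``change_fraction`` of the full-set estimate's
    magnitude, or flips significance at ``alpha``.
    """
    k = len(iset)
    if k < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs k >= 3, got {k}")
    full = ivw(iset, model="fixed")
    records = []
    for inst in iset:
        est = ivw(iset.drop([inst.snp_id]), model="fixed")
        big_change = (
            abs(est.beta - full.beta) > change_fraction * abs(full.beta)
            if full.beta != 0
            else est.beta != 0
        )
        sig_flip = (full.pvalue < alpha) != (est.pvalue < alpha)
        records.append(
            LooRecord(
                left_out_snp=inst.snp_id,
                estimate=est,
                influential=big_change or sig_flip,
            )
        )
    flagged = [r.left_out_snp for r in records if r.influential]
    if flagged:
        logger.info("leave_one_out: influential instruments: %s", ", ".join(flagged))
    return records


def flag_effect_outliers(
    iset: InstrumentSet, abs_beta_x_threshold: float = DEFAULT_OUTLIER_BETA_X
) -> list[str]:
    """SNPs whose absolute exposure effect exceeds the threshold."""
    return [
        i.snp_id for i in iset if abs(i.beta_exposure) > abs_beta_x_threshold
    ]


def split_outliers(
    iset: InstrumentSet, abs_beta_x_threshold: float = DEFAULT_OUTLIER_BETA_X
) -> tuple[InstrumentSet, InstrumentSet]:
    """Convenience: (full set, set without flagged outliers) for side-by-side MR."""
    flagged = flag_effect_outliers(iset, abs_beta_x_threshold)
    return iset, iset.drop(flagged)


def lipid_specific_filter(
    target_instruments: Sequence[str],
    other_lipid_instruments: Sequence[Sequence[str]],
) -> list[str]:
    """Instruments unique to the target exposure, order preserved.

    Removes any target instrument also selected for one of the other
    exposures, so the remaining instruments act on the outcome through the
    target lipid specifically.
    """
    shared = set()
    for other in other_lipid_instruments:
        shared.update(other)
    return [s for s in target_instruments if s not in shared]


def funnel_data(iset: InstrumentSet) -> tuple[list[FunnelPoint], float]:
    """Per-SNP ratios and precisions plus the IVW reference-line value."""
    points = []
    for inst in iset:
        if inst.beta_exposure == 0:
            raise UndefinedRatioError(f"zero exposure beta for {inst.snp_id}")
        points.append(
            FunnelPoint(
                snp_id=inst.snp_id,
                ratio=inst.beta_outcome / inst.beta_exposure,
                precision=abs(inst.beta_exposure) / inst.se_outcome,
            )
        )
    reference = ivw(iset, model="fixed").beta
    return points, reference


def reverse_mr(
    outcome_as_exposure: Sequence[GwasRecord],
    exposure_as_outcome: Sequence[GwasRecord],
    p_threshold: float = 5e-8,
    alpha: float = 0.05,
    **harmonize_kwargs,
) -> MREstimate:
    """Reverse-direction MR: outcome trait as exposure, exposure as outcome.

    Runs the full pipeline with roles swapped — select, harmonize, exclude
    outcome-associated, fixed-effects IVW. With a single surviving
    instrument the result is the Wald ratio (IVW with k=1).
    """
    selected = select_instruments(outcome_as_exposure, p_threshold=p_threshold)
    iset = harmonize(selected, exposure_as_outcome, **harmonize_kwargs)
    iset = exclude_outcome_associated(iset, alpha=alpha)
    return ivw(iset, model="fixed")
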