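"""Instrument selection: clumping, outcome-pleiotropy exclusion, PVE and F.

Valid instruments must be genome-wide significant for the exposure and
approximately independent of one another. Independence is enforced by greedy
clumping: rank significant SNPs by p-value, keep the best, discard its
neighbours (within a distance window, or by r² when an LD matrix is
supplied), and repeat. Instrument strength is summarised per SNP by the
proportion of exposure variance explained,

    PVE = beta^2 / (beta^2 + n * se^2),

and the corresponding F statistic, F = PVE * (n - 2) / (1 - PVE); F > 10 is
the conventional weak-instrument screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import (
    EmptySelectionError,
    EmptySetError,
    InvalidSampleSizeError,
)
from .summary_data import GwasRecord, InstrumentSet

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_R2_THRESHOLD = 0.001
WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-instrument variance explained and F statistic."""

    snp_id: str
    pve: float
    f_stat: float


def select_instruments(
    records: Sequence[GwasRecord],
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = DEFAULT_WINDOW_BP,
    ld: Mapping[str, Mapping[str, float]] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[GwasRecord]:
    """Greedy clumping of genome-wide-significant SNPs.

    SNPs passing ``p_threshold`` are ranked by ascending p (ties broken by
    snp_id, so the output is independent of input row order). The best
    remaining SNP is kept and all others on the same chromosome within
    ``window_bp`` are discarded; when ``ld`` is supplied, the criterion is
    r² ≥ ``r2_threshold`` instead. Output is ordered by chromosome then
    position.
    """
    passing = [r for r in records if r.pvalue <= p_threshold]
    if not passing:
        raise EmptySelectionError(
            f"no SNP passes p <= {p_threshold:g} (best of {len(records)} records)"
        )
    for r in passing:
        if r.chrom is None or r.pos is None:
            raise ValueError(f"clumping requires chrom/pos; missing for {r.snp_id}")
    ranked = sorted(passing, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[GwasRecord] = []
    discarded: set[str] = set()
    for cand in ranked:
        if cand.snp_id in discarded:
            continue
        kept.append(cand)
        for other in ranked:
            if other.snp_id == cand.snp_id or other.snp_id in discarded:
                continue
            if ld is not None:
                r2 = ld.get(cand.snp_id, {}).get(other.snp_id, 0.0)
                if r2 >= r2_threshold:
                    discarded.add(other.snp_id)
            elif other.chrom == cand.chrom and abs(other.pos - cand.pos) <= window_bp:
                discarded.add(other.snp_id)
    kept.sort(key=lambda r: (_chrom_key(r.chrom), r.pos))
    logger.info(
        "select_instruments: %d passing, %d kept after clumping", len(passing), len(kept)
    )
    return kept


def _chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)


def exclude_outcome_associated(
    iset: InstrumentSet, alpha: float = 0.05
) -> InstrumentSet:
    """Drop instruments marginally associated with the outcome.

    An instrument directly associated with the outcome at
    p < alpha / k (Bonferroni over the k pre-removal instruments) is a likely
    pleiotropy violation and is removed. The threshold uses the *pre-removal*
    k. The removal list is logged.
    """
    k = len(iset)
    if k < 1:
        raise EmptySetError("exclude_outcome_associated on an empty instrument set")
    threshold = alpha / k
    removed = [i.snp_id for i in iset if i.outcome_p < threshold]
    if removed:
        logger.info(
            "exclude_outcome_associated: removed %d of %d at p < %g: %s",
            len(removed), k, threshold, ", ".join(removed),
        )
    result = iset.drop(removed)
    if len(result) == 0:
        raise EmptySetError(
            f"all {k} instruments associated with the outcome at p < {threshold:g}"
        )
    return result


def compute_strength(record: GwasRecord) -> InstrumentStrength:
    """PVE and F statistic for one instrument from summary statistics."""
    if record.n is None or record.n <= 2:
        raise InvalidSampleSizeError(
            f"{record.snp_id}: need n > 2 for PVE/F, got {record.n}"
        )
    b2 = record.beta**2
    pve = b2 / (b2 + record.n * record.se**2)
    f_stat = pve * (record.n - 2) / (1.0 - pve)
    return InstrumentStrength(snp_id=record.snp_id, pve=pve, f_stat=f_stat)


def compute_strengths(records: Sequence[GwasRecord]) -> list[InstrumentStrength]:
    """Vector convenience; warns when any F is at or below the weak screen."""
    strengths = [compute_strength(r) for r in records]
    weak = [s.snp_id for s in strengths if s.f_stat <= WEAK_F_THRESHOLD]
    if weak:
        logger.warning(
            "weak instruments (F <= %g): %s", WEAK_F_THRESHOLD, ", ".join(weak)
        )
    return strengths
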