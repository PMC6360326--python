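"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lipidmr import GwasRecord, HarmonizedInstrument, InstrumentSet


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                beta=0.1, se=0.02, pvalue=None, eaf=0.3, n=100_000):
    """GwasRecord with a consistent p-value unless one is given."""
    if pvalue is None:
        from scipy.stats import norm
        pvalue = float(max(2 * norm.sf(abs(beta) / se), np.finfo(float).tiny))
    return GwasRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                      other_allele=oa, eaf=eaf, beta=beta, se=se,
                      pvalue=pvalue, n=n)


def make_instrument(snp_id="rs1", bx=0.1, sx=0.01, by=0.01, sy=0.02,
                    px=1e-20, py=0.5):
    return HarmonizedInstrument(
        snp_id=snp_id, beta_exposure=bx, se_exposure=sx,
        beta_outcome=by, se_outcome=sy, exposure_p=px, outcome_p=py,
    )


def make_set(bx, by, sy, sx=None, name="LDL"):
    """InstrumentSet from parallel arrays of effects and outcome SEs."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full_like(bx, 0.01, dtype=float) if sx is None else np.asarray(sx)
    instruments = [
        make_instrument(snp_id=f"rs{j + 1}", bx=float(bx[j]), sx=float(sx[j]),
                        by=float(by[j]), sy=float(sy[j]))
        for j in range(len(bx))
    ]
    return InstrumentSet(exposure_name=name, outcome_name="ALS",
                         instruments=instruments)


def random_set(rng, k=10, het=0.0):
    """Random instrument set; het adds per-SNP ratio heterogeneity."""
    bx = rng.uniform(0.05, 0.4, k) * rng.choice([-1, 1], k)
    sy = rng.uniform(0.005, 0.05, k)
    theta = rng.normal(0, 0.2)
    by = theta * bx + rng.normal(0, het, k) + rng.normal(0, sy)
    return make_set(bx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def homogeneous_set():
    """Five instruments whose Wald ratios are all exactly 0.25."""
    bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
    return make_set(bx, 0.25 * bx, np.full(5, 0.02))
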