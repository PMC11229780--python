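"""Shared fixtures: record builders and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from mrmediate import (HarmonizedInstrumentSet, HarmonizedPair, SimTruth,
                       SumstatRecord, simulate)


def make_record(
    snp_id: str = "rs1",
    chrom: str = "1",
    pos: int = 1000,
    effect_allele: str = "A",
    other_allele: str = "G",
    eaf: float = 0.3,
    beta: float = 0.1,
    se: float = 0.02,
    pvalue: float | None = None,
    n: int = 10_000,
) -> SumstatRecord:
    if pvalue is None:
        pvalue = float(np.clip(2 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))
    return SumstatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                         effect_allele=effect_allele, other_allele=other_allele,
                         eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n)


def make_pairs(bx, sx, by, sy) -> HarmonizedInstrumentSet:
    """Build a harmonized set directly from effect arrays."""
    records = [
        HarmonizedPair(snp_id=f"rs{j + 1}", beta_exposure=float(bx[j]),
                       se_exposure=float(sx[j]), beta_outcome=float(by[j]),
                       se_outcome=float(sy[j]), eaf=0.3,
                       n_exposure=10_000, n_outcome=10_000)
        for j in range(len(bx))
    ]
    return HarmonizedInstrumentSet(exposure_name="X", outcome_name="Y",
                                   records=records)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def pair_factory():
    return make_pairs


@pytest.fixture
def sim_dataset():
    """A default mediated-model dataset (θ1=0.4, θ2=0.5, θ3=0.1)."""
    return simulate(SimTruth(seed=42))


@pytest.fixture
def strong_truth():
    """Well-powered conditions: 50 exposure + 30 mediator SNPs at n=50k."""
    return SimTruth(n_exp=50_000, n_med=50_000, n_out=50_000, seed=42)
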