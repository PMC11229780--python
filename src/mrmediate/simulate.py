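"""Synthetic GWAS summary-statistic triplets with known structural truth.

The generator emulates the data structure consumed by the pipeline: three
summary-statistic tables (exposure, mediator, outcome) over a shared SNP
panel, with standard errors scaled by allele frequency and sample size
(se = 1/sqrt(2·maf·(1−maf)·n) for a unit-variance trait), an optional
block-exchangeable LD matrix, optional horizontal pleiotropy, and a
structural exposure→mediator→outcome model with effects (θ1, θ2, θ3) so
every estimator can be checked against ground truth.

Simulation is summary-level: observed betas are the true per-SNP effects
plus normal noise with the analytic SE — no individual-level genotypes
are drawn, which is sufficient for every summary-data method here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .sumstats import SumstatRecord, write_sumstats

#: non-palindromic effect/other allele pairs used round-robin
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth structural parameters of a synthetic dataset.

    Defaults mirror the scale of the real study inputs: a microbiome-GWAS
    sized exposure (n≈9k), a metabolite-GWAS sized mediator (n≈8k) and a
    biobank-sized binary outcome (n≈463k) analysed on the linear
    probability scale (hence tiny outcome betas and odds ratios near 1).
    """

    theta1: float = 0.4
    theta2: float = 0.5
    theta3: float = 0.1
    n_snp_exposure: int = 50
    n_snp_mediator: int = 30
    gamma: tuple[float, ...] | None = None
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_r2_range: tuple[float, float] = (0.002, 0.01)
    n_exp: int = 8956
    n_med: int = 7824
    n_out: int = 463_010
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0
    outlier_snp: str | None = None

    def __post_init__(self) -> None:
        if self.n_snp_exposure <= 0 or self.n_snp_mediator < 0:
            raise ValueError("instrument counts must be positive")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        r_lo, r_hi = self.instrument_r2_range
        if not (0.0 < r_lo <= r_hi < 1.0):
            raise ValueError("instrument_r2_range must lie within (0, 1)")
        if self.n_snp_exposure * r_hi >= 1.0:
            raise ValueError(
                "infeasible: summed per-instrument r2 would reach 1 "
                f"({self.n_snp_exposure} x {r_hi})")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ValueError("ld_rho must be in [0, 1]")

    @property
    def total_effect(self) -> float:
        return self.theta3 + self.theta1 * self.theta2


@dataclass
class SimDataset:
    """Generated exposure/mediator/outcome tables, LD, and the truth used."""

    exposure: list[SumstatRecord]
    mediator: list[SumstatRecord]
    outcome: list[SumstatRecord]
    ld: LDMatrix
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three sumstats TSVs, LD matrix and truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, recs in [("exposure", self.exposure), ("mediator", self.mediator),
                           ("outcome", self.outcome)]:
            p = outdir / f"{name}.tsv"
            write_sumstats(recs, p)
            paths[name] = p
        paths["ld"] = outdir / "ld.tsv"
        self.ld.write(paths["ld"])
        paths["truth"] = outdir / "truth.json"
        t = {k: v for k, v in vars(self.truth).items()}
        paths["truth"].write_text(json.dumps(t, indent=1, default=list))
        return paths


def _records(snp_ids, chroms, poss, eas, oas, mafs, beta, se, n) -> list[SumstatRecord]:
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return [
        SumstatRecord(snp_id=snp_ids[j], chrom=chroms[j], pos=int(poss[j]),
                      effect_allele=eas[j], other_allele=oas[j],
                      eaf=float(mafs[j]), beta=float(beta[j]), se=float(se[j]),
                      pvalue=float(p[j]), n=int(n))
        for j in range(len(snp_ids))
    ]


def simulate(truth: SimTruth) -> SimDataset:
    """Draw one synthetic dataset under the structural model.

    Exposure instruments G1 (count ``n_snp_exposure``) affect the
    exposure with effects γ; the mediator inherits θ1·γ from them and has
    its own instruments G2 (count ``n_snp_mediator``) with effects α; the
    outcome receives (θ3 + θ1·θ2)·γ from G1, θ2·α from G2, and direct
    pleiotropic effects δ ~ N(mean, sd²) on a ``pleiotropy_frac`` subset.
    Observed betas add N(0, se²) noise with the analytic SE per trait.
    Fully reproducible from ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n1, n2 = truth.n_snp_exposure, truth.n_snp_mediator
    m = n1 + n2
    snp_ids = [f"rs{j + 1:05d}" for j in range(m)]
    chroms = ["1"] * m

    # LD blocks are contiguous runs of ld_block_size SNPs, 10 kb apart
    # within a block; blocks separated by 20 Mb so they never co-clump.
    block = np.arange(m) // truth.ld_block_size
    within = np.arange(m) % truth.ld_block_size
    poss = 1_000_000 + block * 20_000_000 + within * 10_000
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    eas = [p[0] for p in pairs]
    oas = [p[1] for p in pairs]
    mafs = rng.uniform(*truth.maf_range, size=m)

    se_unit = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs))
    se_exp = se_unit / np.sqrt(truth.n_exp)
    se_med = se_unit / np.sqrt(truth.n_med)
    se_out = se_unit / np.sqrt(truth.n_out)

    # per-instrument explained variance -> effect size on its trait
    if truth.gamma is not None:
        if len(truth.gamma) != n1:
            raise ValueError("gamma length must equal n_snp_exposure")
        gamma = np.asarray(truth.gamma, float)
    else:
        r2g = rng.uniform(*truth.instrument_r2_range, size=n1)
        gamma = rng.choice([-1.0, 1.0], size=n1) * np.sqrt(
            r2g / (2.0 * mafs[:n1] * (1.0 - mafs[:n1])))
    r2a = rng.uniform(*truth.instrument_r2_range, size=n2)
    alpha = rng.choice([-1.0, 1.0], size=n2) * np.sqrt(
        r2a / (2.0 * mafs[n1:] * (1.0 - mafs[n1:])))

    true_exp = np.concatenate([gamma, np.zeros(n2)])
    true_med = np.concatenate([truth.theta1 * gamma, alpha])
    true_out = np.concatenate([(truth.theta3 + truth.theta1 * truth.theta2) * gamma,
                               truth.theta2 * alpha])
    if truth.pleiotropy_frac > 0:
        n_pleio = int(round(truth.pleiotropy_frac * m))
        idx = rng.choice(m, size=n_pleio, replace=False)
        true_out = true_out.copy()
        # directional pleiotropy acts per exposure-increasing allele, so a
        # positive mean biases the oriented Egger intercept upward rather
        # than cancelling across randomly signed instruments
        orient = np.sign(np.where(true_exp != 0, true_exp, 1.0))
        true_out[idx] += orient[idx] * rng.normal(
            truth.pleiotropy_mean, truth.pleiotropy_sd, size=n_pleio)

    obs_exp = true_exp + rng.normal(0.0, se_exp)
    obs_med = true_med + rng.normal(0.0, se_med)
    obs_out = true_out + rng.normal(0.0, se_out)

    r2 = np.eye(m)
    if truth.ld_block_size > 1:
        same_block = block[:, None] == block[None, :]
        r2 = np.where(same_block, truth.ld_rho, 0.0)
        np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(snp_ids=list(snp_ids), r2=r2, positions=[int(p) for p in poss])

    return SimDataset(
        exposure=_records(snp_ids, chroms, poss, eas, oas, mafs, obs_exp, se_exp, truth.n_exp),
        mediator=_records(snp_ids, chroms, poss, eas, oas, mafs, obs_med, se_med, truth.n_med),
        outcome=_records(snp_ids, chroms, poss, eas, oas, mafs, obs_out, se_out, truth.n_out),
        ld=ld, truth=truth,
    )


def inject_outlier(ds: SimDataset, snp_index: int, shift_in_se: float) -> SimDataset:
    """Displace one SNP's outcome beta by ``shift_in_se`` outcome SEs.

    Returns a new dataset; the truth is annotated with the displaced SNP
    so detection checks know the answer.
    """
    recs = list(ds.outcome)
    if not 0 <= snp_index < len(recs):
        raise IndexError(f"snp_index {snp_index} out of range")
    r = recs[snp_index]
    shifted = SumstatRecord(
        snp_id=r.snp_id, chrom=r.chrom, pos=r.pos,
        effect_allele=r.effect_allele, other_allele=r.other_allele,
        eaf=r.eaf, beta=r.beta + shift_in_se * r.se, se=r.se,
        pvalue=float(np.clip(2.0 * stats.norm.sf(abs((r.beta + shift_in_se * r.se) / r.se)),
                             np.finfo(float).tiny, 1.0)),
        n=r.n,
    )
    recs[snp_index] = shifted
    truth = replace(ds.truth, outlier_snp=r.snp_id if shift_in_se != 0 else None)
    return SimDataset(exposure=ds.exposure, mediator=ds.mediator,
                      outcome=recs, ld=ds.ld, truth=truth)
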