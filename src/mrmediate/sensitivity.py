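"""Sensitivity machinery: MR-PRESSO outliers, Steiger directionality, coloc.

These tools probe the instrumental-variable assumptions that the point
estimators cannot check themselves: MR-PRESSO detects horizontally
pleiotropic outlier SNPs by resampling leave-one-out residual sums of
squares; the Steiger test asks whether the instruments explain more
variance in the exposure than in the outcome (causal orientation); and
Wakefield-ABF colocalization asks whether the same causal variant drives
both traits in a region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .estimators import InsufficientInstrumentsError, MREstimate, ivw
from .sumstats import HarmonizedInstrumentSet, InputError, SumstatRecord


class DegenerateCorrectionError(RuntimeError):
    """Every instrument was flagged as an outlier; no corrected estimate."""


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """MR-PRESSO global, per-SNP outlier, and distortion test results."""

    rss_obs: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: list[str]
    distortion_p: float
    corrected: MREstimate


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized via rank-one downdates."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _subset(iv_set: HarmonizedInstrumentSet, keep: Sequence[int]) -> HarmonizedInstrumentSet:
    return HarmonizedInstrumentSet(
        exposure_name=iv_set.exposure_name, outcome_name=iv_set.outcome_name,
        records=[iv_set.records[i] for i in keep],
    )


def mr_presso(
    iv_set: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    sig: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    *Global test* — the observed RSS sums squared leave-one-out residuals
    (by_j − β̂₍₋ⱼ₎·bx_j)²; its null distribution is built by parametric
    resampling of (bx, by) from the fitted no-pleiotropy model, giving an
    empirical p with the +1 correction so p is never exactly 0.

    *Outlier test* — each SNP's observed squared residual is compared with
    its own simulated distribution; per-SNP empirical p-values are
    Bonferroni-adjusted over the instrument count, and SNPs with adjusted
    p < ``sig`` are flagged.

    *Distortion test* — the relative shift between the all-SNP and
    outlier-removed IVW estimates, referenced to the shift produced by
    removing random same-size subsets in the resampled datasets.
    """
    n = iv_set.n_snp
    if n < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires ≥ 4 SNPs")
    r = iv_set.records
    bx = np.array([p.beta_exposure for p in r])
    sx = np.array([p.se_exposure for p in r])
    by = np.array([p.beta_outcome for p in r])
    sy = np.array([p.se_outcome for p in r])
    w = 1.0 / sy**2

    def residual_test(rng: np.random.Generator, excluded: set[int]):
        """Observed and simulated per-SNP squared LOO residuals.

        ``excluded`` SNPs are left out of the no-pleiotropy model fit (their
        own residuals are judged against the slope of the retained SNPs), so
        a refinement pass can judge clean SNPs against an outlier-free null.
        """
        kept = np.array([j not in excluded for j in range(n)])
        wk = np.where(kept, w, 0.0)
        sxy_k = np.sum(wk * bx * by)
        sxx_k = np.sum(wk * bx * bx)
        beta_base = np.where(kept,
                             (sxy_k - wk * bx * by) / (sxx_k - wk * bx * bx),
                             sxy_k / sxx_k)
        resid2_obs = (by - beta_base * bx) ** 2
        bx_sim = rng.normal(bx, sx, size=(n_sim, n))
        by_sim = rng.normal(beta_base * bx, sy, size=(n_sim, n))
        sxy_s = np.sum(wk * bx_sim * by_sim, axis=1, keepdims=True)
        sxx_s = np.sum(wk * bx_sim * bx_sim, axis=1, keepdims=True)
        beta_base_sim = np.where(
            kept[None, :],
            (sxy_s - wk * bx_sim * by_sim) / (sxx_s - wk * bx_sim * bx_sim),
            sxy_s / sxx_s)
        resid2_sim = (by_sim - beta_base_sim * bx_sim) ** 2
        p_snp = (1.0 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1.0)
        return resid2_obs, resid2_sim, p_snp, bx_sim, by_sim

    rng = np.random.default_rng(seed)
    resid2_obs, resid2_sim, p_snp, bx_sim, by_sim = residual_test(rng, set())
    rss_obs = float(resid2_obs.sum())
    rss_sim = resid2_sim.sum(axis=1)
    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    p_adj = np.minimum(1.0, p_snp * n)
    out_ix = [j for j in range(n) if p_adj[j] < sig]
    if out_ix and len(out_ix) < n:
        # refinement: re-test against a null fitted without the first-pass
        # outliers, so their pull on the leave-one-out slopes cannot flag
        # clean SNPs
        _, _, p_snp, _, _ = residual_test(rng, set(out_ix))
        p_adj = np.minimum(1.0, p_snp * n)
        out_ix = [j for j in range(n) if p_adj[j] < sig]
    outlier_p = {r[j].snp_id: float(p_adj[j]) for j in range(n)}
    outliers = [r[j].snp_id for j in out_ix]

    if len(out_ix) == n:
        raise DegenerateCorrectionError("all instruments flagged as outliers")

    full_est, _ = ivw(iv_set)
    if not out_ix:
        return PressoResult(rss_obs=rss_obs, global_p=float(global_p),
                            outlier_p=outlier_p, outliers=[],
                            distortion_p=float("nan"), corrected=full_est)

    keep = [j for j in range(n) if j not in out_ix]
    corrected, _ = ivw(_subset(iv_set, keep))
    d_obs = (full_est.beta - corrected.beta) / abs(corrected.beta)

    # null distortion: remove random same-size subsets in resampled data
    n_out = len(out_ix)
    beta_all_sim = (np.sum(w * bx_sim * by_sim, axis=1)
                    / np.sum(w * bx_sim * bx_sim, axis=1))
    d_sim = np.empty(n_sim)
    for s in range(n_sim):
        drop = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[drop] = False
        b_sub = (np.sum(w[mask] * bx_sim[s, mask] * by_sim[s, mask])
                 / np.sum(w[mask] * bx_sim[s, mask] ** 2))
        d_sim[s] = (beta_all_sim[s] - b_sub) / abs(b_sub)
    distortion_p = (1.0 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1.0)

    return PressoResult(rss_obs=rss_obs, global_p=float(global_p),
                        outlier_p=outlier_p, outliers=outliers,
                        distortion_p=float(distortion_p), corrected=corrected)


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    """Directionality test comparing instrument r² in exposure vs outcome."""

    r2_exposure: float
    r2_outcome: float
    z: float
    pvalue: float
    direction: str
    inconclusive: bool = False


def steiger(
    iv_set: HarmonizedInstrumentSet,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
) -> SteigerResult:
    """Steiger test of causal orientation.

    Per-trait instrument r² sums the per-SNP squared correlations
    t²/(t² + n − 2); the test statistic compares Fisher-transformed √r²
    values scaled by the two sample sizes.  ``direction`` is "forward"
    when the instruments explain more variance in the exposure.
    """
    recs = iv_set.records
    n_exp = n_exposure if n_exposure is not None else recs[0].n_exposure
    n_out = n_outcome if n_outcome is not None else recs[0].n_outcome
    if n_exp < 10 or n_out < 10:
        raise InputError("Steiger test needs sample sizes ≥ 10")

    def trait_r2(betas, ses, n):
        t2 = (np.asarray(betas) / np.asarray(ses)) ** 2
        r2 = float(np.sum(t2 / (t2 + n - 2)))
        if r2 >= 1.0:
            r2 = 1.0 - 1e-12
        return r2

    r2_x = trait_r2([p.beta_exposure for p in recs], [p.se_exposure for p in recs], n_exp)
    r2_y = trait_r2([p.beta_outcome for p in recs], [p.se_outcome for p in recs], n_out)
    z1 = math.atanh(math.sqrt(r2_x))
    z2 = math.atanh(math.sqrt(r2_y))
    z = (z1 - z2) / math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    if z == 0:
        # exact tie: reported forward with p = 1 but flagged
        return SteigerResult(r2_x, r2_y, 0.0, 1.0, "forward", inconclusive=True)
    return SteigerResult(r2_x, r2_y, float(z), float(p),
                         "forward" if r2_x > r2_y else "reverse")


# ---------------------------------------------------------------------------
# Colocalization (Wakefield approximate Bayes factors)
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    H0 no association; H1/H2 association with trait 1/2 only; H3 two
    distinct causal variants; H4 one shared causal variant.
    """

    pp: dict[str, float]
    n_snps_region: int
    priors: tuple[float, float, float]

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


def _log_abf(beta: np.ndarray, se: np.ndarray, sd_prior: float) -> np.ndarray:
    v = se**2
    r = sd_prior**2 / (sd_prior**2 + v)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def _logdiffexp(a: float, b: float) -> float:
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    trait1: Sequence[SumstatRecord],
    trait2: Sequence[SumstatRecord],
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    sd_prior1: float = 0.15,
    sd_prior2: float = 0.2,
) -> ColocResult:
    """Single-causal-variant colocalization from summary statistics.

    Per-SNP Wakefield log-ABFs are combined over the shared SNP set into
    posterior probabilities for H0–H4 under per-SNP causal priors
    (p1, p2, p12).  Prior effect SDs default to 0.15 for a quantitative
    trait and 0.2 for a binary one.
    """
    ix1 = {r.snp_id: r for r in trait1}
    ix2 = {r.snp_id: r for r in trait2}
    shared = sorted(set(ix1) & set(ix2))
    if not shared:
        raise InputError("coloc: no shared SNPs between traits")
    if len(shared) < 10:
        import logging
        logging.getLogger("mrmediate").warning(
            "coloc: only %d shared SNPs in region", len(shared))

    b1 = np.array([ix1[s].beta for s in shared])
    s1 = np.array([ix1[s].se for s in shared])
    b2 = np.array([ix2[s].beta for s in shared])
    s2 = np.array([ix2[s].se for s in shared])
    l1 = _log_abf(b1, s1, sd_prior1)
    l2 = _log_abf(b2, s2, sd_prior2)

    p1, p2, p12 = priors
    ls1 = float(logsumexp(l1))
    ls2 = float(logsumexp(l2))
    l12 = float(logsumexp(l1 + l2))
    # sum over distinct pairs j != k equals S1*S2 - sum_j BF1_j*BF2_j
    l_cross = _logdiffexp(ls1 + ls2, l12)

    log_terms = np.array([
        0.0,
        math.log(p1) + ls1,
        math.log(p2) + ls2,
        math.log(p1) + math.log(p2) + l_cross,
        math.log(p12) + l12,
    ])
    norm = logsumexp(log_terms)
    pp = np.exp(log_terms - norm)
    labels = ["H0", "H1", "H2", "H3", "H4"]
    return ColocResult(pp={k: float(v) for k, v in zip(labels, pp)},
                       n_snps_region=len(shared), priors=priors)
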