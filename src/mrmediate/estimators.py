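"""Univariable two-sample MR estimators and heterogeneity statistics.

All estimators consume a :class:`~mrmediate.sumstats.HarmonizedInstrumentSet`
(allele-aligned per-SNP effects on exposure and outcome) and return a
method-tagged :class:`MREstimate`.  The inverse-variance-weighted (IVW)
estimator with multiplicative random effects is the primary method: a
weighted regression of outcome betas on exposure betas through the origin,
whose standard error is inflated by the Cochran-Q overdispersion factor
when the per-SNP Wald ratios are more heterogeneous than their sampling
error allows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedInstrumentSet

logger = logging.getLogger("mrmediate")

Z975 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


class EstimatorError(RuntimeError):
    """Numerical failure inside an estimator."""


@dataclass(frozen=True)
class MREstimate:
    """A method-tagged causal-effect estimate with normal-theory CI.

    ``or_scale`` holds (exp(beta), exp(ci_low), exp(ci_high)) for
    odds-ratio-style reporting of binary outcomes.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def row(self) -> dict:
        """Common report-row schema shared by all estimators."""
        orv, lo, hi = self.or_scale
        return {
            "method": self.method, "nsnp": self.n_snp,
            "beta": self.beta, "se": self.se,
            "or": orv, "or_ci_low": lo, "or_ci_high": hi,
            "pvalue": self.pvalue,
        }


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic and the overdispersion factor
    applied to the estimator's SE (1 when Q/df ≤ 1; SEs never shrink)."""

    q: float
    df: int
    pvalue: float
    scale_factor: float


def _estimate(method: str, beta: float, se: float, n_snp: int,
              dist: str = "normal", df: int = 0) -> MREstimate:
    if dist == "t":
        crit = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(beta / se), df) if se > 0 else 1.0
    else:
        crit = Z975
        p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
    return MREstimate(method=method, beta=beta, se=se,
                      ci_low=beta - crit * se, ci_high=beta + crit * se,
                      pvalue=max(p, np.finfo(float).tiny), n_snp=n_snp)


def _arrays(iv_set: HarmonizedInstrumentSet):
    r = iv_set.records
    bx = np.array([p.beta_exposure for p in r])
    sx = np.array([p.se_exposure for p in r])
    by = np.array([p.beta_outcome for p in r])
    sy = np.array([p.se_outcome for p in r])
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order delta SE sy/|bx|."""
    if bx == 0:
        raise EstimatorError("Wald ratio undefined: exposure beta is zero")
    beta = by / bx
    se = sy / abs(bx)
    return _estimate("wald_ratio", beta, se, n_snp=1)


# ---------------------------------------------------------------------------
# IVW (multiplicative random effects)
# ---------------------------------------------------------------------------

def ivw(iv_set: HarmonizedInstrumentSet) -> tuple[MREstimate, HeterogeneityResult]:
    """IVW estimate: origin-through WLS of by on bx with weights 1/sy².

    With a single SNP, delegates to :func:`wald_ratio` (and reports a
    degenerate heterogeneity result).  The multiplicative random-effects
    SE is the fixed-effect SE times max(1, sqrt(Q/df)).
    """
    n = iv_set.n_snp
    if n < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 SNP")
    bx, _, by, sy = _arrays(iv_set)
    if n == 1:
        est = wald_ratio(bx[0], 0.0, by[0], sy[0])
        het = HeterogeneityResult(q=0.0, df=0, pvalue=1.0, scale_factor=1.0)
        return (MREstimate(**{**vars(est), "method": "ivw_mre"}), het)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = n - 1
    scale = max(1.0, math.sqrt(q / df))
    het = HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)),
                              scale_factor=scale)
    return _estimate("ivw_mre", beta, se_fixed * scale, n), het


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

def _ml_profile_negloglik(beta: float, bx, sx, by, sy) -> float:
    # per-SNP true exposure effects profiled out of the bivariate-normal
    # likelihood; the concentrated residual has variance sy² + beta²·sx²
    # (variances are known constants, so no log-determinant term survives)
    v = sy**2 + beta**2 * sx**2
    return float(0.5 * np.sum((by - beta * bx) ** 2 / v))


def max_likelihood(iv_set: HarmonizedInstrumentSet) -> MREstimate:
    """Maximum-likelihood MR estimate.

    Models bx_j ~ N(γ_j, sx_j²), by_j ~ N(β·γ_j, sy_j²) with independent
    known measurement errors, profiles out the nuisance γ_j, and maximizes
    the concentrated likelihood over β.  The SE comes from the observed
    (profile) information at the maximum.  Falls back to IVW with a logged
    warning if optimization fails.
    """
    if iv_set.n_snp < 2:
        raise InsufficientInstrumentsError("maximum likelihood requires ≥ 2 SNPs")
    bx, sx, by, sy = _arrays(iv_set)
    start, _ = ivw(iv_set)
    span = 10.0 * max(1.0, abs(start.beta))
    res = optimize.minimize_scalar(
        _ml_profile_negloglik, args=(bx, sx, by, sy),
        bounds=(start.beta - span, start.beta + span),
        method="bounded", options={"xatol": 1e-12},
    )
    if not res.success or not np.isfinite(res.x):
        logger.warning("max_likelihood failed to converge; falling back to IVW")
        est, _ = ivw(iv_set)
        if not np.isfinite(est.beta):
            raise EstimatorError("maximum likelihood non-convergence")
        return MREstimate(**{**vars(est), "method": "max_likelihood"})
    beta = float(res.x)
    h = 1e-5 * max(1.0, abs(beta))
    d2 = (_ml_profile_negloglik(beta + h, bx, sx, by, sy)
          - 2.0 * res.fun
          + _ml_profile_negloglik(beta - h, bx, sx, by, sy)) / h**2
    if d2 <= 0:
        logger.warning("max_likelihood: non-positive curvature; falling back to IVW SE")
        d2 = 1.0 / ivw(iv_set)[0].se ** 2
    return _estimate("max_likelihood", beta, 1.0 / math.sqrt(d2), iv_set.n_snp)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(q, cum, v))


def weighted_median(
    iv_set: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median MR estimate.

    The estimate is the weighted 50th percentile (cumulative-weight
    interpolation) of per-SNP Wald ratios, weighted by the inverse
    first-order variance sy²/bx².  It is consistent when instruments
    carrying ≥ 50% of the weight are valid.  The SE comes from a seeded
    parametric bootstrap perturbing bx and by by their SEs.
    """
    n = iv_set.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("weighted median requires ≥ 3 SNPs")
    bx, sx, by, sy = _arrays(iv_set)
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_percentile(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r = by_b[i] / bx_b[i]
        boots[i] = _weighted_percentile(r, bx_b[i] ** 2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, n)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(
    iv_set: HarmonizedInstrumentSet,
) -> tuple[MREstimate, MREstimate, HeterogeneityResult]:
    """MR-Egger regression: WLS of by on bx *with* an intercept.

    Exposure effects are first oriented so all bx ≥ 0 (the InSIDE
    convention).  The intercept estimates average directional pleiotropy;
    its test is the pleiotropy diagnostic.  The slope is the
    pleiotropy-adjusted causal effect.  P-values use the t distribution
    with n_snp − 2 df; Rucker's Q' applies the same multiplicative
    overdispersion rule as IVW with df = n_snp − 2.
    """
    n = iv_set.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger requires ≥ 3 SNPs")
    bx, _, by, sy = _arrays(iv_set)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    # closed-form 2-parameter WLS
    sw = w.sum()
    mx, my = np.sum(w * bx) / sw, np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    sxy = np.sum(w * (bx - mx) * (by - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    df = n - 2
    scale = max(1.0, math.sqrt(q / df))
    se_slope = scale / math.sqrt(sxx)
    se_int = scale * math.sqrt(1.0 / sw + mx**2 / sxx)

    het = HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)),
                              scale_factor=scale)
    slope_est = _estimate("egger_slope", float(slope), se_slope, n, dist="t", df=df)
    int_est = _estimate("egger_intercept", float(intercept), se_int, n, dist="t", df=df)
    return slope_est, int_est, het


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------

def leave_one_out(iv_set: HarmonizedInstrumentSet) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each SNP omitted in turn."""
    if iv_set.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out requires ≥ 3 SNPs")
    out: list[tuple[str, MREstimate]] = []
    for i, pair in enumerate(iv_set.records):
        sub = HarmonizedInstrumentSet(
            exposure_name=iv_set.exposure_name, outcome_name=iv_set.outcome_name,
            records=iv_set.records[:i] + iv_set.records[i + 1:],
        )
        est, _ = ivw(sub)
        out.append((pair.snp_id, est))
    return out


def all_estimates(
    iv_set: HarmonizedInstrumentSet, seed: int = 0
) -> tuple[list[MREstimate], HeterogeneityResult]:
    """Run the full estimator battery appropriate to the instrument count."""
    est, het = ivw(iv_set)
    results = [est]
    if iv_set.n_snp >= 2:
        results.append(max_likelihood(iv_set))
    if iv_set.n_snp >= 3:
        results.append(weighted_median(iv_set, seed=seed))
        slope, inter, _ = egger(iv_set)
        results.extend([slope, inter])
    return results, het
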