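"""Mediation decomposition by two-step MR and multivariable MR (MVMR).

The structural model is exposure → mediator → outcome with a possible
direct path: writing θ1 for the exposure→mediator effect, θ2 for the
mediator→outcome effect and θ3 for the direct exposure→outcome effect,
the total causal effect is θ3 + θ1·θ2.  Two decompositions of the
indirect (mediated) effect are implemented:

* **product of coefficients** (two-step MR): θ1·θ2, with a delta-method
  standard error;
* **difference in coefficients** (MVMR): total effect minus the direct
  effect estimated by a multivariable model that instruments exposure and
  mediator jointly.

The proportion mediated is 100 × indirect / total, reported only when the
two effects agree in sign — a mediated share is not interpretable when
the indirect effect opposes the total effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import (InsufficientInstrumentsError, MREstimate, Z975, ivw)
from .instruments import LDMatrix, f_statistics, select_by_pvalue, clump
from .sumstats import HarmonizedInstrumentSet, SumstatRecord, harmonize

logger = logging.getLogger("mrmediate")


class CollinearityError(ValueError):
    """The MVMR exposure-beta matrix is rank-deficient."""


class UndefinedProportionError(ValueError):
    """Proportion mediated is undefined (zero total effect)."""


class MediationStageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"mediation stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class Effect:
    """A point estimate with its standard error."""

    beta: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z975 * self.se, self.beta + Z975 * self.se)

    @property
    def pvalue(self) -> float:
        if self.se == 0:
            return 1.0 if self.beta == 0 else 0.0
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))

    @classmethod
    def from_estimate(cls, est: MREstimate) -> "Effect":
        return cls(beta=est.beta, se=est.se)


@dataclass(frozen=True)
class Proportion:
    """Proportion mediated in percent, or NA with a reason."""

    value: float  # percent; NaN when NA
    reason: str | None = None
    over_100: bool = False

    @property
    def is_na(self) -> bool:
        return math.isnan(self.value)


# ---------------------------------------------------------------------------
# Product of coefficients (two-step MR)
# ---------------------------------------------------------------------------

def two_step_indirect(theta1: Effect, theta2: Effect, exact: bool = False) -> Effect:
    """Indirect effect θ1·θ2 with delta-method SE.

    First-order SE: sqrt(θ2²·se1² + θ1²·se2²); ``exact=True`` adds the
    exact-variance cross term se1²·se2².
    """
    if theta1.se <= 0 or theta2.se <= 0:
        raise ValueError("two_step_indirect requires positive SEs")
    var = theta2.beta**2 * theta1.se**2 + theta1.beta**2 * theta2.se**2
    if exact:
        var += theta1.se**2 * theta2.se**2
    return Effect(beta=theta1.beta * theta2.beta, se=math.sqrt(var))


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------

@dataclass
class MVMRInput:
    """Per-SNP outcome effects and a matrix of exposure effects.

    ``beta_exposures`` has one column per exposure; ``se_exposures``
    (optional, same shape) enables conditional F-statistics.
    """

    snp_ids: list[str]
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    beta_exposures: np.ndarray
    exposure_names: list[str]
    se_exposures: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_outcome = np.asarray(self.beta_outcome, float)
        self.se_outcome = np.asarray(self.se_outcome, float)
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, float))
        if self.beta_exposures.shape[0] != len(self.beta_outcome):
            self.beta_exposures = self.beta_exposures.T
        if self.se_exposures is not None:
            self.se_exposures = np.atleast_2d(np.asarray(self.se_exposures, float))
            if self.se_exposures.shape != self.beta_exposures.shape:
                self.se_exposures = self.se_exposures.T


@dataclass
class MVMRResult:
    direct: dict[str, Effect]
    q: float
    q_pvalue: float
    conditional_f: dict[str, float]
    n_snp: int


def _wls_resid(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Residual of a weighted least-squares fit of y on X (no intercept)."""
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return y - X @ coef


def mvmr_ivw(inp: MVMRInput) -> MVMRResult:
    """Multivariable IVW: WLS of outcome betas on the exposure-beta matrix.

    No intercept; weights 1/se_outcome².  Coefficient SEs carry the same
    multiplicative overdispersion rule as univariable IVW with
    df = n_snp − n_exposures.  The conditional F for each exposure
    measures the instrument signal left in its betas after projecting out
    the other exposures' betas (mean chi-square of the residual signal;
    reduces to the mean per-SNP F in the single-exposure case).
    """
    X = inp.beta_exposures
    y = inp.beta_outcome
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientInstrumentsError(
            f"MVMR needs more SNPs ({n}) than exposures + 1 ({k + 1})")
    if np.linalg.matrix_rank(X) < k:
        cors = np.corrcoef(X, rowvar=False)
        worst = max(((i, j) for i in range(k) for j in range(i + 1, k)),
                    key=lambda t: abs(cors[t]), default=(0, 0))
        raise CollinearityError(
            "exposure-beta matrix is rank deficient; near-collinear pair: "
            f"{inp.exposure_names[worst[0]]} / {inp.exposure_names[worst[1]]}")

    w = 1.0 / inp.se_outcome**2
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    df = n - k
    scale = max(1.0, math.sqrt(q / df))
    cov = np.linalg.inv(xtx) * scale**2
    ses = np.sqrt(np.diag(cov))
    direct = {name: Effect(float(b), float(s))
              for name, b, s in zip(inp.exposure_names, coef, ses)}

    cond_f: dict[str, float] = {}
    for i, name in enumerate(inp.exposure_names):
        if inp.se_exposures is None:
            cond_f[name] = float("nan")
            continue
        xi = X[:, i]
        others = np.delete(X, i, axis=1)
        d = xi if others.shape[1] == 0 else _wls_resid(xi, others, w)
        cond_f[name] = float(np.mean((d / inp.se_exposures[:, i]) ** 2))

    return MVMRResult(direct=direct, q=q,
                      q_pvalue=float(stats.chi2.sf(q, df)),
                      conditional_f=cond_f, n_snp=n)


# ---------------------------------------------------------------------------
# Proportion mediated
# ---------------------------------------------------------------------------

def proportion_mediated(total: Effect, indirect: Effect) -> Proportion:
    """100 × indirect / total when the two effects share a sign, else NA.

    Values above 100% (possible through estimation noise) are reported
    with a flag rather than truncated.
    """
    if total.beta == 0:
        raise UndefinedProportionError("total effect is zero")
    if indirect.beta == 0:
        return Proportion(value=0.0)
    if math.copysign(1.0, indirect.beta) != math.copysign(1.0, total.beta):
        return Proportion(value=float("nan"), reason="inconsistent-sign")
    pct = 100.0 * indirect.beta / total.beta
    return Proportion(value=pct, over_100=pct > 100.0)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# End-to-end mediation for one (exposure, mediator) pair
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Full mediation decomposition for one exposure/mediator/outcome trio."""

    exposure: str
    mediator: str
    outcome: str
    total_effect: Effect
    theta1: Effect
    theta2: Effect
    indirect_product: Effect
    direct_mvmr: Effect
    indirect_difference: Effect
    prop_mediated_product: Proportion
    prop_mediated_difference: Proportion
    conditional_f: dict[str, float] = field(default_factory=dict)
    q_pvalue_mvmr: float = float("nan")
    audit: dict = field(default_factory=dict)

    def row(self) -> dict:
        """Serialize in the mediation-report schema (one TSV row)."""
        def pct(p: Proportion) -> str:
            return "NA" if p.is_na else f"{p.value:.2f}"
        return {
            "exposure": self.exposure, "mediator": self.mediator,
            "outcome": self.outcome,
            "total_effect": self.total_effect.beta,
            "total_se": self.total_effect.se,
            "two_step_effect": self.indirect_product.beta,
            "two_step_se": self.indirect_product.se,
            "two_step_prop_mediated_pct": pct(self.prop_mediated_product),
            "mvmr_effect": self.indirect_difference.beta,
            "mvmr_se": self.indirect_difference.se,
            "mvmr_prop_mediated_pct": pct(self.prop_mediated_difference),
            "q_pvalue_mvmr": self.q_pvalue_mvmr,
        }


def _select_instruments(records, ld, p_threshold, r2, window_kb, min_f):
    sel = select_by_pvalue(records, p_threshold)
    if ld is not None and sel:
        sel = clump(sel, ld, r2_threshold=r2, window_kb=window_kb)
    sel, diag = f_statistics(sel, min_f=min_f)
    return sel, diag


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (InsufficientInstrumentsError, Exception) as exc:
        if isinstance(exc, MediationStageError):
            raise
        raise MediationStageError(stage, exc) from exc


def mediate(
    exposure: Sequence[SumstatRecord],
    mediator: Sequence[SumstatRecord],
    outcome: Sequence[SumstatRecord],
    ld: LDMatrix | None = None,
    *,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
    p_threshold_exposure: float = 1e-5,
    p_threshold_mediator: float = 5e-8,
    clump_r2: float = 0.01,
    clump_window_kb: int = 10_000,
    min_f: float = 10.0,
    min_conditional_f: float = 10.0,
    delta_exact: bool = False,
) -> MediationResult:
    """Run the full mediation decomposition for one trio of traits.

    Steps: instrument the exposure and the mediator; estimate θ1
    (exposure→mediator, exposure instruments), θ2 (mediator→outcome,
    mediator instruments) and the total effect (exposure→outcome,
    exposure instruments) by IVW; form the product indirect effect with
    delta-method SE; fit the MVMR model on the union of instruments for
    the direct effect; form the difference indirect effect; report both
    proportions mediated.
    """
    exp_iv, exp_diag = _stage("exposure-instruments", _select_instruments,
                              exposure, ld, p_threshold_exposure,
                              clump_r2, clump_window_kb, min_f)
    med_iv, med_diag = _stage("mediator-instruments", _select_instruments,
                              mediator, ld, p_threshold_mediator,
                              clump_r2, clump_window_kb, min_f)
    # step-2 instruments must act on the outcome only through the mediator;
    # SNPs that are themselves exposure instruments reach the outcome via the
    # direct exposure path too, so they are excluded from step 2
    exposure_hits = {r.snp_id for r in select_by_pvalue(exposure, p_threshold_exposure)}
    n_before = len(med_iv)
    med_iv = [r for r in med_iv if r.snp_id not in exposure_hits]
    if len(med_iv) < n_before:
        logger.info("step 2: excluded %d exposure-associated SNP(s) from "
                    "mediator instruments", n_before - len(med_iv))
    if not exp_iv:
        raise MediationStageError("exposure-instruments",
                                  InsufficientInstrumentsError("no instruments"))
    if not med_iv:
        raise MediationStageError("mediator-instruments",
                                  InsufficientInstrumentsError("no instruments"))

    step1 = _stage("step1", harmonize, exp_iv, mediator,
                   exposure_name=exposure_name, outcome_name=mediator_name)
    theta1 = Effect.from_estimate(_stage("step1", ivw, step1)[0])

    step2 = _stage("step2", harmonize, med_iv, outcome,
                   exposure_name=mediator_name, outcome_name=outcome_name)
    theta2 = Effect.from_estimate(_stage("step2", ivw, step2)[0])

    total_set = _stage("total", harmonize, exp_iv, outcome,
                       exposure_name=exposure_name, outcome_name=outcome_name)
    total = Effect.from_estimate(_stage("total", ivw, total_set)[0])

    indirect_prod = two_step_indirect(theta1, theta2, exact=delta_exact)

    mvmr_input = _stage("mvmr", build_mvmr_input,
                        outcome, [exposure, mediator],
                        [exposure_name, mediator_name],
                        snp_ids={r.snp_id for r in exp_iv} | {r.snp_id for r in med_iv})
    mvmr = _stage("mvmr", mvmr_ivw, mvmr_input)
    direct = mvmr.direct[exposure_name]
    indirect_diff = Effect(
        beta=total.beta - direct.beta,
        se=math.sqrt(total.se**2 + direct.se**2),
    )
    for name, f in mvmr.conditional_f.items():
        if f == f and f < min_conditional_f:
            logger.warning("conditional F for %s is %.2f (< %g)", name, f,
                           min_conditional_f)

    prop_prod = proportion_mediated(total, indirect_prod)
    prop_diff = proportion_mediated(total, indirect_diff)

    return MediationResult(
        exposure=exposure_name, mediator=mediator_name, outcome=outcome_name,
        total_effect=total, theta1=theta1, theta2=theta2,
        indirect_product=indirect_prod, direct_mvmr=direct,
        indirect_difference=indirect_diff,
        prop_mediated_product=prop_prod, prop_mediated_difference=prop_diff,
        conditional_f=mvmr.conditional_f, q_pvalue_mvmr=mvmr.q_pvalue,
        audit={
            "n_iv_exposure": len(exp_iv), "n_iv_mediator": len(med_iv),
            "mean_f_exposure": exp_diag.mean_f, "mean_f_mediator": med_diag.mean_f,
            "n_snp_step1": step1.n_snp, "n_snp_step2": step2.n_snp,
            "n_snp_total": total_set.n_snp, "n_snp_mvmr": mvmr.n_snp,
        },
    )


def build_mvmr_input(
    outcome: Sequence[SumstatRecord],
    exposures: Sequence[Sequence[SumstatRecord]],
    exposure_names: Sequence[str],
    snp_ids: set[str] | None = None,
) -> MVMRInput:
    """Assemble an MVMR design aligned to the outcome's effect alleles.

    Each exposure is harmonized *against the outcome* (so every trait is
    expressed on the outcome's allele orientation); rows are the SNPs
    present in the outcome and in every exposure, optionally restricted
    to ``snp_ids`` (typically the union of instrument sets).
    """
    out_recs = [r for r in outcome if snp_ids is None or r.snp_id in snp_ids]
    aligned: list[dict[str, tuple[float, float]]] = []
    for recs in exposures:
        sub = [r for r in recs if snp_ids is None or r.snp_id in snp_ids]
        h = harmonize(out_recs, sub)  # orient each exposure to outcome alleles
        aligned.append({p.snp_id: (p.beta_outcome, p.se_outcome) for p in h.records})
    out_ix = {r.snp_id: r for r in out_recs}
    shared = sorted(set(out_ix) & set.intersection(*(set(a) for a in aligned)))
    if not shared:
        raise InsufficientInstrumentsError("no SNPs shared across MVMR traits")
    beta_x = np.array([[a[s][0] for a in aligned] for s in shared])
    se_x = np.array([[a[s][1] for a in aligned] for s in shared])
    return MVMRInput(
        snp_ids=shared,
        beta_outcome=np.array([out_ix[s].beta for s in shared]),
        se_outcome=np.array([out_ix[s].se for s in shared]),
        beta_exposures=beta_x,
        exposure_names=list(exposure_names),
        se_exposures=se_x,
    )
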