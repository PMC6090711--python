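"""Two-sample Mendelian randomisation from per-variant GWAS summary statistics.

Implements the estimator family used to interrogate the causal effect of
circulating 25-hydroxyvitamin D (25-OHD) on colorectal cancer risk from
harmonized per-variant effect estimates: the inverse-variance-weighted (IVW)
average of Wald ratios, MR-Egger regression with its pleiotropy intercept
test, simple and weighted median estimators with parametric-bootstrap
standard errors, heterogeneity-penalized re-weighting, and robust
(Tukey-biweight) refits of the IVW and Egger regressions.

All causal estimates are on the log-odds scale per unit increase of the
(log-transformed) exposure and are exponentiated to odds ratios for
reporting.  Variants are assumed independent (no LD) — the usual two-sample
summary MR setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("vitdmr")

#: CI multiplier for 95% normal-theory intervals.
Z95 = 1.96

#: Significance threshold for causal estimates and the Egger intercept test.
ALPHA_CAUSAL = 0.05

#: Heterogeneity is flagged at this Cochran-Q p-value threshold.
ALPHA_HET = 0.10

#: Tukey biweight 95%-efficiency tuning constant for the robust refits.
TUKEY_C = 4.685

#: Multiplier on the per-variant heterogeneity tail probability used for
#: weight penalization: w_k -> w_k * min(1, 20 * p_k).
PENALTY_SCALE = 20.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSummary:
    """Harmonizable per-variant effect estimates from the two GWAS.

    ``beta_exposure`` is the per-allele effect on log-transformed 25-OHD
    (exposure GWAS scale), ``beta_outcome`` the per-allele log-odds effect
    on colorectal cancer.  After :func:`harmonize` all effects are oriented
    to the 25-OHD-increasing allele, so ``beta_exposure > 0``.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    gene_label: str = ""
    chromosome: int = 0
    effect_allele: str = "?"
    other_allele: str = "?"

    def __post_init__(self) -> None:
        if not (self.se_exposure > 0):
            raise ValueError(
                f"{self.variant_id}: se_exposure must be > 0, got {self.se_exposure}"
            )
        if not (self.se_outcome > 0):
            raise ValueError(
                f"{self.variant_id}: se_outcome must be > 0, got {self.se_outcome}"
            )


@dataclass(frozen=True)
class RatioEstimate:
    """Single-variant Wald ratio with first-order (delta-method) SE."""

    variant_id: str
    ratio: float
    ratio_se: float
    iv_weight: float


@dataclass(frozen=True)
class MRResult:
    """A causal estimate on the log-OR scale with diagnostics.

    ``intercept`` fields are populated only for Egger-type methods.
    """

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    n_variants: int
    q_stat: float | None = None
    p_het: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "n_variants": self.n_variants,
            "q": self.q_stat,
            "p_het": self.p_het,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
        }


def _ci_or(beta: float, se: float) -> tuple[float, float, float]:
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def _p_normal(beta: float, se: float) -> float:
    tiny = float(np.finfo(float).tiny)  # keep p in (0, 1] under underflow
    if se == 0:
        return tiny if beta != 0 else 1.0
    return max(float(2.0 * stats.norm.sf(abs(beta) / se)), tiny)


# ---------------------------------------------------------------------------
# Harmonization and per-variant ratios
# ---------------------------------------------------------------------------

def harmonize(variants: Iterable[VariantSummary]) -> list[VariantSummary]:
    """Orient every variant to its exposure-increasing allele.

    Rows with ``beta_exposure < 0`` have both betas sign-flipped and the
    effect/other allele labels swapped.  Rows with ``beta_exposure == 0``
    have no defined orientation and are dropped with a warning.  Duplicate
    variant ids are an error.  Idempotent; input order preserved.
    """
    out: list[VariantSummary] = []
    seen: set[str] = set()
    for v in variants:
        if v.variant_id in seen:
            raise ValueError(f"duplicate variant_id {v.variant_id!r}")
        seen.add(v.variant_id)
        if v.beta_exposure == 0:
            logger.warning(
                "dropping %s: beta_exposure is 0, allele orientation undefined",
                v.variant_id,
            )
            continue
        if v.beta_exposure < 0:
            v = replace(
                v,
                beta_exposure=-v.beta_exposure,
                beta_outcome=-v.beta_outcome,
                effect_allele=v.other_allele,
                other_allele=v.effect_allele,
            )
        out.append(v)
    return out


def wald_ratio(v: VariantSummary) -> RatioEstimate:
    """Single-variant causal ratio ``beta_outcome / beta_exposure``.

    The SE is first-order delta with exposure-side uncertainty ignored
    (``se_outcome / |beta_exposure|``), consistent with the IVW SE below
    which involves only the outcome-side variances.
    """
    if v.beta_exposure == 0:
        raise ValueError(f"{v.variant_id}: beta_exposure is 0, ratio undefined")
    return RatioEstimate(
        variant_id=v.variant_id,
        ratio=v.beta_outcome / v.beta_exposure,
        ratio_se=v.se_outcome / abs(v.beta_exposure),
        iv_weight=v.beta_exposure**2 / v.se_outcome**2,
    )


def _arrays(variants: Sequence[VariantSummary]):
    x = np.array([v.beta_exposure for v in variants], dtype=float)
    y = np.array([v.beta_outcome for v in variants], dtype=float)
    sy = np.array([v.se_outcome for v in variants], dtype=float)
    return x, y, sy


def cochran_q(
    ratios: np.ndarray, weights: np.ndarray, beta: float
) -> tuple[float, float]:
    """Cochran's Q of per-variant ratios around ``beta`` and its chi2 p."""
    q = float(np.sum(weights * (ratios - beta) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, p


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw_estimate(
    variants: Sequence[VariantSummary],
    weights: np.ndarray | None = None,
    method_label: str = "ivw",
) -> MRResult:
    """Inverse-variance-weighted causal estimate.

    beta = sum(X_k Y_k / s_yk^2) / sum(X_k^2 / s_yk^2),
    se   = sqrt(1 / sum(X_k^2 / s_yk^2)),

    equivalently a weighted average of Wald ratios with weights
    ``X_k^2 / s_yk^2``.  ``weights`` may override the IV weights (used by
    the penalized variant); the SE is then ``sqrt(1 / sum(weights))``.
    """
    if len(variants) == 0:
        raise ValueError("ivw_estimate requires at least one variant")
    x, y, sy = _arrays(variants)
    if np.any(x == 0):
        raise ValueError("beta_exposure of 0 encountered; harmonize() drops these")
    ratios = y / x
    w = x**2 / sy**2 if weights is None else np.asarray(weights, dtype=float)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    or_, lo, hi = _ci_or(beta, se)
    q, p_het = cochran_q(ratios, w, beta)
    return MRResult(
        method=method_label,
        beta=beta,
        se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=_p_normal(beta, se),
        n_variants=len(variants),
        q_stat=q,
        p_het=p_het,
    )


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger_estimate(
    variants: Sequence[VariantSummary],
    weights: np.ndarray | None = None,
    overdispersion_floor: bool = True,
    method_label: str = "egger",
) -> MRResult:
    """MR-Egger: weighted regression of Y_k on X_k with a free intercept.

    Weights are ``1 / s_yk^2`` (optionally penalized).  The intercept
    estimates the average directional pleiotropic effect; its ``P < 0.05``
    test flags unbalanced pleiotropy.  SEs use a multiplicative
    overdispersion scale floored at 1 when ``overdispersion_floor`` (the
    convention of the reference summary-MR software); set it to False for
    purely fixed-effect SEs.
    """
    if len(variants) < 2:
        raise ValueError("egger_estimate requires at least 2 variants")
    x, y, sy = _arrays(variants)
    if np.any(x <= 0):
        raise ValueError("egger_estimate requires harmonized input (beta_exposure > 0)")
    w = 1.0 / sy**2 if weights is None else np.asarray(weights, dtype=float)
    design = sm.add_constant(x)
    fit = sm.WLS(y, design, weights=w).fit()
    k = len(variants)
    if k > 2:
        # fit.scale is the weighted residual variance Q_egger / (k - 2)
        scale = max(1.0, fit.scale) if overdispersion_floor else fit.scale
        cov = np.asarray(fit.cov_params()) / fit.scale * scale
        q_egger = float(fit.scale * (k - 2))
        p_het = float(stats.chi2.sf(q_egger, k - 2))
    else:  # saturated two-point fit: zero residual, fixed-effect SEs only
        cov = np.asarray(fit.normalized_cov_params)
        q_egger, p_het = 0.0, float("nan")
    beta = float(fit.params[1])
    se = float(np.sqrt(cov[1, 1]))
    intercept = float(fit.params[0])
    intercept_se = float(np.sqrt(cov[0, 0]))
    or_, lo, hi = _ci_or(beta, se)
    return MRResult(
        method=method_label,
        beta=beta,
        se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=_p_normal(beta, se),
        n_variants=k,
        q_stat=q_egger,
        p_het=p_het,
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_p=_p_normal(intercept, intercept_se),
    )


# ---------------------------------------------------------------------------
# Median estimators
# ---------------------------------------------------------------------------

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight interpolated 50th percentile of the ratios.

    Weights are normalized to sum 1; the percentile position of the j-th
    sorted ratio is ``cumsum_j - w_j / 2`` and the estimate is the linear
    interpolation of the sorted ratios at position 0.5.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    positions = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, positions, r))


def median_estimate(
    variants: Sequence[VariantSummary],
    weighting: str = "weighted",
    n_boot: int = 10_000,
    seed: int | None = None,
    penalize: bool = False,
) -> MRResult:
    """Simple or weighted median of the per-variant Wald ratios.

    ``simple`` uses equal weights, ``weighted`` the IV weights
    ``X_k^2 / s_yk^2`` (optionally heterogeneity-penalized).  The SE comes
    from a parametric bootstrap: each ratio is resampled from
    ``Normal(ratio_k, ratio_se_k)`` ``n_boot`` times (seeded; draws are
    keyed to variants in variant_id order, so the estimate is invariant to
    input row order) and the SD of the resampled medians is reported.
    """
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(variants) < 3:
        raise ValueError("median_estimate requires at least 3 variants")
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; bootstrap SE will be noisy", n_boot)
    if seed is None:
        raise ValueError("median_estimate requires an explicit bootstrap seed")

    est = [wald_ratio(v) for v in variants]
    ratios = np.array([e.ratio for e in est])
    ratio_se = np.array([e.ratio_se for e in est])
    if weighting == "simple":
        w = np.ones(len(variants))
        label = "simple_median"
    else:
        w = np.array([e.iv_weight for e in est])
        label = "weighted_median"
    if penalize:
        ref = _weighted_median(ratios, w)
        w = w * _penalty_multipliers(ratios, np.array([e.iv_weight for e in est]), ref)
        label = f"penalized_{label}"

    beta = _weighted_median(ratios, w)

    # per-variant keyed resampling: draw in variant_id order
    id_order = np.argsort(np.array([e.variant_id for e in est]))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_boot, len(variants)))
    boot_ratios = ratios[id_order] + ratio_se[id_order] * noise
    w_sorted = w[id_order]
    boot = np.array([_weighted_median(br, w_sorted) for br in boot_ratios])
    se = float(boot.std(ddof=1))

    or_, lo, hi = _ci_or(beta, se)
    return MRResult(
        method=label,
        beta=beta,
        se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=_p_normal(beta, se),
        n_variants=len(variants),
    )


# ---------------------------------------------------------------------------
# Penalization and robust refits
# ---------------------------------------------------------------------------

def _penalty_multipliers(
    ratios: np.ndarray, iv_weights: np.ndarray, reference_beta: float
) -> np.ndarray:
    q_contrib = iv_weights * (ratios - reference_beta) ** 2
    p_k = stats.chi2.sf(q_contrib, 1)
    return np.minimum(1.0, PENALTY_SCALE * p_k)


def penalize_weights(
    variants: Sequence[VariantSummary],
    reference_beta: float | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Heterogeneity-penalized weights ``w_k * min(1, 20 * p_k)``.

    ``p_k`` is the upper-tail chi2(1) probability of the variant's
    heterogeneity contribution ``iv_weight_k * (ratio_k - reference)^2``
    around ``reference_beta`` (default: the unpenalized IVW estimate).
    ``weights`` chooses which weights to penalize (default: the IV
    weights); homogeneous variants keep full weight.
    """
    est = [wald_ratio(v) for v in variants]
    ratios = np.array([e.ratio for e in est])
    iv_w = np.array([e.iv_weight for e in est])
    if reference_beta is None:
        reference_beta = ivw_estimate(list(variants)).beta
    base = iv_w if weights is None else np.asarray(weights, dtype=float)
    return base * _penalty_multipliers(ratios, iv_w, reference_beta)


def penalized_ivw_estimate(variants: Sequence[VariantSummary]) -> MRResult:
    w = penalize_weights(variants)
    return ivw_estimate(variants, weights=w, method_label="penalized_ivw")


def penalized_egger_estimate(variants: Sequence[VariantSummary]) -> MRResult:
    x, _, sy = _arrays(variants)
    ref = egger_estimate(variants).beta
    w = penalize_weights(variants, reference_beta=ref, weights=1.0 / sy**2)
    return egger_estimate(variants, weights=w, method_label="penalized_egger")


def robust_estimate(
    variants: Sequence[VariantSummary],
    method: str = "ivw",
    tukey_c: float = TUKEY_C,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MRResult:
    """Robust refit of the IVW or Egger regression.

    The weighted regression is transformed to homoskedastic form (divide
    response and design by ``s_yk``) and refit by iteratively reweighted
    M-estimation with Tukey's biweight (95%-efficiency constant 4.685),
    seeded from the least-squares solution.  Point estimates downweight
    outlying variants; SEs are the robust asymptotic ones.
    """
    if method not in ("ivw", "egger"):
        raise ValueError(f"unknown robust method {method!r}")
    x, y, sy = _arrays(variants)
    if method == "egger":
        if len(variants) < 2:
            raise ValueError("robust egger requires at least 2 variants")
        if np.any(x <= 0):
            raise ValueError("robust egger requires harmonized input")
        design = sm.add_constant(x) / sy[:, None]
    else:
        if len(variants) == 0:
            raise ValueError("robust ivw requires at least one variant")
        design = (x / sy)[:, None]
    fit = sm.RLM(y / sy, design, M=sm.robust.norms.TukeyBiweight(c=tukey_c)).fit(
        maxiter=max_iter, tol=tol
    )
    if not fit.fit_history["params"] or len(fit.fit_history["params"]) >= max_iter:
        raise RuntimeError(
            f"robust {method} did not converge in {max_iter} iterations; "
            f"final params {fit.params}"
        )
    slope_idx = 1 if method == "egger" else 0
    beta = float(fit.params[slope_idx])
    se = float(fit.bse[slope_idx])
    or_, lo, hi = _ci_or(beta, se)
    ratios = y / x
    q, p_het = cochran_q(ratios, x**2 / sy**2, beta) if method == "ivw" else (None, None)
    kwargs = {}
    if method == "egger":
        kwargs = {
            "intercept": float(fit.params[0]),
            "intercept_se": float(fit.bse[0]),
            "intercept_p": _p_normal(float(fit.params[0]), float(fit.bse[0])),
        }
    return MRResult(
        method=f"robust_{method}",
        beta=beta,
        se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=_p_normal(beta, se),
        n_variants=len(variants),
        q_stat=q,
        p_het=p_het,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Method dispatch and nested-subset sensitivity analysis
# ---------------------------------------------------------------------------

METHODS = (
    "ivw",
    "egger",
    "simple_median",
    "weighted_median",
    "penalized_ivw",
    "penalized_egger",
    "penalized_weighted_median",
    "robust_ivw",
    "robust_egger",
)


def estimate(
    variants: Sequence[VariantSummary],
    method: str,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MRResult:
    """Dispatch a single named estimator (labels as in :data:`METHODS`)."""
    method = method.replace("-", "_")
    if method == "ivw":
        return ivw_estimate(variants)
    if method == "egger":
        return egger_estimate(variants)
    if method == "simple_median":
        return median_estimate(variants, "simple", n_boot=n_boot, seed=seed)
    if method == "weighted_median":
        return median_estimate(variants, "weighted", n_boot=n_boot, seed=seed)
    if method == "penalized_ivw":
        return penalized_ivw_estimate(variants)
    if method == "penalized_egger":
        return penalized_egger_estimate(variants)
    if method == "penalized_weighted_median":
        return median_estimate(
            variants, "weighted", n_boot=n_boot, seed=seed, penalize=True
        )
    if method == "robust_ivw":
        return robust_estimate(variants, "ivw")
    if method == "robust_egger":
        return robust_estimate(variants, "egger")
    raise ValueError(f"unknown method {method!r}")


def subset_sensitivity(
    variants: Sequence[VariantSummary],
    order: Sequence[str],
    methods: Sequence[str] = ("ivw",),
    n_boot: int = 10_000,
    seed: int | None = None,
) -> list[MRResult]:
    """Refit on each nested prefix of ``order`` (sizes 2, 3, ..., k).

    Mirrors the sensitivity analysis that starts from the two
    synthesis-pathway variants and sequentially adds the remaining
    instruments.  Unknown variant ids are an error.
    """
    by_id = {v.variant_id: v for v in variants}
    unknown = [vid for vid in order if vid not in by_id]
    if unknown:
        raise ValueError(f"unknown variant ids in order: {unknown}")
    if len(order) < 2:
        raise ValueError("order must list at least 2 variant ids")
    results: list[MRResult] = []
    for size in range(2, len(order) + 1):
        subset = [by_id[vid] for vid in order[:size]]
        for m in methods:
            r = estimate(subset, m, n_boot=n_boot, seed=seed)
            results.append(replace(r, method=f"{r.method}[k={size}]"))
    return results
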