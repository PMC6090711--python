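"""Individual-level Mendelian randomisation with a genetic risk score (GRS).

The single combined instrument is a per-individual allele score over the
25-OHD-raising variants, either unweighted (allele counts) or weighted by
external per-allele effect sizes from the exposure GWAS.  Stage 1 regresses
measured log 25-OHD on the GRS in the exposure subsample (linear model,
with the instrument-strength F statistic); stage 2 regresses case-control
status on the GRS in each cohort (logistic model).  The causal log-odds
ratio per unit log-exposure is the Wald coefficient ratio beta2 / beta1
with a first-order Taylor-expansion SE, and per-cohort estimates are pooled
by DerSimonian-Laird random-effects inverse-variance meta-analysis.

Stage 1 is estimated once, in the designated exposure subsample (the study
design has measured 25-OHD only in one control series), and that single
beta1 feeds every cohort's ratio; its uncertainty enters each Taylor SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .summary_mr import ALPHA_HET, Z95, _ci_or, _p_normal

logger = logging.getLogger("vitdmr")

#: Stage-1 F below this value flags a weak instrument.
WEAK_INSTRUMENT_F = 10.0

#: Recognised tumour-site labels for the stratified analysis.
TUMOUR_SITES = ("proximal", "distal", "rectum")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IndividualDataset:
    """Analysis-ready dosages plus phenotypes for one cohort.

    ``dosages``: n x k DataFrame of counts of the 25-OHD-increasing allele
    in [0, 2] (NaN allowed; mean-imputed per variant at GRS construction).
    ``phenotypes``: DataFrame aligned on the same index with any of the
    columns ``exposure`` (log 25-OHD, nmol/L), ``outcome`` (1 = case),
    ``age``, ``sex``, ``bmi``, ``site`` (tumour site of cases).
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.phenotypes.index):
            raise ValueError(f"{self.cohort_id}: dosage/phenotype index mismatch")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(f"{self.cohort_id}: dosages outside [0, 2]")
        if "outcome" in self.phenotypes:
            out = self.phenotypes["outcome"].dropna().unique()
            if not set(np.asarray(out, dtype=float)).issubset({0.0, 1.0}):
                raise ValueError(f"{self.cohort_id}: outcome must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def column(self, name: str) -> pd.Series:
        if name not in self.phenotypes:
            raise KeyError(f"{self.cohort_id}: no phenotype column {name!r}")
        return self.phenotypes[name]


@dataclass(frozen=True)
class GRSWeights:
    """External per-allele exposure effect sizes, one per instrument variant."""

    variant_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.variant_ids) != len(self.weights):
            raise ValueError("variant_ids and weights differ in length")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w <= 0):
            raise ValueError("weights must be positive after harmonization")

    @classmethod
    def from_variants(cls, variants) -> "GRSWeights":
        return cls(
            variant_ids=tuple(v.variant_id for v in variants),
            weights=tuple(v.beta_exposure for v in variants),
        )


@dataclass(frozen=True)
class Stage1Result:
    beta1: float
    se1: float
    f_statistic: float
    r2: float
    n: int
    p_value: float
    weak_instrument: bool


@dataclass(frozen=True)
class Stage2Result:
    beta2: float
    se2: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class TwoStageResult:
    """Per-cohort Wald coefficient-ratio causal estimate."""

    cohort_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    causal_beta: float
    causal_se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    f_statistic: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass(frozen=True)
class MetaResult:
    """DerSimonian-Laird pooled causal estimate across cohorts."""

    pooled_beta: float
    pooled_se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    q_stat: float
    p_het: float
    cohort_estimates: tuple[TwoStageResult, ...]

    @property
    def heterogeneous(self) -> bool:
        return bool(self.p_het < ALPHA_HET)


# ---------------------------------------------------------------------------
# GRS construction
# ---------------------------------------------------------------------------

def compute_grs(
    data: IndividualDataset, weights: GRSWeights, mode: str = "weighted"
) -> pd.Series:
    """Per-individual allele score over the instrument variants.

    ``weighted`` returns sum_k w_k * dosage_k, ``unweighted`` the plain
    allele count sum_k dosage_k.  Dosage columns are aligned to the weight
    order; missing dosages are mean-imputed per variant within the cohort
    (count logged).
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"unknown GRS mode {mode!r}")
    missing_cols = [v for v in weights.variant_ids if v not in data.dosages.columns]
    if missing_cols:
        raise ValueError(f"{data.cohort_id}: dosage columns missing {missing_cols}")
    dose = data.dosages.loc[:, list(weights.variant_ids)].astype(float)
    n_missing = int(dose.isna().to_numpy().sum())
    if n_missing:
        logger.info(
            "%s: mean-imputing %d missing dosages", data.cohort_id, n_missing
        )
        dose = dose.fillna(dose.mean())
    w = np.asarray(weights.weights) if mode == "weighted" else np.ones(len(weights.weights))
    score = dose.to_numpy() @ w
    return pd.Series(score, index=data.phenotypes.index, name=f"grs_{mode}")


# ---------------------------------------------------------------------------
# Stage 1: instrument -> exposure
# ---------------------------------------------------------------------------

def _design(frame: pd.DataFrame, grs: pd.Series, adjust: Sequence[str]) -> pd.DataFrame:
    cols = {"grs": grs}
    for cov in adjust:
        if cov not in frame:
            raise ValueError(f"adjustment covariate {cov!r} not present")
        cols[cov] = frame[cov]
    return pd.DataFrame(cols)


def stage1_exposure_regression(
    data: IndividualDataset,
    grs: pd.Series,
    adjust: Sequence[str] = (),
) -> Stage1Result:
    """OLS of measured log 25-OHD on the GRS (optionally age/sex/BMI adjusted).

    The instrument-strength F for the GRS term is
    ``(n - p - 1) * R2_partial / (1 - R2_partial)`` — for the univariable
    model this is ``(n - 2) R^2 / (1 - R^2)`` — and ``F < 10`` flags a weak
    instrument.  Individuals missing the exposure or any used covariate are
    dropped (complete-case, logged).
    """
    exposure = data.column("exposure")
    design = _design(data.phenotypes, grs, adjust)
    frame = pd.concat([exposure.rename("exposure"), design], axis=1)
    n_before = len(frame)
    frame = frame.dropna()
    if len(frame) < n_before:
        logger.info(
            "%s stage 1: dropped %d incomplete rows",
            data.cohort_id,
            n_before - len(frame),
        )
    if frame["exposure"].notna().sum() == 0:
        raise ValueError(f"{data.cohort_id}: exposure is entirely missing")
    if len(frame) < 30:
        raise ValueError(
            f"{data.cohort_id}: only {len(frame)} complete exposure rows (< 30)"
        )
    X = sm.add_constant(frame.drop(columns="exposure"))
    fit = sm.OLS(frame["exposure"], X).fit()
    if fit.rsquared >= 1.0 - 1e-12:
        raise ValueError(
            f"{data.cohort_id}: degenerate stage-1 fit (R^2 = 1); "
            "exposure is an exact function of the instrument"
        )
    t_grs = float(fit.tvalues["grs"])
    f_stat = t_grs**2  # equals (n - p - 1) R2_partial / (1 - R2_partial)
    weak = f_stat < WEAK_INSTRUMENT_F
    if weak:
        logger.warning(
            "%s: weak instrument (F = %.2f < %.0f)",
            data.cohort_id,
            f_stat,
            WEAK_INSTRUMENT_F,
        )
    return Stage1Result(
        beta1=float(fit.params["grs"]),
        se1=float(fit.bse["grs"]),
        f_statistic=f_stat,
        r2=float(fit.rsquared),
        n=int(fit.nobs),
        p_value=float(fit.pvalues["grs"]),
        weak_instrument=weak,
    )


# ---------------------------------------------------------------------------
# Confounder scan (second MR assumption)
# ---------------------------------------------------------------------------

def confounder_scan(
    data: IndividualDataset,
    grs: pd.Series,
    confounders: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of the GRS with candidate confounders among controls.

    Continuous confounders: OLS of the confounder on the GRS.  Binary:
    logistic regression on the GRS.  Categorical (non-numeric or > 2
    levels): global F-test of GRS differences across levels.  Any
    ``p < alpha`` is flagged as a potential violation of the independence
    assumption.
    """
    controls = data.phenotypes["outcome"] == 0 if "outcome" in data.phenotypes else pd.Series(True, index=data.phenotypes.index)
    rows = []
    for name in confounders:
        if name not in data.phenotypes:
            raise ValueError(f"unknown confounder {name!r}")
        sub = pd.DataFrame({"conf": data.phenotypes[name], "grs": grs})[controls].dropna()
        col = sub["conf"]
        if col.nunique() < 2:
            raise ValueError(f"confounder {name!r} is constant among controls")
        if not pd.api.types.is_numeric_dtype(col):
            kind = "categorical"
            fit = sm.OLS.from_formula("grs ~ C(conf)", data=sub).fit()
            p = float(fit.f_pvalue)
        elif col.nunique() == 2:
            kind = "binary"
            y = (col == col.max()).astype(float)
            fit = sm.Logit(y, sm.add_constant(sub["grs"])).fit(disp=0)
            p = float(fit.pvalues["grs"])
        else:
            kind = "continuous"
            fit = sm.OLS(col, sm.add_constant(sub["grs"])).fit()
            p = float(fit.pvalues["grs"])
        rows.append(
            {"confounder": name, "kind": kind, "p_value": p, "flagged": p < alpha}
        )
    return pd.DataFrame(rows, columns=["confounder", "kind", "p_value", "flagged"])


# ---------------------------------------------------------------------------
# Stage 2: instrument -> outcome
# ---------------------------------------------------------------------------

def stage2_outcome_regression(
    data: IndividualDataset,
    grs: pd.Series,
    adjust: Sequence[str] = (),
) -> Stage2Result:
    """Logistic regression of case-control status on the GRS."""
    outcome = data.column("outcome")
    design = _design(data.phenotypes, grs, adjust)
    frame = pd.concat([outcome.rename("outcome"), design], axis=1).dropna()
    y = frame["outcome"].astype(float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"{data.cohort_id}: need both cases and controls "
            f"(got {n_cases} cases, {n_controls} controls)"
        )
    X = sm.add_constant(frame.drop(columns="outcome"))
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # includes perfect separation
        raise ValueError(
            f"{data.cohort_id}: stage-2 logistic fit failed "
            f"({n_cases} cases / {n_controls} controls): {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError(
            f"{data.cohort_id}: stage-2 logistic regression did not converge "
            "(possible separation)"
        )
    return Stage2Result(
        beta2=float(fit.params["grs"]),
        se2=float(fit.bse["grs"]),
        n_cases=n_cases,
        n_controls=n_controls,
    )


# ---------------------------------------------------------------------------
# Wald ratio and meta-analysis
# ---------------------------------------------------------------------------

def wald_two_stage(stage1, stage2, cohort_id: str = "cohort") -> TwoStageResult:
    """Wald coefficient-ratio causal estimate beta2 / beta1.

    ``stage1`` / ``stage2`` may be the result dataclasses or plain
    ``(beta, se)`` tuples.  The SE is the first-order Taylor expansion with
    both variance terms and no covariance (the two stages come from
    separate samples):

        se^2 = se2^2 / beta1^2 + beta2^2 * se1^2 / beta1^4
    """
    b1, s1 = (stage1.beta1, stage1.se1) if hasattr(stage1, "beta1") else stage1
    b2, s2 = (stage2.beta2, stage2.se2) if hasattr(stage2, "beta2") else stage2
    if b1 == 0:
        raise ValueError("stage-1 coefficient is 0; Wald ratio undefined")
    causal = b2 / b1
    se = float(np.sqrt(s2**2 / b1**2 + b2**2 * s1**2 / b1**4))
    or_, lo, hi = _ci_or(causal, se)
    return TwoStageResult(
        cohort_id=cohort_id,
        beta1=float(b1),
        se1=float(s1),
        beta2=float(b2),
        se2=float(s2),
        causal_beta=float(causal),
        causal_se=se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=_p_normal(causal, se),
        f_statistic=getattr(stage1, "f_statistic", None),
        n_cases=getattr(stage2, "n_cases", None),
        n_controls=getattr(stage2, "n_controls", None),
    )


def meta_analyze(results: Sequence[TwoStageResult]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort estimates.

    Fixed weights ``u_i = 1 / se_i^2`` give Q and the method-of-moments
    ``tau2 = max(0, (Q - (m-1)) / (sum u - sum u^2 / sum u))``; the pooled
    estimate uses random-effects weights ``1 / (se_i^2 + tau2)``.
    Heterogeneity is flagged at ``p_het < 0.10``.
    """
    if len(results) == 0:
        raise ValueError("meta_analyze requires at least one cohort result")
    b = np.array([r.causal_beta for r in results])
    v = np.array([r.causal_se**2 for r in results])
    if len(results) == 1:
        logger.info("meta_analyze: single cohort, returning it with tau2 = 0")
        r = results[0]
        return MetaResult(
            pooled_beta=r.causal_beta,
            pooled_se=r.causal_se,
            or_=r.or_,
            ci_low=r.ci_low,
            ci_high=r.ci_high,
            p_value=r.p_value,
            tau2=0.0,
            q_stat=0.0,
            p_het=float("nan"),
            cohort_estimates=tuple(results),
        )
    u = 1.0 / v
    b_fixed = float(np.sum(u * b) / np.sum(u))
    q = float(np.sum(u * (b - b_fixed) ** 2))
    m = len(results)
    denom = np.sum(u) - np.sum(u**2) / np.sum(u)
    tau2 = max(0.0, (q - (m - 1)) / denom)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    or_, lo, hi = _ci_or(pooled, pooled_se)
    p_het = float(stats.chi2.sf(q, m - 1))
    if p_het < ALPHA_HET:
        logger.warning("significant between-cohort heterogeneity (p = %.3g)", p_het)
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=_p_normal(pooled, pooled_se),
        tau2=float(tau2),
        q_stat=q,
        p_het=p_het,
        cohort_estimates=tuple(results),
    )


# ---------------------------------------------------------------------------
# End-to-end individual-level analysis
# ---------------------------------------------------------------------------

def two_stage_analysis(
    exposure_data: IndividualDataset,
    outcome_datasets: Sequence[IndividualDataset],
    weights: GRSWeights,
    mode: str = "weighted",
    adjust: Sequence[str] = (),
    stage1_adjust: Sequence[str] | None = None,
) -> MetaResult:
    """Full GRS MR: shared stage 1, per-cohort stage 2, DL meta-analysis.

    Stage 1 is fit once in ``exposure_data`` (the subsample with measured
    25-OHD) and its coefficient feeds every cohort's Wald ratio.  By
    default the stage-1 adjustment set matches ``adjust``; a mismatch is
    allowed but logged.
    """
    if stage1_adjust is None:
        stage1_adjust = adjust
    elif tuple(stage1_adjust) != tuple(adjust):
        logger.warning(
            "stage-1 adjustment %s differs from stage-2 adjustment %s",
            list(stage1_adjust),
            list(adjust),
        )
    grs_exp = compute_grs(exposure_data, weights, mode)
    s1 = stage1_exposure_regression(exposure_data, grs_exp, adjust=stage1_adjust)
    per_cohort = []
    for ds in outcome_datasets:
        grs = compute_grs(ds, weights, mode)
        usable = [c for c in adjust if c in ds.phenotypes and ds.phenotypes[c].notna().any()]
        if list(usable) != list(adjust):
            logger.info(
                "%s: adjusting for %s (of requested %s) based on availability",
                ds.cohort_id,
                usable,
                list(adjust),
            )
        s2 = stage2_outcome_regression(ds, grs, adjust=usable)
        per_cohort.append(wald_two_stage(s1, s2, cohort_id=ds.cohort_id))
    return meta_analyze(per_cohort)


def stratified_analysis(
    exposure_data: IndividualDataset,
    outcome_datasets: Sequence[IndividualDataset],
    weights: GRSWeights,
    site: str,
    mode: str = "weighted",
    adjust: Sequence[str] = (),
) -> MetaResult:
    """Site-stratified MR: cases of one tumour site versus all controls.

    Each cohort keeps its full control series and only the cases labelled
    with ``site`` (one of proximal / distal / rectum), then the usual
    stage-2 + Wald + meta-analysis pipeline runs.  Cohorts with zero cases
    of the site are an error.
    """
    if site not in TUMOUR_SITES:
        raise ValueError(f"unknown tumour site {site!r}; expected one of {TUMOUR_SITES}")
    subsets = []
    for ds in outcome_datasets:
        pheno = ds.phenotypes
        if "site" not in pheno:
            raise ValueError(f"{ds.cohort_id}: no site labels")
        keep = (pheno["outcome"] == 0) | ((pheno["outcome"] == 1) & (pheno["site"] == site))
        n_cases = int(((pheno["outcome"] == 1) & (pheno["site"] == site)).sum())
        if n_cases == 0:
            raise ValueError(f"{ds.cohort_id}: no {site} cases")
        subsets.append(
            IndividualDataset(
                dosages=ds.dosages[keep],
                phenotypes=pheno[keep],
                cohort_id=f"{ds.cohort_id}[{site}]",
            )
        )
    return two_stage_analysis(exposure_data, subsets, weights, mode=mode, adjust=adjust)
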