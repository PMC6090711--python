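"""Synthetic cohorts with the statistical structure the MR analysis assumes.

Generates individual-level case-control cohorts — six independent biallelic
variants in Hardy-Weinberg proportions, a log-scale exposure with a genetic
component calibrated to a target instrument R^2, a latent confounder, a
logistic case-control outcome with configurable causal effect and
per-variant direct (pleiotropic) effects — plus the derivation of
two-sample summary statistics from a pair of cohorts.  Every module in the
package is testable against these generators without any external data.

The default variant architecture mirrors the real six-variant 25-OHD
instrument (per-allele exposure effects from the exposure GWAS); allele
frequencies are plausible common-variant values, not estimated from any
dataset.  Exposure scale defaults (mean log(38) nmol/L, SD 0.5 on the log
scale) are likewise generic choices for a low-latitude-deficient
population, not fitted values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .individual_mr import IndividualDataset, TUMOUR_SITES
from .summary_mr import VariantSummary

logger = logging.getLogger("vitdmr")


@dataclass(frozen=True)
class VariantSpec:
    """One biallelic instrument variant: frequency of the exposure-raising
    allele and its true per-allele effect on the (log) exposure."""

    variant_id: str
    frequency: float
    beta: float
    gene_label: str = ""
    chromosome: int = 0
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not (0 < self.frequency < 1):
            raise ValueError(f"{self.variant_id}: frequency must be in (0, 1)")


#: Six-variant instrument architecture.  Exposure betas are the external
#: per-allele effects of the 25-OHD GWAS; frequencies are generic
#: common-variant values (0.2-0.8), not derived from any cohort.
DEFAULT_VARIANTS: tuple[VariantSpec, ...] = (
    VariantSpec("rs10741657", 0.40, 0.0312, "CYP2R1", 11, "A", "G"),
    VariantSpec("rs10745742", 0.39, 0.0167, "AMDHD1", 12, "T", "C"),
    VariantSpec("rs12785878", 0.28, 0.0361, "NADSYN1/DHCR7", 11, "T", "G"),
    VariantSpec("rs17216707", 0.79, 0.0262, "CYP24A1", 20, "T", "C"),
    VariantSpec("rs3755967", 0.28, 0.0893, "GC", 4, "C", "T"),
    VariantSpec("rs8018720", 0.21, 0.0164, "SEC23A", 14, "G", "C"),
)


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification for one synthetic cohort.

    ``causal_beta`` is the log-OR of the outcome per unit log-exposure;
    ``pleiotropy`` gives per-variant direct log-OR effects on the outcome
    (exclusion-restriction violations); ``confounder_strength`` is the
    effect of a latent standard-normal confounder on both the exposure
    (exposure units) and the outcome (log-odds).  ``case_fraction = None``
    simulates a population cohort; otherwise cases are oversampled from a
    population with ``baseline_risk`` cumulative risk at the mean exposure
    to the requested case fraction.  ``site_causal_beta`` switches the
    outcome to a competing site-specific model for stratified analyses.
    """

    n_individuals: int = 5_000
    variants: tuple[VariantSpec, ...] = DEFAULT_VARIANTS
    target_r2: float = 0.0284
    exposure_mean: float = math.log(38.0)
    exposure_sd: float = 0.5
    causal_beta: float = 0.0
    pleiotropy: tuple[float, ...] | None = None
    confounder_strength: float = 0.0
    case_fraction: float | None = None
    baseline_risk: float = 0.01
    measure_exposure: bool | None = None
    site_causal_beta: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_r2 < 1):
            raise ValueError("target_r2 must be in (0, 1)")
        if self.pleiotropy is not None and len(self.pleiotropy) != len(self.variants):
            raise ValueError("pleiotropy must have one entry per variant")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(v.variant_id for v in self.variants)


def calibrate_genetic_effects(config: SimConfig) -> tuple[np.ndarray, float]:
    """Scale the per-allele effects to hit the target instrument R^2.

    Under HWE the genetic variance is ``sum_k beta_k^2 * 2 p_k (1 - p_k)``;
    effects are rescaled by a common factor so this equals
    ``target_r2 * exposure_sd^2``, and the residual SD is solved from the
    variance decomposition (total = genetic + confounder + noise).  Raises
    when the confounder already absorbs too much variance, reporting the
    analytic maximum achievable R^2.
    """
    p = np.array([v.frequency for v in config.variants])
    b = np.array([v.beta for v in config.variants])
    var_g_raw = float(np.sum(b**2 * 2 * p * (1 - p)))
    total_var = config.exposure_sd**2
    var_g_target = config.target_r2 * total_var
    scale = math.sqrt(var_g_target / var_g_raw)
    var_conf = config.confounder_strength**2
    var_resid = total_var - var_g_target - var_conf
    if var_resid <= 0:
        r2_max = 1.0 - var_conf / total_var
        raise ValueError(
            f"target_r2={config.target_r2} infeasible with "
            f"confounder_strength={config.confounder_strength} and "
            f"exposure_sd={config.exposure_sd}; maximum achievable R^2 is "
            f"{r2_max:.4f}"
        )
    return b * scale, math.sqrt(var_resid)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_population(config: SimConfig, n: int, rng: np.random.Generator):
    """Draw n individuals from the generative model; returns a dict of arrays."""
    betas, resid_sd = calibrate_genetic_effects(config)
    p = np.array([v.frequency for v in config.variants])
    k = len(config.variants)
    g = rng.binomial(2, p, size=(n, k)).astype(float)
    u = rng.standard_normal(n)
    centered_g = g - 2 * p  # centering keeps the exposure mean interpretable
    exposure = (
        config.exposure_mean
        + centered_g @ betas
        + config.confounder_strength * u
        + resid_sd * rng.standard_normal(n)
    )
    alpha = (
        np.zeros(k) if config.pleiotropy is None else np.asarray(config.pleiotropy)
    )
    exp_c = exposure - config.exposure_mean
    pleio_term = centered_g @ alpha
    conf_term = config.confounder_strength * u
    if config.site_causal_beta is None:
        logit0 = math.log(config.baseline_risk / (1 - config.baseline_risk))
        prob = _sigmoid(logit0 + config.causal_beta * exp_c + pleio_term + conf_term)
        outcome = (rng.random(n) < prob).astype(float)
        site = np.full(n, None, dtype=object)
        is_case = outcome == 1
        if is_case.any():
            site[is_case] = rng.choice(
                TUMOUR_SITES, size=int(is_case.sum()), p=(0.35, 0.35, 0.30)
            )
    else:
        # competing site-specific events: each tumour site has its own
        # logistic liability; a case's site is the event that fired
        unknown = set(config.site_causal_beta) - set(TUMOUR_SITES)
        if unknown:
            raise ValueError(f"unknown site labels {sorted(unknown)}")
        site_risk = config.baseline_risk / len(TUMOUR_SITES)
        logit0 = math.log(site_risk / (1 - site_risk))
        outcome = np.zeros(n)
        site = np.full(n, None, dtype=object)
        for s in rng.permutation(TUMOUR_SITES):  # random tie-break order
            beta_s = config.causal_beta + config.site_causal_beta.get(s, 0.0)
            prob_s = _sigmoid(logit0 + beta_s * exp_c + pleio_term + conf_term)
            fired = (rng.random(n) < prob_s) & (outcome == 0)
            outcome[fired] = 1.0
            site[fired] = s
    return {"g": g, "exposure": exposure, "outcome": outcome, "site": site}


def _assemble(config: SimConfig, pop: dict, rng: np.random.Generator, cohort_id: str):
    n = len(pop["outcome"])
    measure = (
        config.measure_exposure
        if config.measure_exposure is not None
        else config.case_fraction is None
    )
    pheno = pd.DataFrame(
        {
            "exposure": pop["exposure"] if measure else np.full(n, np.nan),
            "outcome": pop["outcome"],
            # covariates independent of genotype by construction, so the
            # confounder scan is null unless the generator is told otherwise
            "age": np.round(rng.normal(60.0, 10.0, n), 1),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": np.round(rng.normal(27.5, 4.5, n), 2),
            "site": pop["site"],
        }
    )
    dosages = pd.DataFrame(pop["g"], columns=list(config.variant_ids))
    return IndividualDataset(dosages=dosages, phenotypes=pheno, cohort_id=cohort_id)


def simulate_cohort(
    config: SimConfig, cohort_id: str = "sim", seed: int | None = None
) -> IndividualDataset:
    """Simulate one cohort; deterministic given the seed.

    With ``case_fraction = None`` this is a population cohort of
    ``n_individuals``.  Otherwise cases and controls are accumulated from
    successive population draws until the configured case-control split is
    reached (cases oversampled relative to their population frequency).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.case_fraction is None:
        pop = _draw_population(config, config.n_individuals, rng)
        return _assemble(config, pop, rng, cohort_id)

    n_cases = int(round(config.n_individuals * config.case_fraction))
    n_controls = config.n_individuals - n_cases
    got_cases: list[dict] = []
    got_controls: list[dict] = []
    have_cases = have_controls = 0
    # expected case probability ~ baseline_risk; draw with head-room
    chunk = max(10_000, int(1.5 * n_cases / config.baseline_risk / 10))
    for _ in range(1000):
        if have_cases >= n_cases and have_controls >= n_controls:
            break
        pop = _draw_population(config, chunk, rng)
        case_mask = pop["outcome"] == 1
        for mask, store, have, need in (
            (case_mask, got_cases, have_cases, n_cases),
            (~case_mask, got_controls, have_controls, n_controls),
        ):
            take = min(int(mask.sum()), need - have)
            if take > 0:
                idx = np.flatnonzero(mask)[:take]
                store.append({key: val[idx] for key, val in pop.items()})
        have_cases = sum(len(c["outcome"]) for c in got_cases)
        have_controls = sum(len(c["outcome"]) for c in got_controls)
    else:
        raise RuntimeError("case-control sampling did not fill quotas")
    parts = got_cases + got_controls
    pooled = {key: np.concatenate([p[key] for p in parts]) for key in parts[0]}
    # shuffle so row order carries no case status information
    perm = rng.permutation(len(pooled["outcome"]))
    pooled = {key: val[perm] for key, val in pooled.items()}
    return _assemble(config, pooled, rng, cohort_id)


def simulate_two_sample(
    config: SimConfig,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
    case_fraction: float = 0.3,
    seed: int | None = None,
) -> tuple[IndividualDataset, IndividualDataset]:
    """Simulate the two-sample design: an exposure cohort with measured
    25-OHD and an independent case-control outcome cohort."""
    base_seed = config.seed if seed is None else seed
    s_exp, s_out = np.random.SeedSequence(base_seed).spawn(2)
    cfg_exp = replace(
        config,
        n_individuals=n_exposure or config.n_individuals,
        case_fraction=None,
        measure_exposure=True,
    )
    cfg_out = replace(
        config,
        n_individuals=n_outcome or config.n_individuals,
        case_fraction=config.case_fraction or case_fraction,
        measure_exposure=False,
    )
    a = simulate_cohort(cfg_exp, "exposure_cohort", seed=s_exp.generate_state(1)[0] % 2**31)
    b = simulate_cohort(cfg_out, "outcome_cohort", seed=s_out.generate_state(1)[0] % 2**31)
    return a, b


def summarize_to_two_sample(
    cohort_a: IndividualDataset, cohort_b: IndividualDataset
) -> list[VariantSummary]:
    """Per-variant GWAS of the two cohorts, assembled for summary MR.

    Exposure effects: per-variant OLS of measured exposure on dosage in
    cohort A.  Outcome effects: per-variant logistic regression of case
    status on dosage in cohort B.  If the same object is passed twice the
    rows are still well formed (sample overlap is the caller's concern and
    is logged).
    """
    ids_a = list(cohort_a.dosages.columns)
    ids_b = list(cohort_b.dosages.columns)
    if ids_a != ids_b:
        raise ValueError(f"variant sets differ: {ids_a} vs {ids_b}")
    if cohort_a is cohort_b or cohort_a.cohort_id == cohort_b.cohort_id:
        logger.warning("exposure and outcome cohorts overlap; two-sample assumptions void")
    exposure = cohort_a.column("exposure")
    if exposure.notna().sum() == 0:
        raise ValueError(f"{cohort_a.cohort_id}: no measured exposure")
    outcome = cohort_b.column("outcome")
    rows: list[VariantSummary] = []
    for vid in ids_a:
        ge = cohort_a.dosages[vid]
        ok = exposure.notna() & ge.notna()
        fit_x = sm.OLS(exposure[ok], sm.add_constant(ge[ok].rename("g"))).fit()
        gy = cohort_b.dosages[vid]
        okb = outcome.notna() & gy.notna()
        fit_y = sm.Logit(
            outcome[okb].astype(float), sm.add_constant(gy[okb].rename("g"))
        ).fit(disp=0)
        rows.append(
            VariantSummary(
                variant_id=vid,
                beta_exposure=float(fit_x.params["g"]),
                se_exposure=float(fit_x.bse["g"]),
                beta_outcome=float(fit_y.params["g"]),
                se_outcome=float(fit_y.bse["g"]),
            )
        )
    return rows


#: Scenario presets.  The observational scenario plants the protective
#: effect reported by observational studies of 25-OHD and colorectal
#: cancer (OR 0.83 per exposure SD, i.e. log(0.83)/sd per unit log-nmol/L);
#: the pleiotropic preset adds a directional 0.05 log-OR per allele to
#: every variant; the confounded preset gives the latent confounder a 0.3
#: effect on both exposure and outcome.
SCENARIOS = ("null", "observational_effect", "pleiotropic", "confounded")


def scenario(name: str) -> SimConfig:
    """A fully populated preset :class:`SimConfig` for a named scenario."""
    base = SimConfig()
    if name == "null":
        return base
    if name == "observational_effect":
        return replace(base, causal_beta=math.log(0.83) / base.exposure_sd)
    if name == "pleiotropic":
        return replace(base, pleiotropy=(0.05,) * len(base.variants))
    if name == "confounded":
        return replace(base, confounder_strength=0.3)
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
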