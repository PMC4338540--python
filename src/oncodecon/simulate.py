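"""Synthetic cohort generator with known ground truth.

Generates cohorts with the statistical structure the downstream analysis
assumes: a binary driver-lesion matrix with controlled marginal frequencies
and pairwise co-occurrence / mutual-exclusivity, a log-scale expression
matrix produced by the additive model ``Y = baseline + X B + factors +
noise`` with gene-wise noise variances drawn from a scaled inverse
chi-square prior, link-transformed clinical phenotypes with
missing-completely-at-random masking, and right-censored exponential
survival driven by grouped covariates.  Every generated bundle carries a
:class:`SimTruth` with the generative parameters, so recovery of effects,
prior hyper-parameters and risk-variance shares can be tested exactly.

All generators are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import (
    ClinicalTable,
    CohortBundle,
    ExpressionMatrix,
    LesionMatrix,
    SurvivalTable,
)

# default driver-lesion panel: 12 recurrent point mutations + 4 cytogenetic
# alterations typical of an MDS cohort, with rough marginal frequencies
DEFAULT_LESIONS: list[tuple[str, str, float]] = [
    ("SF3B1", "genetic", 0.22),
    ("TET2", "genetic", 0.20),
    ("SRSF2", "genetic", 0.14),
    ("ASXL1", "genetic", 0.12),
    ("DNMT3A", "genetic", 0.10),
    ("RUNX1", "genetic", 0.09),
    ("U2AF1", "genetic", 0.08),
    ("TP53", "genetic", 0.07),
    ("EZH2", "genetic", 0.06),
    ("ZRSR2", "genetic", 0.06),
    ("STAG2", "genetic", 0.05),
    ("CBL", "genetic", 0.05),
    ("del_5q", "cytogenetic", 0.10),
    ("mono_7", "cytogenetic", 0.07),
    ("tri_8", "cytogenetic", 0.08),
    ("del_20q", "cytogenetic", 0.05),
]

# pairwise log-odds interactions: spliceosome genes mutually exclusive,
# a few co-occurring pairs
DEFAULT_INTERACTIONS: list[tuple[str, str, float]] = [
    ("SF3B1", "SRSF2", -3.0),
    ("SF3B1", "U2AF1", -3.0),
    ("SRSF2", "U2AF1", -3.0),
    ("SF3B1", "ZRSR2", -2.0),
    ("TET2", "SRSF2", 1.2),
    ("ASXL1", "EZH2", 1.0),
    ("RUNX1", "STAG2", 1.0),
    ("TP53", "del_5q", 1.0),
]


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PhenotypeSpec:
    """Generative spec for one clinical variable.

    ``domain`` fixes the link: real -> identity, positive -> log,
    unit-interval / binary -> logit.  ``intercept``, ``lesion_coefs`` and
    ``factor_coefs`` act on the transformed scale.
    """

    name: str
    domain: str
    intercept: float
    lesion_coefs: dict[str, float] = field(default_factory=dict)
    factor_coefs: list[float] = field(default_factory=list)
    sex_coef: float = 0.0
    age_coef: float = 0.0
    noise_sd: float = 0.3
    missing_rate: float = 0.05
    units: str = ""


def default_phenotypes() -> list[PhenotypeSpec]:
    return [
        PhenotypeSpec("haemoglobin", "positive", np.log(10.0),
                      {"SF3B1": 0.06, "del_5q": -0.10, "TP53": -0.08},
                      [0.05, -0.03], noise_sd=0.12, missing_rate=0.02, units="g/dl"),
        PhenotypeSpec("platelets", "positive", np.log(180.0),
                      {"del_5q": 0.35, "SRSF2": -0.20, "mono_7": -0.30, "RUNX1": -0.25},
                      [-0.08, 0.05], noise_sd=0.45, missing_rate=0.02, units="1e9/l"),
        PhenotypeSpec("neutrophils", "positive", np.log(2.0),
                      {"mono_7": -0.40, "RUNX1": -0.25, "CBL": 0.20},
                      [0.10, 0.0], noise_sd=0.50, missing_rate=0.05, units="1e9/l"),
        PhenotypeSpec("bm_blasts", "unit-interval", logit(0.04),
                      {"RUNX1": 0.9, "TP53": 0.7, "mono_7": 0.6, "SF3B1": -0.5},
                      [0.2, 0.0], noise_sd=0.8, missing_rate=0.05, units="fraction"),
        PhenotypeSpec("ring_sideroblasts", "unit-interval", logit(0.03),
                      {"SF3B1": 3.2, "del_5q": -0.4},
                      [0.0, 0.0], noise_sd=1.0, missing_rate=0.10, units="fraction"),
        PhenotypeSpec("wbc", "positive", np.log(4.0),
                      {"CBL": 0.35, "SRSF2": 0.15},
                      [0.08, 0.0], noise_sd=0.40, missing_rate=0.02, units="1e9/l"),
    ]


@dataclass
class SurvivalSpec:
    """Per-group log-hazard coefficients and censoring target."""

    lesion_coefs: dict[str, float] = field(default_factory=lambda: {
        "TP53": 0.9, "RUNX1": 0.5, "EZH2": 0.45, "ASXL1": 0.35,
        "mono_7": 0.7, "del_5q": -0.2, "SF3B1": -0.35,
    })
    factor_coefs: list[float] = field(default_factory=lambda: [0.45, 0.30])
    sex_coef: float = -0.10
    age_coef: float = 0.025  # per year, centred at cohort mean
    baseline_scale_days: float = 1500.0  # mean survival at r = 0
    censoring_rate: float = 0.4


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic cohort."""

    n_samples: int = 150          # disease samples
    n_normals: int = 17           # healthy controls, all-zero lesion rows
    n_genes: int = 2000
    lesions: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_LESIONS))
    interactions: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_INTERACTIONS))
    # expression
    n_targets_per_lesion: int = 50
    n_disease_targets: int = 100
    effect_size: float = 0.7
    effect_dist: str = "normal"   # "normal": N(0, effect_size^2); "fixed": +/- effect_size
    n_factors: int = 2
    loading_scale: float = 0.15
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    d0_true: float = 4.0
    s0_sq_true: float = 0.25
    # phenotypes & survival
    phenotypes: list[PhenotypeSpec] = field(default_factory=default_phenotypes)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    # demographics
    female_rate: float = 0.45
    age_mean: float = 68.0
    age_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cls, freq in self.lesions:
            if not 0.0 < freq < 1.0:
                raise SimulationConfigError(f"lesion {name!r} frequency {freq} not in (0,1)")
        n_lesions = len(self.lesions)
        if self.n_genes < max(self.n_targets_per_lesion, self.n_disease_targets):
            raise SimulationConfigError("n_genes smaller than requested target count")
        if not 0.0 <= self.survival.censoring_rate < 1.0:
            raise SimulationConfigError("censoring rate must be in [0, 1)")
        names = [n for n, _, _ in self.lesions]
        if len(set(names)) != n_lesions:
            raise SimulationConfigError("duplicate lesion names")
        if self.effect_dist not in ("normal", "fixed"):
            raise SimulationConfigError(f"unknown effect_dist {self.effect_dist!r}")

    @property
    def lesion_names(self) -> list[str]:
        return [n for n, _, _ in self.lesions]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "phenotypes" in d:
            d["phenotypes"] = [PhenotypeSpec(**p) for p in d["phenotypes"]]
        if "survival" in d:
            d["survival"] = SurvivalSpec(**d["survival"])
        for key in ("lesions", "interactions"):
            if key in d:
                d[key] = [tuple(x) for x in d[key]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground-truth generative parameters of one simulated cohort."""

    effect_matrix: pd.DataFrame        # (lesions + disease) x genes
    target_sets: dict[str, list[str]]  # lesion -> true target genes
    factor_scores: np.ndarray          # samples x n_factors
    factor_loadings: np.ndarray        # genes x n_factors
    noise_variances: np.ndarray        # per gene
    phenotype_coefs: dict[str, dict]
    hazard_coefs: dict[str, dict]      # group -> {covariate: coef}
    risk: np.ndarray                   # true log-hazard per sample
    risk_components: pd.DataFrame      # samples x groups, true r_{ig}


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage stream so toggling one stage cannot shift others."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# mutation matrix


def simulate_mutation_matrix(config: SimulationConfig, seed: int | None = None) -> LesionMatrix:
    """Draw a binary lesion matrix by sequential conditional logistic sampling.

    Lesions are sampled in their configured order; lesion ``j`` is drawn
    Bernoulli with logit ``alpha_j + sum_{i<j} w_ij x_i`` where ``w`` is the
    pairwise log-odds interaction matrix and ``alpha_j`` is calibrated by
    root-finding so the marginal frequency matches the configured one.
    Normal controls get all-zero rows.
    """
    rng = _stage_rng(config.seed if seed is None else seed, 1)
    names = config.lesion_names
    idx = {n: i for i, n in enumerate(names)}
    W = np.zeros((len(names), len(names)))
    for a, b, w in config.interactions:
        if a not in idx or b not in idx:
            raise SimulationConfigError(f"interaction references unknown lesion ({a}, {b})")
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w

    n = config.n_samples
    X = np.zeros((n, len(names)))
    for j, (name, _, freq) in enumerate(config.lesions):
        eta = X[:, :j] @ W[:j, j]

        def mean_prob(alpha: float) -> float:
            return float(np.mean(expit(alpha + eta))) - freq

        lo, hi = -30.0, 30.0
        if mean_prob(lo) > 0 or mean_prob(hi) < 0:
            raise SimulationConfigError(
                f"cannot calibrate marginal frequency {freq} for lesion {name!r}"
            )
        alpha = brentq(mean_prob, lo, hi, xtol=1e-10)
        X[:, j] = (rng.random(n) < expit(alpha + eta)).astype(float)

    sample_ids = [f"MDS{i:04d}" for i in range(n)] + [f"NRM{i:04d}" for i in range(config.n_normals)]
    full = np.vstack([X, np.zeros((config.n_normals, len(names)))])
    df = pd.DataFrame(full, index=sample_ids, columns=names)
    classes = {n: c for n, c, _ in config.lesions}
    return LesionMatrix(df, classes)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    lesions: LesionMatrix,
    normal_flag: pd.Series,
    config: SimulationConfig,
    seed: int | None = None,
):
    """Simulate log-expression from the additive lesion-effect model.

    ``Y_gs = baseline_g + disease_s * Bdis_g + sum_j X_sj B_jg
    + sum_f L_gf F_sf + eps_gs`` with ``Var(eps_g)`` drawn from a scaled
    inverse chi-square with ``(d0_true, s0_sq_true)``.

    Returns ``(ExpressionMatrix, truth)`` where truth carries the effect
    matrix, true target sets, factor structure and realized noise variances.
    """
    rng = _stage_rng(config.seed if seed is None else seed, 2)
    samples = lesions.samples
    n = len(samples)
    g = config.n_genes
    genes = [f"G{i:05d}" for i in range(g)]
    names = lesions.lesions

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)

    def draw_effects(k: int) -> np.ndarray:
        if config.effect_dist == "fixed":
            return config.effect_size * rng.choice([-1.0, 1.0], size=k)
        return rng.normal(0.0, config.effect_size, size=k)

    B = np.zeros((len(names) + 1, g))  # rows: lesions then disease indicator
    target_sets: dict[str, list[str]] = {}
    for j, name in enumerate(names):
        tg = rng.choice(g, size=config.n_targets_per_lesion, replace=False)
        B[j, tg] = draw_effects(len(tg))
        target_sets[name] = [genes[t] for t in sorted(tg)]
    if config.n_disease_targets > 0:
        tg = rng.choice(g, size=config.n_disease_targets, replace=False)
        B[-1, tg] = draw_effects(len(tg))
        target_sets["disease"] = [genes[t] for t in sorted(tg)]
    else:
        target_sets["disease"] = []

    X = lesions.values.to_numpy(dtype=float)
    disease = (normal_flag.loc[samples].to_numpy(dtype=float) != 1.0).astype(float)
    design = np.column_stack([X, disease])  # n x (lesions+1)

    if config.n_factors > 0:
        F = rng.normal(size=(n, config.n_factors))
        L = rng.normal(0.0, config.loading_scale, size=(g, config.n_factors))
    else:
        F = np.zeros((n, 0))
        L = np.zeros((g, 0))

    # scaled inverse chi-square: var_g = d0 * s0^2 / chi2_{d0}
    noise_var = config.d0_true * config.s0_sq_true / rng.chisquare(config.d0_true, size=g)
    eps = rng.normal(size=(g, n)) * np.sqrt(noise_var)[:, None]

    Y = baseline[:, None] + (design @ B).T + (F @ L.T).T + eps
    expr = ExpressionMatrix(pd.DataFrame(Y, index=genes, columns=samples))
    effect_df = pd.DataFrame(B, index=names + ["disease"], columns=genes)
    return expr, effect_df, target_sets, F, L, noise_var


# ---------------------------------------------------------------------------
# phenotypes


_TRANSFORMS = {
    "real": (lambda x: x, lambda y: y),
    "positive": (np.log, np.exp),
    "unit-interval": (logit, expit),
    "binary": (logit, expit),
}


def simulate_phenotypes(
    lesions: LesionMatrix,
    factors: np.ndarray,
    demographics: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> ClinicalTable:
    """Draw clinical variables on the transformed scale and invert the link.

    For each phenotype: linear predictor over lesions, latent factors and
    demographics; Gaussian noise added on the transformed scale; the
    declared transform inverted (identity / exp / inverse-logit); then a
    missing-completely-at-random mask at the configured rate.
    """
    rng = _stage_rng(config.seed if seed is None else seed, 3)
    samples = lesions.samples
    X = lesions.values
    n = len(samples)
    cols = {}
    domains = {}
    units = {}
    age_c = demographics["age"].to_numpy(dtype=float) - config.age_mean
    sex = demographics["sex"].to_numpy(dtype=float)
    for spec in config.phenotypes:
        if spec.domain not in _TRANSFORMS:
            raise SimulationConfigError(f"unknown transform domain {spec.domain!r}")
        _, inverse = _TRANSFORMS[spec.domain]
        eta = np.full(n, spec.intercept)
        for lesion, coef in spec.lesion_coefs.items():
            eta += coef * X[lesion].to_numpy(dtype=float)
        for f, coef in enumerate(spec.factor_coefs):
            if f < factors.shape[1]:
                eta += coef * factors[:, f]
        eta += spec.sex_coef * sex + spec.age_coef * age_c
        eta += rng.normal(0.0, spec.noise_sd, size=n)
        vals = inverse(eta)
        if spec.domain == "binary":
            vals = (rng.random(n) < vals).astype(float)
        miss = rng.random(n) < spec.missing_rate
        vals = np.where(miss, np.nan, vals)
        cols[spec.name] = vals
        domains[spec.name] = spec.domain
        units[spec.name] = spec.units
    df = pd.DataFrame(cols, index=samples)
    return ClinicalTable(df, domains, units)


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    risk: np.ndarray,
    samples: list[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> SurvivalTable:
    """Exponential event times scaled by exp(risk), independent exponential censoring.

    The censoring rate is calibrated by root-finding on the censoring
    hazard so the expected censored fraction matches the configured target.
    """
    spec = config.survival
    if spec.baseline_scale_days <= 0:
        raise SimulationConfigError("baseline hazard scale must be positive")
    rng = _stage_rng(config.seed if seed is None else seed, 4)
    h0 = 1.0 / spec.baseline_scale_days
    rate = h0 * np.exp(risk)
    T = rng.exponential(1.0 / rate)
    target = spec.censoring_rate
    if target <= 0:
        time, status = T, np.ones_like(T)
    else:
        # P(censored | r) = c / (c + rate); solve mean over samples = target
        def mean_censored(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean(c / (c + rate))) - target

        log_c = brentq(mean_censored, np.log(h0) - 20, np.log(h0) + 20, xtol=1e-10)
        C = rng.exponential(np.exp(-log_c), size=len(T))
        time = np.minimum(T, C)
        status = (T <= C).astype(float)
    df = pd.DataFrame({"time_days": np.round(time, 1), "status": status}, index=samples)
    return SurvivalTable(df)


def build_true_risk(
    lesions: LesionMatrix,
    factors: np.ndarray,
    demographics: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame, dict[str, dict]]:
    """Assemble the true log-hazard and its per-group components."""
    spec = config.survival
    X = lesions.values
    classes = lesions.classes
    n = len(lesions.samples)
    comp = {g: np.zeros(n) for g in ("genetic", "cytogenetic", "expression", "demographic")}
    coefs: dict[str, dict] = {g: {} for g in comp}
    for lesion, c in spec.lesion_coefs.items():
        if lesion not in X.columns:
            raise SimulationConfigError(f"survival coefficient for unknown lesion {lesion!r}")
        grp = "genetic" if classes[lesion] == "genetic" else "cytogenetic"
        comp[grp] += c * X[lesion].to_numpy(dtype=float)
        coefs[grp][lesion] = c
    for f, c in enumerate(spec.factor_coefs):
        if f < factors.shape[1]:
            comp["expression"] += c * factors[:, f]
            coefs["expression"][f"factor{f + 1}"] = c
    age_c = demographics["age"].to_numpy(dtype=float) - config.age_mean
    comp["demographic"] += spec.sex_coef * demographics["sex"].to_numpy(dtype=float)
    comp["demographic"] += spec.age_coef * age_c
    coefs["demographic"] = {"sex": spec.sex_coef, "age": spec.age_coef}
    comp_df = pd.DataFrame(comp, index=lesions.samples)
    risk = comp_df.to_numpy().sum(axis=1)
    return risk, comp_df, coefs


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: SimulationConfig) -> tuple[CohortBundle, SimTruth]:
    """Generate a fully aligned cohort bundle plus its ground truth."""
    lesions = simulate_mutation_matrix(config)
    samples = lesions.samples
    n = len(samples)
    normal_flag = pd.Series(
        [0] * config.n_samples + [1] * config.n_normals, index=samples, name="normal"
    )
    rng_demo = _stage_rng(config.seed, 5)
    sex = (rng_demo.random(n) < config.female_rate).astype(int)
    age = np.clip(np.round(rng_demo.normal(config.age_mean, config.age_sd, size=n)), 20, 95)
    demographics = pd.DataFrame({"sex": sex, "age": age.astype(int)}, index=samples)

    expr, effect_df, target_sets, F, L, noise_var = simulate_expression(
        lesions, normal_flag, config
    )
    clinical = simulate_phenotypes(lesions, F, demographics, config)
    risk, comp_df, hazard_coefs = build_true_risk(lesions, F, demographics, config)
    survival = simulate_survival(risk, samples, config)

    bundle = CohortBundle(
        expression=expr,
        lesions=lesions,
        clinical=clinical,
        demographics=demographics,
        survival=survival,
        normal_flag=normal_flag,
    )
    bundle.validate()
    truth = SimTruth(
        effect_matrix=effect_df,
        target_sets=target_sets,
        factor_scores=F,
        factor_loadings=L,
        noise_variances=noise_var,
        phenotype_coefs={p.name: dataclasses.asdict(p) for p in config.phenotypes},
        hazard_coefs=hazard_coefs,
        risk=risk,
        risk_components=comp_df,
    )
    return bundle, truth
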