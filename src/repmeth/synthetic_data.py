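"""Synthetic cohorts, beta-value matrices and locus annotations.

The study data this pipeline was designed around (placental LINE-1/AluYb8
pyrosequencing plus 27K-style array beta-values) were never deposited, so
this module generates cohorts with the same statistical structure: two
correlated repeat-element methylation markers on the percent scale, a birth
weight percentile driven by a linear model on markers and covariates, a
loci x subjects beta matrix with a fixed number of latent methylation
classes, and per-locus genomic attribute annotations (CGI, polycomb target,
TFBS proximity, repeat-family overlap).

Defaults are calibrated to the source cohort's printed descriptive
statistics: marker means/SDs of 51.7 +/- 4.6 (LINE-1) and 65.0 +/- 3.3
(AluYb8), marker correlation 0.29, array-wide mean methylation ~0.238, and
marginal per-10% birth-weight effects of 9.7 and 14.5 percentile points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import classify_growth

__all__ = [
    "SimConfig",
    "TrueLabels",
    "simulate_cohort",
    "simulate_beta_matrix",
    "simulate_annotation",
    "structural_marker_effects",
]

# 16 latent-class beta means, strictly increasing (class 1 = least
# methylated). The ladder is dyadic on the logit scale — classes sit at
# +/-1.8 +/-0.8 +/-0.4 +/-0.22 around a center of -2.0592 — so each level
# of a depth-4 binary hierarchy is separated by more than the span of the
# levels below it (the classes are recoverable by recursive bipartition),
# while the equal-weight matrix-wide mean is 0.238, the promoter-heavy
# array scale.
_DEFAULT_CLASS_MEANS = (
    0.0051, 0.0079, 0.0112, 0.0173, 0.0246, 0.0377, 0.0532, 0.0802,
    0.1572, 0.2246, 0.2933, 0.3919, 0.4802, 0.5892, 0.6728, 0.7615,
)
_DEFAULT_CLASS_WEIGHTS = (0.0625,) * 16
# Array beta-values are approximately homoscedastic on the logit (M-value)
# scale; emulate that with per-class concentration c = 1/(s^2 m (1-m)) so
# every class has logit-scale spread ~s and sibling classes are comparably
# separated across the whole methylation range.
_DEFAULT_LOGIT_SD = 0.3


def _default_class_beta_params() -> tuple[tuple[float, float], ...]:
    s2 = _DEFAULT_LOGIT_SD ** 2
    out = []
    for m in _DEFAULT_CLASS_MEANS:
        c = 1.0 / (s2 * m * (1.0 - m))
        out.append((m * c, (1.0 - m) * c))
    return tuple(out)


def _default_attribute_frequencies() -> dict:
    return {
        "cgi": 0.70,
        "pcg": 0.12,
        "tfbs": 0.50,
        "repeat": {"alu": 0.08, "line1": 0.06, "line2": 0.04, "mir": 0.03},
        "sex_chromosome": 0.0,
        # optional per-class overrides: {class_index: {"cgi": 0.81, ...}}
        "class_overrides": {},
    }


@dataclass
class SimConfig:
    """Generator configuration; defaults reproduce the study conditions.

    Marker effects are *marginal* effects: the expected per-10% coefficient
    of each single-marker adjusted birth-weight regression. Because the two
    markers are correlated, the generator internally converts the marginal
    pair into structural coefficients (see ``structural_marker_effects``)
    so that each single-marker model recovers its configured value.
    """

    n_subjects: int = 380
    n_array_subjects: int = 184
    n_loci: int = 2000              # desk-scale stand-in for 26,486
    n_latent_classes: int = 16

    marker_means: tuple[float, float] = (51.7, 65.0)   # (LINE-1, AluYb8), %
    marker_sds: tuple[float, float] = (4.6, 3.3)
    marker_correlation: float = 0.29

    # percentile points per 10 percentage-point methylation increase
    effect_line1_per10: float = 9.7
    effect_alu_per10: float = 14.5
    effect_male_sex: float = 12.81      # vs female referent
    effect_white_ethnicity: float = 7.06

    covariate_prevalences: dict = field(default_factory=lambda: {
        "male": 190 / 380,
        "caucasian": 217 / 380,
        "tobacco": 36 / 380,
        "alcohol": 3 / 380,
        "vitamins": 314 / 380,
    })

    # not printed by the source study; chosen to give comparable CI widths
    residual_sd: float = 25.0

    maternal_age_mean: float = 29.5
    maternal_age_sd: float = 4.5
    bmi_mean: float = 26.0
    bmi_sd: float = 5.5
    gestational_age_mean: float = 277.0   # days; term deliveries only
    gestational_age_sd: float = 8.0

    class_beta_params: tuple = field(default_factory=_default_class_beta_params)
    class_weights: tuple = _DEFAULT_CLASS_WEIGHTS
    attribute_frequencies: dict = field(default_factory=_default_attribute_frequencies)
    n_tfbs_factors: int = 258
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_array_subjects", "n_loci",
                     "n_latent_classes", "n_tfbs_factors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.marker_correlation < 1.0:
            raise ValueError("marker_correlation must lie in (-1, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        for key, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {key!r} outside [0, 1]")
        if len(self.class_beta_params) != self.n_latent_classes:
            raise ValueError("class_beta_params length != n_latent_classes")
        if len(self.class_weights) != self.n_latent_classes:
            raise ValueError("class_weights length != n_latent_classes")
        for a, b in self.class_beta_params:
            if a <= 0 or b <= 0:
                raise ValueError("beta shape parameters must be positive")
        w = np.asarray(self.class_weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("class_weights must be nonnegative, not all zero")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrueLabels:
    """Ground truth attached to a simulated beta matrix."""

    latent_class: np.ndarray           # per-locus class index, 1..K
    class_means: np.ndarray            # beta mean per class, increasing
    effects: dict                      # configured effect sizes used

    def __post_init__(self) -> None:
        k = self.latent_class
        if np.any((k < 1) | (k > len(self.class_means))):
            raise ValueError("latent class index out of range")


def structural_marker_effects(config: SimConfig) -> tuple[float, float]:
    """Structural per-10% coefficients implied by the marginal pair.

    With markers correlated at rho, fitting a single-marker model leaves the
    other marker in the error term, shifting the coefficient by the omitted
    marker's effect times the regression of one marker on the other. The
    configured values are the marginal (reported) effects, so we invert

        marginal_1 = b1 + b2 * rho * s2 / s1
        marginal_2 = b2 + b1 * rho * s1 / s2

    for the structural (b1, b2) used in the generative linear predictor.
    """
    return _structural_uncorrected(config)


def _structural_uncorrected(config: SimConfig) -> tuple[float, float]:
    s1, s2 = (sd / 10.0 for sd in config.marker_sds)
    rho = config.marker_correlation
    m = np.array([[1.0, rho * s2 / s1], [rho * s1 / s2, 1.0]])
    b = np.linalg.solve(m, [config.effect_line1_per10, config.effect_alu_per10])
    return float(b[0]), float(b[1])


def truncation_attenuation(config: SimConfig) -> float:
    """Slope attenuation induced by clipping percentiles to [0.1, 99.9].

    Clipping a linear-plus-Gaussian outcome flattens its conditional mean
    wherever draws hit a bound, shrinking every fitted slope by the average
    probability of landing inside the bounds. With the linear predictor
    itself normal with variance tau^2 around the centre of the scale, that
    probability is kappa = 2*Phi(49.9 / sqrt(sigma^2 + tau^2)) - 1. The
    generator divides its structural coefficients by kappa so the
    configured effects are what a fitted model recovers in expectation.
    """
    b1, b2 = _structural_uncorrected(config)
    s1, s2 = (sd / 10.0 for sd in config.marker_sds)
    rho = config.marker_correlation
    prev = config.covariate_prevalences
    tau2 = (
        (b1 * s1) ** 2 + (b2 * s2) ** 2 + 2 * b1 * b2 * rho * s1 * s2
        + config.effect_male_sex ** 2 * prev["male"] * (1 - prev["male"])
        + config.effect_white_ethnicity ** 2
        * prev["caucasian"] * (1 - prev["caucasian"])
    )
    from scipy.stats import norm

    return float(2.0 * norm.cdf(49.9 / np.sqrt(config.residual_sd ** 2 + tau2)) - 1.0)


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def simulate_cohort(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort of term deliveries with repeat-element methylation.

    LINE-1 and AluYb8 means come from a bivariate normal on the percent
    scale (truncated to [0, 100] by clipping); binary covariates are
    independent Bernoulli draws at their configured prevalences; birth
    weight percentile is a linear predictor on centered covariates plus
    Gaussian noise, truncated to [0.1, 99.9].
    """
    rng = np.random.default_rng([1, config.seed if seed is None else seed])
    n = config.n_subjects
    prev = config.covariate_prevalences

    mu = np.asarray(config.marker_means)
    s1, s2 = config.marker_sds
    rho = config.marker_correlation
    cov = np.array([[s1 ** 2, rho * s1 * s2], [rho * s1 * s2, s2 ** 2]])
    markers = rng.multivariate_normal(mu, cov, size=n)
    markers = np.clip(markers, 0.0, 100.0)
    line1, alu = markers[:, 0], markers[:, 1]

    male = rng.random(n) < prev["male"]
    white = rng.random(n) < prev["caucasian"]
    tobacco = rng.random(n) < prev["tobacco"]
    alcohol = rng.random(n) < prev["alcohol"]
    vitamins = rng.random(n) < prev["vitamins"]

    age = np.clip(rng.normal(config.maternal_age_mean, config.maternal_age_sd, n), 18, 40)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15, 55)
    ga = np.clip(rng.normal(config.gestational_age_mean, config.gestational_age_sd, n), 260, 294)

    b1, b2 = structural_marker_effects(config)
    # pre-divide all slopes by the clipping attenuation so configured
    # effects are what fitted models recover in expectation
    kappa = truncation_attenuation(config)
    lin = (
        50.0
        + (b1 / kappa) * (line1 - mu[0]) / 10.0
        + (b2 / kappa) * (alu - mu[1]) / 10.0
        + (config.effect_male_sex / kappa) * (male - prev["male"])
        + (config.effect_white_ethnicity / kappa) * (white - prev["caucasian"])
    )
    pct = lin + rng.normal(0.0, config.residual_sd, n)
    pct = np.clip(pct, 0.1, 99.9)

    df = pd.DataFrame({
        "subject_id": _subject_ids(n),
        "sex": np.where(male, "male", "female"),
        "maternal_age": np.round(age, 2),
        "bmi": np.round(bmi, 2),
        "ethnicity": np.where(white, "Caucasian", "non-Caucasian"),
        "tobacco": np.where(tobacco, "yes", "no"),
        "alcohol": np.where(alcohol, "yes", "no"),
        "vitamins": np.where(vitamins, "yes", "no"),
        "gestational_age": np.round(ga, 1),
        "birth_weight_percentile": pct,
        "line1_mean": line1,
        "aluyb8_mean": alu,
    })
    df["growth_category"] = [classify_growth(p) for p in df["birth_weight_percentile"]]
    return df


def simulate_beta_matrix(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TrueLabels]:
    """Draw a loci x subjects beta matrix from latent methylation classes.

    Each locus belongs to exactly one latent class; its beta values across
    subjects are iid draws from that class's beta distribution. Classes are
    indexed 1..K in order of increasing mean methylation.
    """
    rng = np.random.default_rng([2, config.seed if seed is None else seed])
    params = np.asarray(config.class_beta_params, dtype=float)
    if np.any(params <= 0):
        raise ValueError("beta shape parameters must be positive")
    means = params[:, 0] / params.sum(axis=1)
    order = np.argsort(means, kind="stable")     # class 1 = lowest methylation
    params = params[order]
    means = means[order]
    weights = np.asarray(config.class_weights, dtype=float)[order]
    weights = weights / weights.sum()

    k = rng.choice(config.n_latent_classes, size=config.n_loci, p=weights) + 1
    a = params[k - 1, 0][:, None]
    b = params[k - 1, 1][:, None]
    beta = rng.beta(a, b, size=(config.n_loci, config.n_array_subjects))

    loci = [f"cg{i:05d}" for i in range(1, config.n_loci + 1)]
    matrix = pd.DataFrame(beta, index=pd.Index(loci, name="locus_id"),
                          columns=_subject_ids(config.n_array_subjects))
    truth = TrueLabels(
        latent_class=k,
        class_means=means,
        effects={
            "line1_per10": config.effect_line1_per10,
            "alu_per10": config.effect_alu_per10,
        },
    )
    return matrix, truth


def simulate_annotation(
    config: SimConfig,
    labels: TrueLabels | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-locus genomic attributes and TFBS identity sets.

    Produces a chromosome, binary flags for CGI / polycomb-target / TFBS
    proximity, a one-of repeat-family overlap (Alu, LINE-1, LINE-2, MIR or
    none), and — for TFBS-proximal loci — a nonempty set of factor names
    drawn from a pool of ``n_tfbs_factors``. Attribute frequencies may be
    overridden per latent class via ``attribute_frequencies["class_overrides"]``
    when ``labels`` is supplied (used to enrich e.g. CGI or PcG loci in
    specific methylation classes).
    """
    rng = np.random.default_rng([3, config.seed if seed is None else seed])
    n = config.n_loci
    freq = config.attribute_frequencies
    rep = freq.get("repeat", {})
    rep_names = ("alu", "line1", "line2", "mir")
    rep_p = np.array([rep.get(r, 0.0) for r in rep_names], dtype=float)
    if rep_p.sum() > 1.0 + 1e-12:
        raise ValueError("repeat-category probabilities must sum to <= 1")

    def per_locus(attr: str, base: float) -> np.ndarray:
        p = np.full(n, base)
        overrides = freq.get("class_overrides", {})
        if labels is not None and overrides:
            for cls, ov in overrides.items():
                if attr in ov:
                    p[labels.latent_class == int(cls)] = float(ov[attr])
        return p

    cgi = rng.random(n) < per_locus("cgi", freq.get("cgi", 0.0))
    pcg = rng.random(n) < per_locus("pcg", freq.get("pcg", 0.0))
    tfbs = rng.random(n) < per_locus("tfbs", freq.get("tfbs", 0.0))

    cuts = np.concatenate([[0.0], np.cumsum(rep_p)])
    u = rng.random(n)
    repeat_class = np.full(n, "none", dtype=object)
    for name, lo, hi in zip(rep_names, cuts[:-1], cuts[1:]):
        repeat_class[(u >= lo) & (u < hi)] = name

    sex_frac = float(freq.get("sex_chromosome", 0.0))
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object)
    if sex_frac > 0:
        on_sex = rng.random(n) < sex_frac
        chrom[on_sex] = rng.choice(["chrX", "chrY"], size=int(on_sex.sum()), p=[0.8, 0.2])

    factors = np.array([f"TF{i:03d}" for i in range(1, config.n_tfbs_factors + 1)])
    tf_sets: list[str] = []
    for flag in tfbs:
        if not flag:
            tf_sets.append("")
            continue
        size = min(1 + rng.poisson(1.0), 5, config.n_tfbs_factors)
        chosen = rng.choice(factors, size=size, replace=False)
        tf_sets.append(";".join(sorted(chosen)))

    loci = [f"cg{i:05d}" for i in range(1, n + 1)]
    return pd.DataFrame({
        "chromosome": chrom,
        "cgi": cgi,
        "pcg": pcg,
        "tfbs": tfbs,
        "repeat_alu": repeat_class == "alu",
        "repeat_line1": repeat_class == "line1",
        "repeat_line2": repeat_class == "line2",
        "repeat_mir": repeat_class == "mir",
        "tfbs_factors": tf_sets,
    }, index=pd.Index(loci, name="locus_id"))
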