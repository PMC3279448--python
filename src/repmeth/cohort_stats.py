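"""Growth categorization, case–control matching, univariate tests and
adjusted birth-weight regressions.

Standard tests are delegated to scipy.stats and model fits to statsmodels;
this module pins down the contracts the pipeline relies on (strict SGA/LGA
boundaries, deterministic greedy matching, per-10% marker scaling,
complete-case handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "classify_growth",
    "match_controls",
    "kruskal_wallis",
    "chi_square",
    "pearson_ci",
    "fit_birthweight_model",
    "CorrelationResult",
    "RegressionResult",
    "MARKER_COLUMNS",
]

MARKER_COLUMNS = {"line1": "line1_mean", "aluyb8": "aluyb8_mean"}

_COVARIATES = ["maternal_age", "bmi"]
_BINARY = [("sex", "male"), ("ethnicity", "Caucasian"),
           ("tobacco", "yes"), ("alcohol", "yes"), ("vitamins", "yes")]


def classify_growth(percentile: float) -> str:
    """SGA below the 10th percentile, LGA above the 90th, AGA between.

    Both boundaries are strict: a birth weight at exactly the 10th or 90th
    percentile is appropriate for gestational age.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"birth weight percentile {percentile} outside (0, 100)")
    if percentile < 10.0:
        return "SGA"
    if percentile > 90.0:
        return "LGA"
    return "AGA"


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame) -> pd.DataFrame:
    """Greedily pair each SGA case with a non-SGA control.

    Eligibility: same infant sex, maternal age within +/- 3 years and
    gestational age within +/- 2 days. Cases are processed in subject-id
    order; each takes its nearest eligible control by maternal-age gap,
    ties broken by smaller gestational-age gap then lowest control id.
    Unmatched cases appear with control_id = NA (reported, not fatal).
    """
    if (cases["growth_category"] != "SGA").any():
        raise ValueError("cases must all be SGA")
    if (pool["growth_category"] == "SGA").any():
        raise ValueError("pool must contain no SGA subjects")

    available = pool.set_index("subject_id")
    used: set[str] = set()
    rows = []
    for _, case in cases.sort_values("subject_id").iterrows():
        elig = available[
            (available["sex"] == case["sex"])
            & ((available["maternal_age"] - case["maternal_age"]).abs() <= 3.0)
            & ((available["gestational_age"] - case["gestational_age"]).abs() <= 2.0)
            & (~available.index.isin(used))
        ]
        if elig.empty:
            rows.append((case["subject_id"], pd.NA))
            continue
        key = pd.DataFrame({
            "d_age": (elig["maternal_age"] - case["maternal_age"]).abs(),
            "d_ga": (elig["gestational_age"] - case["gestational_age"]).abs(),
        }, index=elig.index)
        best = key.sort_values(["d_age", "d_ga"]).index
        # lowest id among exact ties on both keys
        top = key.loc[best[0]]
        tied = key[(key["d_age"] == top["d_age"]) & (key["d_ga"] == top["d_ga"])]
        chosen = min(tied.index)
        used.add(chosen)
        rows.append((case["subject_id"], chosen))
    return pd.DataFrame(rows, columns=["case_id", "control_id"])


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based Kruskal–Wallis H with tie correction, chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("Kruskal–Wallis needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0  # scipy raises on all-identical data
    h, p = st.kruskal(*samples)
    return float(h), float(p)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on a 2-way count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    expected = st.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count; collapse categories first")
    res = st.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def pearson_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with the Fisher-z confidence interval tanh(atanh r ± z/√(n−3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r = float(st.pearsonr(x, y).statistic)
    # conventional 1.96 at the default level; exact quantile otherwise
    z = 1.96 if level == 0.95 else st.norm.ppf(0.5 + level / 2.0)
    hw = z / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - hw), np.tanh(np.arctanh(r) + hw)
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n)


@dataclass
class RegressionResult:
    marker: str
    table: pd.DataFrame       # term, coef, ci_low, ci_high, t, p
    n: int

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _design(cohort: pd.DataFrame, marker_col: str) -> tuple[pd.DataFrame, pd.Series]:
    d = pd.DataFrame(index=cohort.index)
    d["marker_per10"] = cohort[marker_col] / 10.0
    d["sex_male"] = (cohort["sex"] == "male").astype(float)
    d["maternal_age"] = cohort["maternal_age"]
    d["bmi"] = cohort["bmi"]
    d["ethnicity_caucasian"] = (cohort["ethnicity"] == "Caucasian").astype(float)
    d["tobacco"] = (cohort["tobacco"] == "yes").astype(float)
    d["alcohol"] = (cohort["alcohol"] == "yes").astype(float)
    d["vitamins"] = (cohort["vitamins"] == "yes").astype(float)
    y = cohort["birth_weight_percentile"].astype(float)
    keep = d.notna().all(axis=1) & y.notna()
    return d[keep], y[keep]


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (via incremental rank)."""
    aliased = []
    for j in range(1, x.shape[1]):
        if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
            aliased.append(names[j])
    return aliased


def fit_birthweight_model(cohort: pd.DataFrame, marker: str = "line1") -> RegressionResult:
    """Adjusted OLS of birth weight percentile on one repeat-element marker.

    The marker enters per 10 percentage points of methylation; covariates
    are infant sex (female referent), maternal age, pre-pregnancy BMI,
    ethnicity (non-Caucasian referent), and tobacco, alcohol and prenatal
    vitamin use. Complete-case analysis; requires >= 20 complete rows.
    """
    marker_col = MARKER_COLUMNS[marker]
    d, y = _design(cohort, marker_col)
    if len(d) < 20:
        raise ValueError(f"only {len(d)} complete cases; need >= 20")
    x = sm.add_constant(d, has_constant="add")
    constant = [c for c in d.columns if d[c].nunique() <= 1]
    if "marker_per10" in constant:
        raise ValueError("marker has no variation")
    if constant:
        import warnings

        warnings.warn(f"covariate(s) with no variation dropped: {constant}")
        x = x.drop(columns=constant)
    xm = x.to_numpy(dtype=float)
    # normalize columns so the rank test is scale-free
    xn = xm / np.linalg.norm(xm, axis=0)
    if np.linalg.matrix_rank(xn, tol=1e-8) < xn.shape[1]:
        bad = _aliased_columns(xn, list(x.columns))
        raise ValueError(f"collinear design; aliased terms: {', '.join(bad)}")
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "term": x.columns,
        "coef": fit.params.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return RegressionResult(marker=marker, table=table, n=int(fit.nobs))
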