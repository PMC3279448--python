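"""Beta-value computation, repeat summarization, outlier screening and
autosomal filtering.

The beta-value is computed exactly as on the 27K platform, from average
probe intensities with the +100 stabilizing offset and negative intensities
clamped to zero; no normalization is applied. Sample-level QC is a
Mahalanobis screen on a low-dimensional per-subject summary of the beta
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "beta_from_intensities",
    "mean_repeat_methylation",
    "subject_summary",
    "screen_outliers",
    "filter_autosomal",
    "OutlierReport",
    "REPEAT_POSITIONS",
]

# CpG positions read per pyrosequencing assay
REPEAT_POSITIONS = {"LINE-1": 4, "AluYb8": 5}

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def beta_from_intensities(m, u):
    """beta = max(M,0) / [max(M,0) + max(U,0) + 100].

    Accepts scalars or arrays of average methylated (M) and unmethylated
    (U) probe intensities; the +100 offset keeps the ratio defined and
    strictly below 1 even at zero unmethylated signal.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(u))):
        raise ValueError("intensities must be finite")
    mc = np.maximum(m, 0.0)
    uc = np.maximum(u, 0.0)
    out = mc / (mc + uc + 100.0)
    return float(out) if out.ndim == 0 else out


def mean_repeat_methylation(element: str, position_values) -> float:
    """Mean percent methylation over an element's sequenced CpG positions."""
    if element not in REPEAT_POSITIONS:
        raise ValueError(f"unknown element {element!r}")
    expected = REPEAT_POSITIONS[element]
    vals = np.asarray(position_values, dtype=float)
    if vals.shape != (expected,):
        raise ValueError(
            f"{element} requires exactly {expected} position values, got {vals.size}"
        )
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("percent methylation outside [0, 100]")
    return float(vals.mean())


def subject_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-subject (mean beta, SD of beta, fraction beta > 0.7) summary."""
    return pd.DataFrame({
        "mean_beta": matrix.mean(axis=0),
        "sd_beta": matrix.std(axis=0, ddof=1),
        "frac_high": (matrix > 0.7).mean(axis=0),
    })


@dataclass
class OutlierReport:
    distances: pd.Series       # squared Mahalanobis distance per subject
    flags: pd.Series
    threshold: float
    alpha: float


def screen_outliers(matrix: pd.DataFrame, alpha: float = 0.001) -> OutlierReport:
    """Flag subjects whose beta-distribution summary is a Mahalanobis outlier.

    Each subject is reduced to a 3-dimensional summary (mean, SD, fraction
    of loci with beta > 0.7); squared Mahalanobis distances against the
    cohort mean and covariance are compared with the chi-square(3)
    upper-alpha quantile. ``alpha >= 1`` disables flagging.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    summ = subject_summary(matrix)
    p = summ.shape[1]
    if summ.shape[0] < p + 2:
        raise ValueError(f"need at least {p + 2} subjects for a {p}-dim screen")
    x = summ.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < p or np.linalg.cond(cov) > 1e12:
        raise ValueError(
            "singular summary covariance; reduce the summary dimension "
            "(e.g. drop a constant feature)"
        )
    diff = x - mu
    d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    threshold = np.inf if alpha >= 1.0 else float(st.chi2.isf(alpha, df=p))
    distances = pd.Series(d2, index=summ.index, name="mahalanobis_sq")
    flags = pd.Series(d2 > threshold, index=summ.index, name="outlier")
    return OutlierReport(distances=distances, flags=flags,
                         threshold=threshold, alpha=alpha)


def filter_autosomal(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop loci mapping to X or Y, preserving the order of the rest."""
    missing = matrix.index.difference(annotation.index)
    if len(missing) > 0:
        shown = ", ".join(map(str, missing[:10]))
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"loci missing from annotation: {shown}{more}")
    chrom = annotation.loc[matrix.index, "chromosome"].astype(str)
    keep = ~chrom.isin(SEX_CHROMOSOMES)
    return matrix.loc[keep.to_numpy()]
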