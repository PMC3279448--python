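"""Per-class regressions on repeat-element methylation and the max-|t|
permutation omnibus test.

Each class-level aggregate methylation value is regressed (simple least
squares) on a repeat-element marker, the marker entering per 10 percentage
points. The omnibus statistic is the largest absolute t-statistic across
the class regressions; its null distribution comes from jointly permuting
the marker across subjects and refitting every class, so the 0.95 quantile
of the permuted maxima doubles as a familywise (multiplicity-adjusted)
per-class significance limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OmnibusResult", "class_regressions", "max_t_permutation",
           "plot_omnibus"]

_T_CAP = 1e6  # reported in place of an infinite t on a noiseless fit


def _align(aggregates: pd.DataFrame, marker) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(marker, pd.Series):
        marker = pd.Series(np.asarray(marker, dtype=float), index=aggregates.index)
    if len(marker) != len(aggregates) and len(
        aggregates.index.intersection(marker.index)
    ) < len(aggregates):
        raise ValueError("subjects of aggregates and marker are not aligned")
    if not aggregates.index.equals(marker.index):
        common = aggregates.index.intersection(marker.index)
        if len(common) < len(aggregates):
            raise ValueError("subjects of aggregates and marker are not aligned")
        marker = marker.loc[aggregates.index]
    return aggregates, marker.to_numpy(dtype=float)


def _t_from_r(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - r * r, 1.0 / (_T_CAP ** 2))
    return np.clip(r * np.sqrt((n - 2) / denom), -_T_CAP, _T_CAP)


def _standardize_columns(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit norm; constant columns flagged."""
    yc = y - y.mean(axis=0)
    norm = np.linalg.norm(yc, axis=0)
    constant = norm < 1e-12
    norm[constant] = 1.0
    return yc / norm, constant


def class_regressions(aggregates: pd.DataFrame, marker) -> pd.DataFrame:
    """Simple OLS of each class aggregate on the marker (per-10% scale).

    Returns a class-indexed frame of slopes (beta fraction per 10%
    methylation) and t-statistics. Constant aggregate columns get t = 0
    with a warning; a perfectly collinear fit reports t at a finite cap.
    """
    aggregates, x = _align(aggregates, marker)
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 subjects for class regressions, got {n}")
    x10 = x / 10.0
    xc = x10 - x10.mean()
    xnorm = np.linalg.norm(xc)
    if xnorm < 1e-12:
        raise ValueError("marker is constant")
    y = aggregates.to_numpy(dtype=float)
    ystd, constant = _standardize_columns(y)
    r = ystd.T @ (xc / xnorm)
    t = _t_from_r(r, n)
    ynorm = np.linalg.norm(y - y.mean(axis=0), axis=0)
    slope = r * ynorm / xnorm
    if constant.any():
        import warnings

        warnings.warn(f"{constant.sum()} constant aggregate column(s); t set to 0")
        t[constant] = 0.0
        slope[constant] = 0.0
    return pd.DataFrame({"slope_per10": slope, "t": t},
                        index=aggregates.columns.rename("class"))


@dataclass
class OmnibusResult:
    per_class: pd.DataFrame     # class, slope_per10, t, significant
    observed_max_t: float
    p_value: float
    null_limit: float           # 0.95 quantile of permuted max |t| (use +/-)
    null_max_t: np.ndarray
    n_permutations: int
    seed: int | None


def max_t_permutation(
    aggregates: pd.DataFrame,
    marker,
    B: int = 10000,
    seed: int | None = None,
    level: float = 0.05,
) -> OmnibusResult:
    """Omnibus max-|t| permutation test across class regressions.

    The marker vector is shuffled across subjects (one shared shuffle per
    permutation replicate — the maximum is over jointly permuted fits) and
    all class regressions are recomputed; the omnibus p-value uses the
    add-one estimator (1 + #{null >= observed}) / (B + 1). The null limit
    is the empirical (1 - level) quantile of the permuted maxima, to be
    drawn symmetrically about zero against the per-class t-statistics.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations for a stable null")
    per_class = class_regressions(aggregates, marker)
    observed = float(per_class["t"].abs().max())

    _, x = _align(aggregates, marker)
    n = len(x)
    x10c = x / 10.0 - x.mean() / 10.0
    xstd = x10c / np.linalg.norm(x10c)
    ystd, constant = _standardize_columns(aggregates.to_numpy(dtype=float))
    ystd[:, constant] = 0.0

    rng = np.random.default_rng(seed)
    perm = np.empty((n, B))
    for b in range(B):
        perm[:, b] = xstd[rng.permutation(n)]
    r_null = ystd.T @ perm                      # classes x B
    null_max = np.abs(_t_from_r(r_null, n)).max(axis=0)

    p = (1.0 + np.count_nonzero(null_max >= observed)) / (B + 1.0)
    limit = float(np.quantile(null_max, 1.0 - level))
    table = per_class.copy()
    table["significant"] = table["t"].abs() > limit
    return OmnibusResult(per_class=table, observed_max_t=observed,
                         p_value=float(p), null_limit=limit,
                         null_max_t=null_max, n_permutations=B, seed=seed)


def plot_omnibus(result: OmnibusResult, class_means=None, ax=None,
                 title: str | None = None):
    """Dot plot of per-class t-statistics with dashed familywise null limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = result.per_class["t"].to_numpy()
    pos = np.arange(len(t))
    if class_means is not None:
        sc = ax.scatter(pos, t, c=np.asarray(class_means), cmap="viridis",
                        vmin=0, vmax=1, zorder=3)
        plt.colorbar(sc, ax=ax, label="mean class methylation")
    else:
        ax.scatter(pos, t, zorder=3)
    ax.axhline(result.null_limit, color="red", linestyle="--")
    ax.axhline(-result.null_limit, color="red", linestyle="--")
    ax.axhline(0.0, color="grey", linewidth=0.5)
    ax.set_xticks(pos)
    ax.set_xticklabels([str(c) for c in result.per_class.index], rotation=90,
                       fontsize=7)
    ax.set_xlabel("class")
    ax.set_ylabel("t-stat")
    if title:
        ax.set_title(title)
    return ax
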