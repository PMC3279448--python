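"""Recursively partitioned beta-mixture clustering of CpG loci.

Loci are clustered by their methylation profile across subjects: starting
from the full set, each node is tentatively split into a 2-component
mixture in which every component has an independent beta density per
subject column. The split is kept only when it improves the node's BIC,
and the recursion is pruned after ``max_depth`` levels of splits (four by
default, giving at most 16 terminal classes). Terminal classes are
renumbered so class 1 is the least methylated.

The weighted EM uses a deterministic initialization (split at the weighted
median of locus mean methylation) and an M-step that refines
method-of-moments estimates with damped Newton steps on the per-subject
beta likelihood; a candidate M-step update is only accepted where it does
not decrease the expected complete-data log-likelihood, so the observed
log-likelihood is nondecreasing across EM iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, polygamma, psi

__all__ = [
    "BetaMixtureFit",
    "RpmmNode",
    "RpmmTree",
    "ClassAssignment",
    "fit_beta_mixture_em",
    "rpmm_fit",
    "order_classes",
]

_SHAPE_MIN = 1e-2
_SHAPE_MAX = 1e6


def _clip_beta(x: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(x, eps, 1.0 - eps)


def _component_q(a, b, t1, t2, w):
    """Expected complete-data log-likelihood contribution per subject."""
    return (a - 1.0) * t1 + (b - 1.0) * t2 - w * betaln(a, b)


def _mstep_shapes(wk, x, lx, l1x, old_a=None, old_b=None, newton_iter=25):
    """Per-subject beta shape estimates for one weighted component.

    Method-of-moments start, Newton refinement of the weighted MLE, and a
    final elementwise guard keeping whichever of {refined, MoM, previous}
    parameters scores the highest weighted likelihood — the guard is what
    makes the surrounding EM monotone.
    """
    w = wk.sum()
    mu = wk @ x / w
    m2 = wk @ (x * x) / w
    var = np.maximum(m2 - mu * mu, 1e-10)
    mu = np.clip(mu, 1e-6, 1.0 - 1e-6)
    conc = np.clip(mu * (1.0 - mu) / var - 1.0, 1e-2, _SHAPE_MAX)
    a = np.clip(mu * conc, _SHAPE_MIN, _SHAPE_MAX)
    b = np.clip((1.0 - mu) * conc, _SHAPE_MIN, _SHAPE_MAX)
    a_mom, b_mom = a.copy(), b.copy()

    t1 = wk @ lx
    t2 = wk @ l1x
    for _ in range(newton_iter):
        g1 = t1 - w * (psi(a) - psi(a + b))
        g2 = t2 - w * (psi(b) - psi(a + b))
        tg_ab = polygamma(1, a + b)
        haa = -w * (polygamma(1, a) - tg_ab)
        hbb = -w * (polygamma(1, b) - tg_ab)
        hab = w * tg_ab
        det = haa * hbb - hab * hab
        ok = det > 0
        det = np.where(ok, det, 1.0)
        da = np.where(ok, -(hbb * g1 - hab * g2) / det, 0.0)
        db = np.where(ok, -(haa * g2 - hab * g1) / det, 0.0)
        # damp: limit each multiplicative change to a factor of 5
        a_new = np.clip(a + da, a / 5.0, a * 5.0)
        b_new = np.clip(b + db, b / 5.0, b * 5.0)
        a = np.clip(a_new, _SHAPE_MIN, _SHAPE_MAX)
        b = np.clip(b_new, _SHAPE_MIN, _SHAPE_MAX)
        if np.max(np.abs(da)) < 1e-8 and np.max(np.abs(db)) < 1e-8:
            break

    q_newton = _component_q(a, b, t1, t2, w)
    q_mom = _component_q(a_mom, b_mom, t1, t2, w)
    worse = q_newton < q_mom
    a = np.where(worse, a_mom, a)
    b = np.where(worse, b_mom, b)
    if old_a is not None:
        q_cur = _component_q(a, b, t1, t2, w)
        q_old = _component_q(old_a, old_b, t1, t2, w)
        keep_old = q_cur < q_old
        a = np.where(keep_old, old_a, a)
        b = np.where(keep_old, old_b, b)
    return a, b


def _loglik_matrix(lx, l1x, a, b):
    """Per-locus log density under each component; a, b are (K, S)."""
    return lx @ (a - 1.0).T + l1x @ (b - 1.0).T - betaln(a, b).sum(axis=1)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    cut = np.searchsorted(cw, 0.5 * cw[-1])
    return float(values[order][min(cut, len(values) - 1)])


@dataclass
class BetaMixtureFit:
    pi: np.ndarray              # (K,)
    a: np.ndarray               # (K, S)
    b: np.ndarray               # (K, S)
    resp: np.ndarray            # (L, K)
    loglik: float
    ll_trace: list
    converged: bool
    degenerate: bool            # a component collapsed below min_weight


def fit_beta_mixture_em(
    matrix,
    weights=None,
    K: int = 2,
    *,
    eps: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_weight: float = 1e-3,
) -> BetaMixtureFit:
    """Weighted EM for a K-component per-subject beta mixture over loci.

    ``matrix`` is loci x subjects (DataFrame or array); ``weights`` are
    per-locus membership weights inherited from the parent node (ones by
    default). Beta values are clipped to [eps, 1-eps] before likelihood
    evaluation. Returns the fit with the full log-likelihood trace; if a
    component's mixing weight falls below ``min_weight`` the fit is marked
    degenerate and the caller should fall back to a single component.
    """
    x = _clip_beta(np.asarray(matrix, dtype=float), eps)
    n_loci = x.shape[0]
    if weights is None:
        weights = np.ones(n_loci)
    weights = np.asarray(weights, dtype=float)
    if np.count_nonzero(weights) < 2 * K:
        raise ValueError(f"need >= {2 * K} loci with nonzero weight")
    lx = np.log(x)
    l1x = np.log1p(-x)

    # deterministic initialization: hard split at the weighted median of
    # locus mean methylation (rank halves when the median is degenerate)
    locus_mean = x.mean(axis=1)
    resp = np.zeros((n_loci, K))
    if K == 1:
        resp[:, 0] = 1.0
    else:
        med = _weighted_median(locus_mean, weights)
        low = locus_mean <= med
        if low.all() or not low.any():
            order = np.argsort(locus_mean, kind="stable")
            low = np.zeros(n_loci, bool)
            low[order[: n_loci // 2]] = True
        resp[low, 0] = 1.0
        resp[~low, -1] = 1.0
        if K > 2:  # spread middle components evenly by rank
            order = np.argsort(locus_mean, kind="stable")
            resp[:] = 0.0
            for k in range(K):
                resp[order[(n_loci * k) // K:(n_loci * (k + 1)) // K], k] = 1.0

    a = np.zeros((K, x.shape[1]))
    b = np.zeros_like(a)
    old_a = old_b = None
    pi = np.full(K, 1.0 / K)
    trace: list[float] = []
    loglik = -np.inf
    converged = degenerate = False
    for _ in range(max_iter):
        wk_all = weights[:, None] * resp
        comp_w = wk_all.sum(axis=0)
        pi = comp_w / comp_w.sum()
        if np.any(pi < min_weight):
            degenerate = True
            break
        for k in range(K):
            oa = old_a[k] if old_a is not None else None
            ob = old_b[k] if old_b is not None else None
            a[k], b[k] = _mstep_shapes(wk_all[:, k], x, lx, l1x, oa, ob)
        old_a, old_b = a.copy(), b.copy()

        ll_mat = _loglik_matrix(lx, l1x, a, b) + np.log(pi)
        m = ll_mat.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(ll_mat - m).sum(axis=1))
        new_loglik = float(weights @ lse)
        resp = np.exp(ll_mat - lse[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (1.0 + abs(loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    return BetaMixtureFit(pi=pi, a=a.copy(), b=b.copy(), resp=resp,
                          loglik=loglik, ll_trace=trace,
                          converged=converged, degenerate=degenerate)


@dataclass
class RpmmNode:
    label: str                  # binary path from the root ("" = root)
    depth: int
    weights: np.ndarray         # per-locus membership weight
    a: np.ndarray | None = None  # single-component per-subject shapes
    b: np.ndarray | None = None
    split_bic: float | None = None
    single_bic: float | None = None
    split_trace: list | None = None     # EM log-likelihood trace of the 2-way fit
    children: tuple | None = None

    @property
    def is_terminal(self) -> bool:
        return self.children is None

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "depth": self.depth,
            "n_effective": float(self.weights.sum()),
            "single_bic": self.single_bic,
            "split_bic": self.split_bic,
        }
        if self.children is not None:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class RpmmTree:
    root: RpmmNode
    subjects: list
    max_depth: int

    def terminal_nodes(self) -> list:
        out: list[RpmmNode] = []

        def walk(node: RpmmNode) -> None:
            if node.is_terminal:
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


@dataclass
class ClassAssignment:
    labels: np.ndarray          # per-locus class index, 1..K
    class_means: np.ndarray     # mean beta per class
    class_sizes: np.ndarray
    node_labels: list = field(default_factory=list)
    locus_ids: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_means)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.locus_ids, name="class")


def order_classes(assignment: ClassAssignment) -> ClassAssignment:
    """Renumber classes by increasing mean methylation.

    Ties on the mean are broken by class size, the larger class taking the
    lower index.
    """
    order = sorted(
        range(assignment.n_classes),
        key=lambda k: (assignment.class_means[k], -assignment.class_sizes[k]),
    )
    relabel = np.empty(assignment.n_classes, dtype=int)
    for new, old in enumerate(order):
        relabel[old] = new + 1
    return ClassAssignment(
        labels=relabel[assignment.labels - 1],
        class_means=assignment.class_means[order],
        class_sizes=assignment.class_sizes[order],
        node_labels=[assignment.node_labels[k] for k in order]
        if assignment.node_labels else [],
        locus_ids=assignment.locus_ids,
    )


def rpmm_fit(
    matrix,
    max_depth: int = 4,
    *,
    eps: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_weight: float = 1e-3,
    weight_floor: float = 1e-8,
) -> tuple[RpmmTree, ClassAssignment]:
    """Fit the recursive beta-mixture tree and assign loci to classes.

    At each node a 2-component split is accepted iff its BIC (penalty: two
    shapes per subject per component plus one mixing weight, against the
    node's effective locus count) improves on the unsplit node's BIC.
    Loci are hard-assigned to the terminal node with the largest membership
    weight; classes are then renumbered by increasing mean methylation.
    """
    if isinstance(matrix, pd.DataFrame):
        locus_ids = list(matrix.index)
        subjects = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        locus_ids = list(range(x.shape[0]))
        subjects = list(range(x.shape[1]))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 loci")
    n_loci, n_subj = x.shape
    xc = _clip_beta(x, eps)

    em_kw = dict(eps=eps, tol=tol, max_iter=max_iter, min_weight=min_weight)

    def grow(node: RpmmNode) -> None:
        active = node.weights > weight_floor
        w_act = node.weights[active]
        n_eff = float(w_act.sum())
        sub = xc[active]
        single = fit_beta_mixture_em(sub, w_act, K=1, **em_kw)
        node.a, node.b = single.a[0], single.b[0]
        node.single_bic = -2.0 * single.loglik + (2 * n_subj) * np.log(max(n_eff, 2.0))
        if node.depth >= max_depth or active.sum() < 4:
            return
        split = fit_beta_mixture_em(sub, w_act, K=2, **em_kw)
        node.split_trace = split.ll_trace
        if split.degenerate:
            return
        node.split_bic = -2.0 * split.loglik + (4 * n_subj + 1) * np.log(max(n_eff, 2.0))
        if node.split_bic >= node.single_bic:
            return
        children = []
        for k in range(2):
            w_child = np.zeros(n_loci)
            w_child[active] = w_act * split.resp[:, k]
            children.append(RpmmNode(label=node.label + str(k),
                                     depth=node.depth + 1, weights=w_child))
        node.children = tuple(children)
        for c in node.children:
            grow(c)

    root = RpmmNode(label="", depth=0, weights=np.ones(n_loci))
    grow(root)
    tree = RpmmTree(root=root, subjects=subjects, max_depth=max_depth)

    terminals = tree.terminal_nodes()
    term_weights = np.stack([t.weights for t in terminals], axis=1)
    hard = term_weights.argmax(axis=1)
    means = np.array([
        x[hard == t].mean() if np.any(hard == t) else np.nan
        for t in range(len(terminals))
    ])
    keep = ~np.isnan(means)  # drop terminals that captured no locus
    remap = -np.ones(len(terminals), dtype=int)
    remap[keep] = np.arange(keep.sum())
    hard = remap[hard]
    means = means[keep]
    sizes = np.bincount(hard, minlength=int(keep.sum()))
    assignment = ClassAssignment(
        labels=hard + 1,
        class_means=means,
        class_sizes=sizes,
        node_labels=[t.label for t, k in zip(terminals, keep) if k],
        locus_ids=locus_ids,
    )
    return tree, order_classes(assignment)
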