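"""Sparse generalized canonical correlation analysis (SGCCA).

Fits, for J standardized data views X_1..X_J, per-view weight vectors w_j
maximizing the design-weighted multi-block criterion

    sum_{j<l} c_jl * g(cov(X_j w_j, X_l w_l))

subject to ||w_j||_2 <= 1 and ||w_j||_1 <= s_j, where g is the scheme
function (horst: identity, centroid: absolute value, factorial: square), c is
a symmetric nonnegative design matrix connecting the views, and s_j =
lambda_j * sqrt(p_j) is the per-view L1 budget (lambda_j = 1 disables the L1
constraint because the L2 ball then lies inside the L1 ball).

Optimization is block-coordinate ascent: each w_j in turn is replaced by the
projection of its partial gradient onto the intersection of the L2 and L1
balls (soft-thresholding with the threshold located by bisection, followed by
L2 normalization). Each update maximizes a linear minorant of the criterion
over the feasible set, so the recorded objective is nondecreasing. Successive
components are obtained by deflating each view by its own component score,
which makes within-view scores of distinct components orthogonal on the
training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import MultiViewDataset

SCHEMES = ("horst", "centroid", "factorial")


# ---------------------------------------------------------------------------
# constraint projection


def project_l1l2(a: np.ndarray, s: float, tol: float = 1e-10) -> np.ndarray | None:
    """Project direction ``a`` onto {||w||2 <= 1, ||w||1 <= s} (s >= 1).

    Returns the maximizer of <a, w> over the set: soft-threshold ``a`` at the
    smallest threshold making the L2-normalized result satisfy the L1 budget,
    the threshold found by bisection to ``tol`` on the L1 norm. Returns None
    for a zero direction (caller keeps the current weights).
    """
    norm_a = float(np.linalg.norm(a))
    if norm_a == 0.0:
        return None
    w = a / norm_a
    if float(np.abs(w).sum()) <= s + tol:
        return w

    abs_a = np.abs(a)
    lo, hi = 0.0, float(abs_a.max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        shrunk = np.sign(a) * np.maximum(abs_a - mid, 0.0)
        nrm = float(np.linalg.norm(shrunk))
        l1 = float(np.abs(shrunk).sum()) / nrm if nrm > 0 else 0.0
        if l1 > s:
            lo = mid
        else:
            hi = mid
        if abs(l1 - s) < tol and l1 <= s + tol:
            return shrunk / nrm
    shrunk = np.sign(a) * np.maximum(abs_a - hi, 0.0)
    nrm = float(np.linalg.norm(shrunk))
    if nrm == 0.0:
        # threshold collapsed everything; keep the largest coordinate only
        w = np.zeros_like(a)
        j = int(np.argmax(abs_a))
        w[j] = np.sign(a[j])
        return w
    return shrunk / nrm


# ---------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class SparsityConfig:
    """Per-view shrinkage lambda_j in [1/sqrt(p_j), 1]; L1 budget lambda_j*sqrt(p_j)."""

    lambda_per_view: tuple[float, ...]

    @classmethod
    def uniform(cls, lam: float, n_views: int) -> "SparsityConfig":
        return cls(tuple(float(lam) for _ in range(n_views)))

    def budgets(self, p_per_view: Sequence[int]) -> list[float]:
        if len(self.lambda_per_view) != len(p_per_view):
            raise ValueError(
                f"{len(self.lambda_per_view)} lambdas for {len(p_per_view)} views"
            )
        out = []
        for lam, p in zip(self.lambda_per_view, p_per_view):
            if not 0 < lam <= 1:
                raise ValueError(f"lambda {lam} outside (0, 1]")
            s = lam * np.sqrt(p)
            if s < 1 - 1e-12:
                raise ValueError(
                    f"lambda {lam} below the 1/sqrt(p) floor for p={p}: "
                    "the L1 and L2 constraints would be jointly infeasible"
                )
            out.append(float(max(s, 1.0)))
        return out


def uniform_design(n_views: int) -> np.ndarray:
    """Fully connected design with unit weights (the all-views 'unified' model)."""
    c = np.ones((n_views, n_views)) - np.eye(n_views)
    return c


def _check_design(c: np.ndarray, n_views: int) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.shape != (n_views, n_views):
        raise ValueError(f"design must be {n_views}x{n_views}, got {c.shape}")
    if not np.allclose(c, c.T):
        raise ValueError("design matrix must be symmetric")
    if (c < 0).any():
        raise ValueError("design weights must be nonnegative")
    if np.any(np.diag(c) != 0):
        raise ValueError("design diagonal must be zero")
    if not (c > 0).any():
        raise ValueError("design needs at least one positive off-diagonal entry")
    return c


# ---------------------------------------------------------------------------
# model containers


@dataclass
class SGCCAModel:
    """Fitted per-view weight vectors for K components plus fit settings."""

    weights: list[np.ndarray]  # per view: p_j x K
    scheme: str
    design: np.ndarray
    lambdas: tuple[float, ...]
    n_components: int
    view_names: list[str]
    variable_names: list[list[str]]
    convergence_trace: list[list[float]]  # per component: objective per iteration
    converged: list[bool]
    seed: int = 0

    def weight_frame(self):
        import pandas as pd

        rows = []
        for name, vnames, w in zip(self.view_names, self.variable_names, self.weights):
            for i, v in enumerate(vnames):
                rows.append({"view": name, "variable": v, **{
                    f"comp_{k + 1}": w[i, k] for k in range(self.n_components)
                }})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "scheme": self.scheme,
            "design": self.design.tolist(),
            "lambdas": list(self.lambdas),
            "n_components": self.n_components,
            "view_names": self.view_names,
            "variable_names": self.variable_names,
            "weights": [w.tolist() for w in self.weights],
            "convergence_trace": self.convergence_trace,
            "converged": self.converged,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SGCCAModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            weights=[np.asarray(w, dtype=float) for w in obj["weights"]],
            scheme=obj["scheme"],
            design=np.asarray(obj["design"], dtype=float),
            lambdas=tuple(obj["lambdas"]),
            n_components=obj["n_components"],
            view_names=obj["view_names"],
            variable_names=obj["variable_names"],
            convergence_trace=obj["convergence_trace"],
            converged=obj["converged"],
            seed=obj["seed"],
        )


@dataclass
class Scores:
    """Per-view component scores y_j^(k) = X_j^(k-deflated) w_j^(k)."""

    values: list[np.ndarray]  # per view: n x K
    view_names: list[str]
    participant_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.values[0].shape[1]

    def view(self, name: str) -> np.ndarray:
        return self.values[self.view_names.index(name)]


@dataclass
class AVEReport:
    """Inner and outer average variance explained per component."""

    inner_ave: np.ndarray  # K
    outer_ave_per_view: np.ndarray  # J x K
    cumulative_outer_ave: np.ndarray  # K, nondecreasing
    view_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# fitting


def _scheme_weight(cov: float, scheme: str) -> float:
    """g'(cov): gradient weight of one pairwise covariance term."""
    if scheme == "horst":
        return 1.0
    if scheme == "centroid":
        return 1.0 if cov >= 0 else -1.0
    if scheme == "factorial":
        return 2.0 * cov
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def _scheme_value(cov: float, scheme: str) -> float:
    if scheme == "horst":
        return cov
    if scheme == "centroid":
        return abs(cov)
    return cov * cov


def _init_weight(x: np.ndarray) -> np.ndarray:
    """Leading right singular vector, sign-fixed (largest-|entry| positive)."""
    # economical: eigenvector of the p x p Gram when p <= n, else via SVD
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    w = vt[0]
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w = -w
    return w


def _pair_cov(c_blocks, ws, j, l):
    if j < l:
        return float(ws[j] @ c_blocks[(j, l)] @ ws[l])
    return float(ws[l] @ c_blocks[(l, j)] @ ws[j])


def _objective(c_blocks, ws, design, scheme) -> float:
    total = 0.0
    J = len(ws)
    for j in range(J):
        for l in range(j + 1, J):
            if design[j, l] == 0:
                continue
            total += design[j, l] * _scheme_value(_pair_cov(c_blocks, ws, j, l), scheme)
    return total


def _fit_component(
    xs: list[np.ndarray],
    design: np.ndarray,
    budgets: list[float],
    scheme: str,
    tol: float,
    max_iter: int,
    init_weights: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[float], bool]:
    n = xs[0].shape[0]
    J = len(xs)
    c_blocks = {
        (j, l): xs[j].T @ xs[l] / (n - 1)
        for j in range(J)
        for l in range(j + 1, J)
        if design[j, l] > 0
    }
    if init_weights is not None:
        ws = [np.asarray(w, dtype=float).copy() for w in init_weights]
    else:
        ws = [_init_weight(x) for x in xs]
        # continuation: when an L1 budget binds, start from the unconstrained
        # optimum rather than the per-view SVD — block ascent started cold at
        # a sparse budget is prone to poor local optima
        if any(s < np.sqrt(x.shape[1]) - 1e-9 for s, x in zip(budgets, xs)):
            free = [float(np.sqrt(x.shape[1])) for x in xs]
            ws, _, _ = _fit_component(xs, design, free, scheme, tol, max_iter)
    # make the start feasible under the L1 budget
    for j in range(J):
        proj = project_l1l2(ws[j], budgets[j])
        if proj is not None:
            ws[j] = proj

    trace = [_objective(c_blocks, ws, design, scheme)]
    converged = False
    for _ in range(max_iter):
        for j in range(J):
            grad = np.zeros_like(ws[j])
            for l in range(J):
                if l == j or design[j, l] == 0:
                    continue
                cov = _pair_cov(c_blocks, ws, j, l)
                gw = _scheme_weight(cov, scheme)
                block = c_blocks[(j, l)] if j < l else c_blocks[(l, j)].T
                grad += design[j, l] * gw * (block @ ws[l])
            proj = project_l1l2(grad, budgets[j])
            if proj is not None:
                ws[j] = proj
        obj = _objective(c_blocks, ws, design, scheme)
        trace.append(obj)
        prev = trace[-2]
        if abs(obj - prev) <= tol * max(abs(prev), 1e-12):
            converged = True
            break
    return ws, trace, converged


def _apply_sign_convention(
    ws: list[np.ndarray], ys: list[np.ndarray], design: np.ndarray, anchor: int, scheme: str
) -> list[np.ndarray]:
    """Resolve per-component sign indeterminacy for stable reporting.

    The anchor (clinical) view is flipped so its largest-magnitude weight is
    positive; every other view is flipped so its score covaries positively
    with the anchor score (fallback: own largest-entry rule). Per-view flips
    leave the centroid and factorial objectives invariant; under the horst
    scheme only a simultaneous flip of all views preserves the objective, so
    only the anchor rule is applied globally there.
    """
    flips = np.ones(len(ws))
    wa = ws[anchor]
    j = int(np.argmax(np.abs(wa)))
    if wa[j] < 0:
        flips[anchor] = -1.0
    if scheme == "horst":
        return [w * flips[anchor] for w in ws]
    ya = ys[anchor] * flips[anchor]
    for v in range(len(ws)):
        if v == anchor:
            continue
        cov = design[v, anchor] * float(ys[v] @ ya)
        if cov < 0:
            flips[v] = -1.0
        elif cov == 0:
            k = int(np.argmax(np.abs(ws[v])))
            if ws[v][k] < 0:
                flips[v] = -1.0
    return [w * f for w, f in zip(ws, flips)]


def fit_sgcca(
    dataset: MultiViewDataset,
    design: np.ndarray | None = None,
    sparsity: SparsityConfig | float = 1.0,
    n_components: int = 1,
    scheme: str = "centroid",
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    anchor_view: str | int = 0,
    init_weights: list[np.ndarray] | None = None,
) -> SGCCAModel:
    """Fit K sparse canonical components to standardized, aligned views.

    ``sparsity`` may be a scalar lambda applied to every view or a full
    :class:`SparsityConfig`. ``anchor_view`` names the view whose component
    sign is fixed first (by convention the clinical view). ``init_weights``
    warm-starts the first component (one feasible vector per view), e.g. from
    a fit at a neighboring sparsity level when tracing a regularization path;
    the default start is each view's leading right singular vector.
    """
    xs = [x.copy() for x in dataset.matrices()]
    if xs[0].shape[0] < 3:
        raise ValueError("need at least 3 participants")
    if len(xs) < 2:
        raise ValueError("need at least 2 views")
    J = len(xs)
    design = uniform_design(J) if design is None else _check_design(design, J)
    if isinstance(sparsity, (int, float)):
        sparsity = SparsityConfig.uniform(float(sparsity), J)
    budgets = sparsity.budgets([x.shape[1] for x in xs])
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    anchor = anchor_view if isinstance(anchor_view, int) else dataset.view_names.index(anchor_view)

    weights = [np.zeros((x.shape[1], n_components)) for x in xs]
    traces: list[list[float]] = []
    converged: list[bool] = []
    for k in range(n_components):
        ws, trace, ok = _fit_component(
            xs, design, budgets, scheme, tol, max_iter,
            init_weights=init_weights if k == 0 else None,
        )
        ys = [x @ w for x, w in zip(xs, ws)]
        ws = _apply_sign_convention(ws, ys, design, anchor, scheme)
        ys = [x @ w for x, w in zip(xs, ws)]
        for j in range(J):
            weights[j][:, k] = ws[j]
        traces.append(trace)
        converged.append(ok)
        if k + 1 < n_components:  # own-block deflation
            for j in range(J):
                y = ys[j]
                denom = float(y @ y)
                if denom > 0:
                    xs[j] = xs[j] - np.outer(y, y @ xs[j]) / denom
    return SGCCAModel(
        weights=weights,
        scheme=scheme,
        design=design,
        lambdas=sparsity.lambda_per_view,
        n_components=n_components,
        view_names=list(dataset.view_names),
        variable_names=[list(v.variable_names) for v in dataset.views],
        convergence_trace=traces,
        converged=converged,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# projection of (new) data and AVE


def transform(model: SGCCAModel, dataset: MultiViewDataset) -> Scores:
    """Project a dataset through the model, replaying deflation with its weights.

    Component k scores are computed on the k-times-deflated matrices, so
    transforming the training data reproduces the fitted training scores.
    """
    if [v.name for v in dataset.views] != model.view_names:
        raise ValueError(
            f"dataset views {[v.name for v in dataset.views]} do not match the "
            f"model's views {model.view_names} (order matters)"
        )
    xs = []
    for v in dataset.views:
        j = model.view_names.index(v.name)
        expect = model.variable_names[j]
        if v.variable_names != expect:
            missing = [x for x in expect if x not in v.variable_names]
            extra = [x for x in v.variable_names if x not in expect]
            raise ValueError(
                f"view {v.name!r} variables do not match the model "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
        xs.append(v.values.copy())
    K = model.n_components
    out = [np.zeros((x.shape[0], K)) for x in xs]
    # a view deflated below numerical noise yields exact-zero scores, keeping
    # later components of rank-deficient data from amplifying rounding error
    floors = [1e-10 * max(np.linalg.norm(x), 1.0) for x in xs]
    for k in range(K):
        for j, x in enumerate(xs):
            if np.linalg.norm(x) <= floors[j]:
                xs[j] = np.zeros_like(x)
                continue
            y = x @ model.weights[j][:, k]
            out[j][:, k] = y
            denom = float(y @ y)
            if denom > 0 and k + 1 < K:
                xs[j] = x - np.outer(y, y @ x) / denom
    return Scores(values=out, view_names=list(model.view_names), participant_ids=list(dataset.participant_ids))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    # exactly-zero scores (view deflated to nothing) contribute zero coupling;
    # a constant-but-nonzero score is a genuine degeneracy and an error
    if not a.any() or not b.any():
        return 0.0
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance score in AVE computation")
    return float(ac @ bc / (na * nb))


def inner_ave(scores: Scores, design: np.ndarray) -> np.ndarray:
    """Design-weighted mean squared score correlation per component."""
    J = len(scores.values)
    K = scores.n_components
    total_weight = sum(design[j, l] for j in range(J) for l in range(j + 1, J))
    out = np.zeros(K)
    for k in range(K):
        acc = 0.0
        for j in range(J):
            for l in range(j + 1, J):
                if design[j, l] == 0:
                    continue
                acc += design[j, l] * _corr(scores.values[j][:, k], scores.values[l][:, k]) ** 2
        out[k] = acc / total_weight
    return out


def compute_ave(scores: Scores, dataset: MultiViewDataset, design: np.ndarray) -> AVEReport:
    """Inner and outer AVE of the given scores on the given data.

    Outer AVE of component k for a view is the mean squared correlation of the
    view's original (non-deflated) variables with the component score. Own-
    block deflation makes within-view scores orthogonal, so per-component
    contributions are disjoint and the cumulative outer AVE — views weighted
    by their variable counts, matching the "variance among all data views"
    summary — stays within [0, 1].
    """
    J = len(dataset.views)
    design = _check_design(design, J)
    K = scores.n_components
    inner = inner_ave(scores, design)
    outer = np.zeros((J, K))
    ps = [v.p for v in dataset.views]
    for j, v in enumerate(dataset.views):
        x = v.values
        xc = x - x.mean(axis=0)
        nx = np.linalg.norm(xc, axis=0)
        for k in range(K):
            y = scores.values[j][:, k]
            if not y.any():
                outer[j, k] = 0.0
                continue
            yc = y - y.mean()
            ny = np.linalg.norm(yc)
            if ny == 0:
                raise ValueError(f"zero-variance score: view {v.name!r}, component {k + 1}")
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(nx > 0, (xc.T @ yc) / (nx * ny), 0.0)
            outer[j, k] = float(np.mean(r**2))
    weights = np.asarray(ps, dtype=float)
    cumulative = np.cumsum(weights @ outer) / weights.sum()
    return AVEReport(
        inner_ave=inner,
        outer_ave_per_view=outer,
        cumulative_outer_ave=cumulative,
        view_names=list(dataset.view_names),
    )
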