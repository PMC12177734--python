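"""Sparsity tuning, component-count selection, stability selection, final refit.

The sparsity level is chosen on the training sample by a permutation z-score:
at each grid value the total inner AVE of the fitted model is compared with
models fitted to data whose participants were permuted independently within
each view (which destroys cross-view covariance while preserving each view's
internal structure). The number of components is read off the cumulative
outer-AVE curve, variables are screened by subsampled refits (stability
selection), and the final model refits the retained variables with the L1
constraint disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .data import MultiViewDataset
from .sgcca import (
    AVEReport,
    SGCCAModel,
    SparsityConfig,
    compute_ave,
    fit_sgcca,
    inner_ave,
    transform,
)

NONZERO_TOL = 1e-12


def clipped_lambdas(lam: float, p_per_view: list[int]) -> SparsityConfig:
    """Uniform lambda clipped per view to its feasibility floor 1/sqrt(p_j)."""
    return SparsityConfig(tuple(min(1.0, max(lam, 1.0 / np.sqrt(p))) for p in p_per_view))


def permute_within_views(dataset: MultiViewDataset, rng: np.random.Generator) -> MultiViewDataset:
    """Permute participant rows independently within each view (null model)."""
    n = dataset.n
    return dataset.with_values([v.values[rng.permutation(n)] for v in dataset.views])


def _total_inner_ave(
    dataset: MultiViewDataset, design, sparsity, n_components, scheme, seed
) -> float:
    model = fit_sgcca(
        dataset, design=design, sparsity=sparsity, n_components=n_components,
        scheme=scheme, seed=seed,
    )
    scores = transform(model, dataset)
    return float(inner_ave(scores, model.design).sum())


def lambda_objective_path(
    train: MultiViewDataset,
    lambdas,
    design: np.ndarray | None = None,
    scheme: str = "centroid",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Converged single-component objective along an increasing lambda ladder.

    The ladder is traced by continuation: each fit is warm-started from the
    solution at the previous (smaller) lambda, which is feasible under the
    larger budget. Combined with monotone ascent this guarantees the returned
    objectives are nondecreasing in lambda, which independent cold starts do
    not (block-coordinate ascent only reaches local optima).
    """
    ps = [v.p for v in train.views]
    objs = []
    init = None
    for lam in np.sort(np.asarray(lambdas, dtype=float)):
        model = fit_sgcca(
            train, design=design, sparsity=clipped_lambdas(float(lam), ps),
            n_components=1, scheme=scheme, tol=tol, max_iter=max_iter,
            init_weights=init,
        )
        objs.append(model.convergence_trace[0][-1])
        init = [w[:, 0] for w in model.weights]
    return np.asarray(objs)


@dataclass
class SparsityTuningResult:
    lambda_grid: np.ndarray
    observed: np.ndarray  # total inner AVE per lambda
    null_mean: np.ndarray
    null_sd: np.ndarray
    z_per_lambda: np.ndarray
    n_perm: int
    chosen_lambda: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "observed_inner_ave": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z_per_lambda,
            }
        )


def default_lambda_grid() -> np.ndarray:
    return np.round(np.linspace(0.1, 1.0, 10), 10)


def tune_sparsity(
    train: MultiViewDataset,
    design: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    n_components_for_tuning: int = 1,
    n_perm: int = 200,
    seed: int = 0,
    scheme: str = "centroid",
    n_jobs: int = 1,
) -> SparsityTuningResult:
    """Choose lambda maximizing the permutation z of the total inner AVE.

    Grid values below a view's 1/sqrt(p) feasibility floor are clipped per
    view. Ties in z are broken toward the smaller lambda. Deterministic for a
    fixed seed regardless of ``n_jobs``.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.sort(np.asarray(lambda_grid, float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if (grid <= 0).any() or (grid > 1).any():
        raise ValueError("lambda grid values must lie in (0, 1]")
    ps = [v.p for v in train.views]
    root = np.random.SeedSequence(seed)
    perm_seeds = root.generate_state(grid.size * n_perm).reshape(grid.size, n_perm)

    def one_lambda(i: int) -> tuple[float, np.ndarray]:
        spars = clipped_lambdas(float(grid[i]), ps)
        obs = _total_inner_ave(train, design, spars, n_components_for_tuning, scheme, seed)
        nulls = np.empty(n_perm)
        for b in range(n_perm):
            rng = np.random.default_rng(int(perm_seeds[i, b]))
            permuted = permute_within_views(train, rng)
            nulls[b] = _total_inner_ave(
                permuted, design, spars, n_components_for_tuning, scheme, seed
            )
        return obs, nulls

    results = Parallel(n_jobs=n_jobs)(delayed(one_lambda)(i) for i in range(grid.size))
    observed = np.array([r[0] for r in results])
    null_mean = np.array([r[1].mean() for r in results])
    null_sd = np.array([r[1].std(ddof=1) for r in results])
    if (null_sd == 0).any():
        bad = grid[null_sd == 0]
        raise ValueError(f"degenerate permutation null (sd = 0) at lambda {bad}")
    z = (observed - null_mean) / null_sd
    chosen = float(grid[int(np.argmax(z))])  # argmax returns the first (smallest) maximizer
    return SparsityTuningResult(grid, observed, null_mean, null_sd, z, n_perm, chosen)


@dataclass
class ComponentCurve:
    cumulative_outer_ave: np.ndarray  # K_max, nondecreasing
    chosen_k: int
    epsilon: float

    @property
    def marginal_gains(self) -> np.ndarray:
        return np.diff(self.cumulative_outer_ave, prepend=0.0)


def select_n_components(
    train: MultiViewDataset,
    design: np.ndarray | None = None,
    sparsity: SparsityConfig | float = 1.0,
    k_max: int = 10,
    epsilon: float = 0.01,
    scheme: str = "centroid",
    seed: int = 0,
    override_k: int | None = None,
) -> ComponentCurve:
    """Pick the component count where the cumulative outer-AVE curve levels off.

    Fits ``k_max`` components once; the chosen K is the last component whose
    marginal gain in cumulative outer AVE is at least ``epsilon`` (so
    ``epsilon = 0`` keeps all ``k_max`` components). ``override_k`` forces a
    manual choice while still reporting the full curve.
    """
    if k_max > min(v.p for v in train.views):
        raise ValueError("k_max exceeds the smallest view dimension")
    model = fit_sgcca(
        train, design=design, sparsity=sparsity, n_components=k_max, scheme=scheme, seed=seed
    )
    scores = transform(model, train)
    ave = compute_ave(scores, train, model.design)
    curve = ave.cumulative_outer_ave
    gains = np.diff(curve, prepend=0.0)
    qualifying = np.flatnonzero(gains >= epsilon)
    chosen = int(qualifying[-1]) + 1 if qualifying.size else 1
    if override_k is not None:
        chosen = int(override_k)
    return ComponentCurve(cumulative_outer_ave=curve, chosen_k=chosen, epsilon=epsilon)


@dataclass
class StabilityResult:
    selection_frequency: dict[str, np.ndarray]  # view -> per-variable frequency
    variable_names: dict[str, list[str]]
    n_subsamples: int
    subsample_fraction: float
    retention_threshold: float

    @property
    def retained(self) -> dict[str, list[str]]:
        return {
            view: [
                name
                for name, f in zip(self.variable_names[view], freq)
                if f >= self.retention_threshold
            ]
            for view, freq in self.selection_frequency.items()
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for view, freq in self.selection_frequency.items():
            for name, f in zip(self.variable_names[view], freq):
                rows.append(
                    {
                        "view": view,
                        "variable": name,
                        "frequency": f,
                        "retained": bool(f >= self.retention_threshold),
                    }
                )
        return pd.DataFrame(rows)


def stability_selection(
    train: MultiViewDataset,
    design: np.ndarray | None = None,
    sparsity: SparsityConfig | float = 0.3,
    n_components: int = 1,
    n_subsamples: int = 200,
    subsample_fraction: float = 0.5,
    retention_threshold: float = 0.9,
    seed: int = 0,
    scheme: str = "centroid",
    n_jobs: int = 1,
    skip_views: tuple[str, ...] = (),
) -> StabilityResult:
    """Selection frequency of every variable over subsampled SGCCA refits.

    Each subsample draws ``subsample_fraction`` of the training participants
    without replacement and refits; a variable counts as selected when its
    weight is nonzero in any component. Views listed in ``skip_views`` are
    exempt from screening: they are reported with frequency 1 everywhere.
    Deterministic for a fixed seed regardless of ``n_jobs``.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    n = train.n
    m = int(np.floor(subsample_fraction * n))
    if m < 3:
        raise ValueError(f"subsample of {m} participants is too small")
    ids = train.participant_ids
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_subsamples)

    def one_subsample(b: int) -> list[np.ndarray]:
        rng = np.random.default_rng(int(sub_seeds[b]))
        keep = sorted(rng.choice(n, size=m, replace=False))
        sub = train.subset_participants([ids[i] for i in keep])
        model = fit_sgcca(
            sub, design=design, sparsity=sparsity, n_components=n_components,
            scheme=scheme, seed=seed,
        )
        return [(np.abs(w) > NONZERO_TOL).any(axis=1) for w in model.weights]

    hits = Parallel(n_jobs=n_jobs)(delayed(one_subsample)(b) for b in range(n_subsamples))
    view_names = train.view_names
    freq = {}
    for j, view in enumerate(view_names):
        counts = np.sum([h[j] for h in hits], axis=0)
        f = counts / n_subsamples
        if view in skip_views:
            f = np.ones_like(f, dtype=float)
        freq[view] = f.astype(float)
    return StabilityResult(
        selection_frequency=freq,
        variable_names={v.name: list(v.variable_names) for v in train.views},
        n_subsamples=n_subsamples,
        subsample_fraction=subsample_fraction,
        retention_threshold=retention_threshold,
    )


def refit_final(
    train: MultiViewDataset,
    retained: dict[str, list[str]],
    n_components: int,
    design: np.ndarray | None = None,
    lam: float = 1.0,
    scheme: str = "centroid",
    seed: int = 0,
) -> tuple[SGCCAModel, AVEReport]:
    """Refit on the retained variables with the L1 constraint disabled."""
    empty = [v for v, names in retained.items() if len(names) == 0]
    if empty:
        raise ValueError(f"stability selection retained no variables in view(s) {empty}")
    sub = train.subset_variables(retained)
    model = fit_sgcca(
        sub, design=design, sparsity=lam, n_components=n_components, scheme=scheme, seed=seed
    )
    scores = transform(model, sub)
    ave = compute_ave(scores, sub, model.design)
    return model, ave
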