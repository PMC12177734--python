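"""Permutation significance, score regression, structural coefficients.

Significance of each canonical component is assessed against models fitted to
participant-permuted training data, in both the training sample (observed
training inner AVE ranked among the randomized models' training inner AVEs)
and the held-out sample (test data projected through the actual and each
randomized model). Clinical component scores are then regressed on the seven
neuroimaging component scores with bootstrap confidence intervals, and each
component score is correlated back to its view's original variables
(structural coefficients) with bootstrap significance and
Benjamini-Hochberg control within each component x view family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import MultiViewDataset
from .model_selection import permute_within_views
from .sgcca import SGCCAModel, Scores, fit_sgcca, inner_ave, transform


# ---------------------------------------------------------------------------
# permutation significance


@dataclass
class PermutationTestResult:
    """Observed inner AVE per component ranked against a permutation null."""

    context: str  # "train" or "test"
    observed: np.ndarray  # K
    null_draws: np.ndarray  # B x K
    z: np.ndarray  # K
    p_perm: np.ndarray  # K

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, self.observed.size + 1)
        return pd.DataFrame(
            {
                "component": k,
                "context": self.context,
                "observed_inner_ave": self.observed,
                "null_mean": self.null_draws.mean(axis=0),
                "null_sd": self.null_draws.std(axis=0, ddof=1),
                "z": self.z,
                "p_perm": self.p_perm,
            }
        )


def _rank_against_null(observed: np.ndarray, nulls: np.ndarray, context: str) -> PermutationTestResult:
    b = nulls.shape[0]
    p = (1 + (nulls >= observed[None, :]).sum(axis=0)) / (b + 1)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - nulls.mean(axis=0)) / sd, np.nan)
    return PermutationTestResult(context=context, observed=observed, null_draws=nulls, z=z, p_perm=p)


def permutation_significance(
    model: SGCCAModel,
    train: MultiViewDataset,
    test: MultiViewDataset,
    n_perm: int = 200,
    seed: int = 0,
    n_jobs: int = 1,
) -> dict[str, PermutationTestResult]:
    """Per-component permutation z and P in the training and test contexts.

    ``n_perm`` randomized models are fitted to training data whose
    participants were permuted independently within each view, with the same
    settings as ``model``. The test-context null reuses those randomized
    models: the test data are projected through each of them and through the
    actual model, and the inner AVEs are compared.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = model.design
    refit = dict(
        design=design,
        sparsity=_sparsity_of(model),
        n_components=model.n_components,
        scheme=model.scheme,
        seed=model.seed,
    )
    obs_train = inner_ave(transform(model, train), design)
    obs_test = inner_ave(transform(model, test), design)

    perm_seeds = np.random.SeedSequence(seed).generate_state(n_perm)

    def one_perm(b: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(int(perm_seeds[b]))
        permuted = permute_within_views(train, rng)
        null_model = fit_sgcca(permuted, **refit)
        null_train = inner_ave(transform(null_model, permuted), design)
        null_test = inner_ave(transform(null_model, test), design)
        return null_train, null_test

    draws = Parallel(n_jobs=n_jobs)(delayed(one_perm)(b) for b in range(n_perm))
    null_train = np.array([d[0] for d in draws])
    null_test = np.array([d[1] for d in draws])
    return {
        "train": _rank_against_null(obs_train, null_train, "train"),
        "test": _rank_against_null(obs_test, null_test, "test"),
    }


def _sparsity_of(model: SGCCAModel):
    from .sgcca import SparsityConfig

    return SparsityConfig(tuple(model.lambdas))


# ---------------------------------------------------------------------------
# bootstrap helpers


def _bootstrap_p(estimates: np.ndarray, boots: np.ndarray, method: str) -> np.ndarray:
    """Two-sided bootstrap p per column of ``boots`` against a zero null."""
    if method == "normal":
        se = boots.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(se > 0, estimates / se, np.inf * np.sign(estimates))
        return 2 * stats.norm.sf(np.abs(z))
    if method == "percentile":
        b = boots.shape[0]
        below = (boots < 0).sum(axis=0)
        above = (boots > 0).sum(axis=0)
        return np.minimum(1.0, 2 * (np.minimum(below, above) + 1) / (b + 1))
    raise ValueError(f"unknown bootstrap p method {method!r}")


def _bootstrap_ci(
    estimates: np.ndarray, boots: np.ndarray, method: str, level: float = 0.95
) -> np.ndarray:
    """95% bootstrap interval per column; bias-corrected percentile by default.

    The plain percentile interval under-covers for statistics with finite-
    sample bias (the regression fit r is biased away from zero by overfitting,
    and resampling doubles that bias); the bias-corrected (BC) interval shifts
    the percentile endpoints by the estimated median bias and restores nominal
    coverage.
    """
    alpha = 1 - level
    if method == "percentile":
        return np.quantile(boots, [alpha / 2, 1 - alpha / 2], axis=0).T
    if method == "bc":
        b = boots.shape[0]
        frac = ((boots < estimates[None, :]).sum(axis=0)
                + 0.5 * (boots == estimates[None, :]).sum(axis=0)) / b
        z0 = stats.norm.ppf(np.clip(frac, 1 / (b + 1), 1 - 1 / (b + 1)))
        lo = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
        hi = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
        out = np.empty((estimates.size, 2))
        for j in range(estimates.size):
            out[j] = np.quantile(boots[:, j], [lo[j], hi[j]])
        return out
    raise ValueError(f"unknown bootstrap CI method {method!r}")


# ---------------------------------------------------------------------------
# regression of clinical on neuroimaging scores


@dataclass
class ComponentRegressionResult:
    """OLS of one clinical component score on the imaging component scores."""

    component: int
    r: float
    r_ci: tuple[float, float]
    r_p: float
    predictor_names: list[str]
    coefficients: np.ndarray
    coef_ci: np.ndarray  # J x 2
    coef_p: np.ndarray
    significant: np.ndarray  # bool, at alpha_coef
    alpha_coef: float
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.component,
                "predictor": self.predictor_names,
                "coefficient": self.coefficients,
                "ci_low": self.coef_ci[:, 0],
                "ci_high": self.coef_ci[:, 1],
                "p_boot": self.coef_p,
                "significant": self.significant,
            }
        )


def _ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    sf = fitted.std()
    r = float(np.corrcoef(y, fitted)[0, 1]) if sf > 0 else 0.0
    return beta, r


def component_regression(
    clinical_scores: Scores,
    imaging_scores: Scores,
    component: int,
    clinical_view: str | None = None,
    imaging_views: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha_coef: float = 0.008,
    p_method: str = "normal",
    ci_method: str = "bc",
) -> ComponentRegressionResult:
    """Regress the clinical component score on the imaging component scores.

    ``component`` is 1-based. The model fit r is the correlation between the
    observed and fitted clinical score; participants are resampled with
    replacement ``n_boot`` times for bootstrap 95% CIs (bias-corrected
    percentile by default, ``ci_method='percentile'`` for the plain rule), and
    two-sided bootstrap p-values use the normal approximation
    estimate/bootstrap-SE by default (``p_method='percentile'`` switches to
    the percentile rule). Coefficient flags use ``alpha_coef`` (default .008,
    roughly .05 over 7 predictors).
    """
    if clinical_view is None:
        clinical_view = clinical_scores.view_names[0]
    if imaging_views is None:
        imaging_views = [v for v in imaging_scores.view_names if v != clinical_view]
    if clinical_scores.participant_ids != imaging_scores.participant_ids:
        raise ValueError("clinical and imaging scores are not participant-aligned")
    k = component - 1
    y = clinical_scores.view(clinical_view)[:, k]
    x = np.column_stack([imaging_scores.view(v)[:, k] for v in imaging_views])
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 participants for the score regression")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = []
        for j in range(x.shape[1]):
            others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
            resid = x[:, j] - others @ np.linalg.lstsq(others, x[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(x[:, j])):
                collinear.append(imaging_views[j])
        raise ValueError(f"rank-deficient predictors; collinear views: {collinear}")

    beta, r = _ols_fit(design, y)
    rng = np.random.default_rng(seed)
    boot_r = np.empty(n_boot)
    boot_beta = np.empty((n_boot, design.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bb, br = _ols_fit(design[idx], y[idx])
        boot_beta[b] = bb
        boot_r[b] = br
    r_ci = _bootstrap_ci(np.array([r]), boot_r[:, None], ci_method)[0]
    r_p = float(_bootstrap_p(np.array([r]), boot_r[:, None], p_method)[0])
    coefs = beta[1:]
    coef_boots = boot_beta[:, 1:]
    coef_ci = _bootstrap_ci(coefs, coef_boots, ci_method)
    coef_p = _bootstrap_p(coefs, coef_boots, p_method)
    return ComponentRegressionResult(
        component=component,
        r=r,
        r_ci=(float(r_ci[0]), float(r_ci[1])),
        r_p=r_p,
        predictor_names=list(imaging_views),
        coefficients=coefs,
        coef_ci=coef_ci,
        coef_p=coef_p,
        significant=coef_p < alpha_coef,
        alpha_coef=alpha_coef,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# structural coefficients and loadings


def _column_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of x with y; NaN for dead columns."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    nx = np.linalg.norm(xc, axis=0)
    ny = np.linalg.norm(yc)
    out = np.full(x.shape[1], np.nan)
    ok = (nx > 0) & (ny > 0)
    out[ok] = (xc[:, ok].T @ yc) / (nx[ok] * ny)
    return out


def structural_coefficients(
    scores: Scores,
    dataset: MultiViewDataset,
    n_boot: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
    components: list[int] | None = None,
    p_method: str = "normal",
) -> pd.DataFrame:
    """Correlate each view's component score back to its original variables.

    Returns one row per (component, view, variable) with the structural
    coefficient r, a bootstrap percentile 95% CI, a two-sided bootstrap p and
    its Benjamini-Hochberg adjustment within each (component, view) family.
    Zero-variance variables are flagged undefined and excluded from the FDR
    family.
    """
    if components is None:
        components = list(range(1, scores.n_components + 1))
    rng = np.random.default_rng(seed)
    n = len(scores.participant_ids)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for comp in components:
        k = comp - 1
        for view in dataset.views:
            if view.name not in scores.view_names:
                continue
            y = scores.view(view.name)[:, k]
            x = view.values
            r = _column_correlations(x, y)
            boots = np.empty((n_boot, view.p))
            for b in range(n_boot):
                idx = boot_idx[b]
                boots[b] = _column_correlations(x[idx], y[idx])
            defined = ~np.isnan(r)
            ci = np.full((view.p, 2), np.nan)
            if defined.any():
                ci[defined] = np.nanquantile(boots[:, defined], [0.025, 0.975], axis=0).T
            p = np.full(view.p, np.nan)
            p[defined] = _bootstrap_p(r[defined], boots[:, defined], p_method)
            p_fdr = np.full(view.p, np.nan)
            if defined.any():
                p_fdr[defined] = multipletests(p[defined], method="fdr_bh")[1]
            for i, name in enumerate(view.variable_names):
                rows.append(
                    {
                        "component": comp,
                        "view": view.name,
                        "variable": name,
                        "r": r[i],
                        "ci_low": ci[i, 0] if defined[i] else np.nan,
                        "ci_high": ci[i, 1] if defined[i] else np.nan,
                        "p": p[i],
                        "p_fdr": p_fdr[i],
                        "significant": bool(defined[i] and p_fdr[i] < fdr_alpha),
                        "defined": bool(defined[i]),
                    }
                )
    return pd.DataFrame(rows)


def top_items(
    table: pd.DataFrame, component: int, n: int = 25, view: str | None = None
) -> pd.DataFrame:
    """Top-n significant items of a component ranked by |r| (ties: name order)."""
    sub = table[(table["component"] == component) & table["significant"]]
    if view is not None:
        sub = sub[sub["view"] == view]
    sub = sub.assign(abs_r=sub["r"].abs()).sort_values(
        ["abs_r", "variable"], ascending=[False, True], kind="mergesort"
    )
    return sub.drop(columns="abs_r").head(n).reset_index(drop=True)


def aggregated_loadings(
    table: pd.DataFrame,
    section_map: dict[str, list[str]],
    view: str = "clinical",
    mode: str = "signed",
) -> pd.DataFrame:
    """Sectionwise mean of a view's structural coefficients per component.

    ``mode='signed'`` averages the coefficients as they are; ``mode='absolute'``
    averages their absolute values. Every variable of the view must belong to
    a section.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    sub = table[table["view"] == view]
    mapped = {v for members in section_map.values() for v in members}
    unmapped = sorted(set(sub["variable"]) - mapped)
    if unmapped:
        raise ValueError(f"variables not covered by section_map: {unmapped[:5]}")
    rows = []
    for comp in sorted(sub["component"].unique()):
        comp_tab = sub[sub["component"] == comp].set_index("variable")
        if "defined" in comp_tab.columns:
            comp_tab = comp_tab[comp_tab["defined"].astype(bool)]
        if comp_tab.empty:  # e.g. the view's scores deflated to zero
            continue
        for section, members in section_map.items():
            present = [m for m in members if m in comp_tab.index]
            if not present:
                continue
            r = comp_tab.loc[present, "r"].to_numpy(dtype=float)
            agg = float(np.abs(r).mean()) if mode == "absolute" else float(r.mean())
            rows.append(
                {
                    "component": comp,
                    "section": section,
                    "aggregated_loading": agg,
                    "n_items": len(present),
                }
            )
    return pd.DataFrame(rows)
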