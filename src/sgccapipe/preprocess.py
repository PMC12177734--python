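"""Confound residualization, standardization, splitting and skip-rule encoding.

The pipeline order is: encode skip-rule zeros (clinical view only, if raw data
carry missingness) -> split train/test -> residualize age/sex/site ->
standardize. Residualization and standardization statistics are always
estimated on the training participants and applied unchanged to held-out
participants, so test-set significance statements are free of leakage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data import CovariateTable, MultiViewDataset, ViewMatrix


def residualize_confounds(
    dataset: MultiViewDataset, fit_ids: Sequence[str] | None = None
) -> MultiViewDataset:
    """Remove linear age/sex/site effects from every column of every view.

    An OLS fit on [intercept, age, sex, site indicators] is estimated on
    ``fit_ids`` (default: all participants) and its fitted values are
    subtracted for *all* participants; the coefficient matrices and site level
    order are stored on the returned dataset so the identical correction can be
    replayed on new data.
    """
    ids = dataset.participant_ids
    if fit_ids is None:
        fit_ids = ids
    fit_ids = [str(i) for i in fit_ids]
    unknown = set(fit_ids) - set(ids)
    if unknown:
        raise ValueError(f"fit_ids not in dataset: {sorted(unknown)[:5]}")

    cov_all = dataset.covariates.subset(ids)
    cov_fit = dataset.covariates.subset(fit_ids)
    site_levels = sorted(set(cov_fit.site))
    outside = sorted(set(cov_all.site) - set(site_levels))
    if outside:
        raise ValueError(
            f"site level(s) {outside} present outside fit_ids but absent within it"
        )
    d_fit, _ = cov_fit.design_matrix(site_levels)
    d_all, _ = cov_all.design_matrix(site_levels)

    betas: dict[str, np.ndarray] = {}
    new_values = []
    fit_rows = [ids.index(i) for i in fit_ids]
    for view in dataset.views:
        beta, *_ = np.linalg.lstsq(d_fit, view.values[fit_rows], rcond=None)
        betas[view.name] = beta
        new_values.append(view.values - d_all @ beta)
    return dataset.with_values(
        new_values,
        residualization={"site_levels": site_levels, "betas": betas},
    )


def apply_residualization(dataset: MultiViewDataset, model: dict) -> MultiViewDataset:
    """Replay a stored residualization (train betas) on another dataset."""
    cov = dataset.covariates.subset(dataset.participant_ids)
    d, _ = cov.design_matrix(model["site_levels"])
    new_values = [v.values - d @ model["betas"][v.name] for v in dataset.views]
    return dataset.with_values(new_values, residualization=model)


def standardize(
    dataset: MultiViewDataset, fit_ids: Sequence[str] | None = None
) -> MultiViewDataset:
    """Center and scale every column by mean/SD computed on ``fit_ids``."""
    ids = dataset.participant_ids
    if fit_ids is None:
        fit_ids = ids
    fit_rows = [ids.index(str(i)) for i in fit_ids]
    stats: dict[str, dict[str, np.ndarray]] = {}
    new_values = []
    for view in dataset.views:
        sub = view.values[fit_rows]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [view.variable_names[j] for j in dead]
            raise ValueError(f"zero-SD columns in view {view.name!r}: {names}")
        stats[view.name] = {"mean": mean, "sd": sd}
        new_values.append((view.values - mean) / sd)
    return dataset.with_values(new_values, standardization=stats)


def apply_standardization(dataset: MultiViewDataset, stats: dict) -> MultiViewDataset:
    """Transform with previously stored (training) means and SDs."""
    new_values = [
        (v.values - stats[v.name]["mean"]) / stats[v.name]["sd"] for v in dataset.views
    ]
    return dataset.with_values(new_values, standardization=stats)


def split_train_test(
    dataset: MultiViewDataset, train_fraction: float, seed: int
) -> tuple[MultiViewDataset, MultiViewDataset]:
    """Random participant partition; train size = floor(train_fraction * n)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = dataset.n
    n_train = int(np.floor(train_fraction * n))
    if n_train < 2:
        raise ValueError(f"train set of {n_train} participants is too small")
    perm = np.random.default_rng(seed).permutation(n)
    ids = dataset.participant_ids
    train_ids = [ids[i] for i in sorted(perm[:n_train])]
    test_ids = [ids[i] for i in sorted(perm[n_train:])]
    return dataset.subset_participants(train_ids), dataset.subset_participants(test_ids)


def preprocess_train_test(
    dataset: MultiViewDataset, train_fraction: float, seed: int
) -> tuple[MultiViewDataset, MultiViewDataset]:
    """Split, then residualize and standardize with train-estimated statistics."""
    train, test = split_train_test(dataset, train_fraction, seed)
    train = standardize(residualize_confounds(train))
    test = apply_standardization(
        apply_residualization(test, train.residualization), train.standardization
    )
    return train, test


def encode_skip_zeros(
    view: ViewMatrix, section_map: dict, gate_items: dict | None = None
) -> ViewMatrix:
    """Replace missing entries governed by a zero gate item with 0.

    ``section_map`` maps section names to ordered member variables;
    ``gate_items`` maps section names to the gate variable (default: the first
    member). Any remaining missingness is an error — the pipeline requires
    complete data after skip-rule encoding.
    """
    col = {v: i for i, v in enumerate(view.variable_names)}
    for members in section_map.values():
        for name in members:
            if name not in col:
                raise ValueError(f"section_map variable {name!r} not in view {view.name!r}")
    if gate_items is None:
        gate_items = {sec: members[0] for sec, members in section_map.items()}
    for sec, gate in gate_items.items():
        if gate not in col:
            raise ValueError(f"gate item {gate!r} not in view {view.name!r}")

    x = view.values.copy()
    governed = np.zeros_like(x, dtype=bool)
    for sec, members in section_map.items():
        gate_col = col[gate_items[sec]]
        gated = x[:, gate_col] == 0
        for name in members:
            j = col[name]
            if j == gate_col:
                continue
            governed[:, j] = governed[:, j] | gated
    missing = np.isnan(x)
    fill = missing & governed
    x[fill] = 0.0
    left = np.argwhere(missing & ~fill)
    if left.size:
        r, c = left[0]
        raise ValueError(
            f"missing entry not governed by any zero gate: participant "
            f"{view.participant_ids[r]!r}, variable {view.variable_names[c]!r} "
            f"({len(left)} such entries)"
        )
    return ViewMatrix(view.name, view.participant_ids, view.variable_names, x)
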