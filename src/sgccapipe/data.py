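"""Multi-view data containers.

A *data view* is one participant-by-variable block (clinical items, cortical
thickness, task contrasts, ...). A :class:`MultiViewDataset` bundles the views of
one study sample together with a covariate table (age, sex, site) and any
preprocessing statistics estimated on a training subset, so that test
participants can be transformed with training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ID_COLUMN = "participant_id"


@dataclass
class ViewMatrix:
    """One named participant x variable block with aligned participant IDs."""

    name: str
    participant_ids: list[str]
    variable_names: list[str]
    values: np.ndarray  # n x p, float64; ordinal views stored as reals

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.participant_ids = [str(i) for i in self.participant_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        n, p = self.values.shape
        if n != len(self.participant_ids):
            raise ValueError(
                f"view {self.name!r}: {n} rows but {len(self.participant_ids)} participant IDs"
            )
        if p != len(self.variable_names):
            raise ValueError(
                f"view {self.name!r}: {p} columns but {len(self.variable_names)} variable names"
            )
        if len(set(self.participant_ids)) != n:
            raise ValueError(f"view {self.name!r}: duplicate participant IDs")
        if len(set(self.variable_names)) != p:
            raise ValueError(f"view {self.name!r}: duplicate variable names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, ID_COLUMN, self.participant_ids)
        return df

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "ViewMatrix":
        if df.columns[0] != ID_COLUMN:
            raise ValueError(f"first column must be {ID_COLUMN!r}, got {df.columns[0]!r}")
        return cls(
            name=name,
            participant_ids=[str(i) for i in df[ID_COLUMN]],
            variable_names=[str(c) for c in df.columns[1:]],
            values=df.iloc[:, 1:].to_numpy(dtype=float),
        )

    def subset_participants(self, ids: Sequence[str]) -> "ViewMatrix":
        index = {pid: i for i, pid in enumerate(self.participant_ids)}
        rows = [index[str(i)] for i in ids]
        return ViewMatrix(self.name, list(ids), list(self.variable_names), self.values[rows])

    def subset_variables(self, names: Sequence[str]) -> "ViewMatrix":
        index = {v: i for i, v in enumerate(self.variable_names)}
        cols = [index[str(v)] for v in names]
        return ViewMatrix(
            self.name, list(self.participant_ids), [str(v) for v in names], self.values[:, cols]
        )


@dataclass
class CovariateTable:
    """Age (years), sex (0/1) and site (categorical) per participant."""

    participant_ids: list[str]
    age: np.ndarray
    sex: np.ndarray
    site: np.ndarray

    def __post_init__(self) -> None:
        self.participant_ids = [str(i) for i in self.participant_ids]
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.site = np.asarray([str(s) for s in self.site], dtype=object)
        n = len(self.participant_ids)
        if not (len(self.age) == len(self.sex) == len(self.site) == n):
            raise ValueError("covariate columns must all have one row per participant")

    def subset(self, ids: Sequence[str]) -> "CovariateTable":
        index = {pid: i for i, pid in enumerate(self.participant_ids)}
        rows = [index[str(i)] for i in ids]
        return CovariateTable(
            list(ids), self.age[rows], self.sex[rows], self.site[rows]
        )

    def design_matrix(self, site_levels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Intercept + age + sex + full site indicator contrasts (first level dropped)."""
        if site_levels is None:
            site_levels = sorted(set(self.site))
        cols = [np.ones(len(self.participant_ids)), self.age, self.sex]
        names = ["intercept", "age", "sex"]
        for level in list(site_levels)[1:]:
            cols.append((self.site == level).astype(float))
            names.append(f"site[{level}]")
        return np.column_stack(cols), names

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {ID_COLUMN: self.participant_ids, "age": self.age, "sex": self.sex, "site": self.site}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateTable":
        return cls(
            participant_ids=[str(i) for i in df[ID_COLUMN]],
            age=df["age"].to_numpy(dtype=float),
            sex=df["sex"].to_numpy(dtype=float),
            site=df["site"].to_numpy(),
        )


@dataclass
class MultiViewDataset:
    """Ordered views with aligned participants plus covariates and fit statistics.

    ``standardization`` and ``residualization`` record statistics estimated on a
    training subset so held-out participants can be transformed identically.
    """

    views: list[ViewMatrix]
    covariates: CovariateTable
    standardization: dict | None = None
    residualization: dict | None = None

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("dataset needs at least one view")
        ids0 = self.views[0].participant_ids
        for v in self.views[1:]:
            if v.participant_ids != ids0:
                raise ValueError(
                    f"participant IDs of view {v.name!r} differ from view {self.views[0].name!r}"
                )
        cov_ids = set(self.covariates.participant_ids)
        missing = [i for i in ids0 if i not in cov_ids]
        if missing:
            raise ValueError(f"covariates missing for participants: {missing[:5]}")
        for v in self.views:
            if np.isnan(v.values).any():
                raise ValueError(f"view {v.name!r} contains missing values")

    @property
    def participant_ids(self) -> list[str]:
        return self.views[0].participant_ids

    @property
    def n(self) -> int:
        return self.views[0].n

    @property
    def view_names(self) -> list[str]:
        return [v.name for v in self.views]

    def view(self, name: str) -> ViewMatrix:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(f"no view named {name!r}; have {self.view_names}")

    def matrices(self) -> list[np.ndarray]:
        return [v.values for v in self.views]

    def subset_participants(self, ids: Sequence[str]) -> "MultiViewDataset":
        ids = [str(i) for i in ids]
        return MultiViewDataset(
            views=[v.subset_participants(ids) for v in self.views],
            covariates=self.covariates.subset(ids),
            standardization=self.standardization,
            residualization=self.residualization,
        )

    def select_views(self, names: Sequence[str]) -> "MultiViewDataset":
        """Restrict to the named views, in the given order."""
        return replace(self, views=[self.view(n) for n in names])

    def subset_variables(self, retained: dict[str, Sequence[str]]) -> "MultiViewDataset":
        """Subset each named view to the given variables (views absent from the map kept whole)."""
        views = [
            v.subset_variables(retained[v.name]) if v.name in retained else v
            for v in self.views
        ]
        return replace(self, views=views)

    def with_values(self, new_values: list[np.ndarray], **updates) -> "MultiViewDataset":
        views = [
            ViewMatrix(v.name, v.participant_ids, v.variable_names, vals)
            for v, vals in zip(self.views, new_values)
        ]
        return replace(self, views=views, **updates)


def write_view_tsv(view: ViewMatrix, path: str | Path) -> None:
    view.to_frame().to_csv(path, sep="\t", index=False)


def read_view_tsv(name: str, path: str | Path) -> ViewMatrix:
    # round_trip parsing keeps cached stages bit-identical to in-memory values
    return ViewMatrix.from_frame(name, pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_covariates_tsv(cov: CovariateTable, path: str | Path) -> None:
    cov.to_frame().to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path: str | Path) -> CovariateTable:
    return CovariateTable.from_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))
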