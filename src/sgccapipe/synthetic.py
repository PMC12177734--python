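"""Synthetic multi-view data with planted sparse shared components.

Emulates the design of a multimodal psychiatric-neuroimaging study: eight data
views for one sample of participants — one questionnaire-like clinical view
(ordinal items in named sections, with gate items whose zeros force the rest of
the section to zero, mimicking interview skip rules coded as zeros) and seven
continuous "imaging" views. All views share a small number of latent
components through sparse loading matrices, on top of view-specific Gaussian
noise and additive linear age/sex/site confound effects.

The generator returns the ground truth (latent scores, sparse loadings and
their supports, confound values) so every downstream stage — confound
residualization, sparsity tuning, stability selection, permutation
significance — can be validated against planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import CovariateTable, MultiViewDataset, ViewMatrix

CONTINUOUS = "continuous"
ORDINAL = "ordinal_zero_inflated"


@dataclass(frozen=True)
class ViewSpec:
    name: str
    n_variables: int
    family: str = CONTINUOUS

    def __post_init__(self):
        if self.family not in (CONTINUOUS, ORDINAL):
            raise ValueError(f"unknown view family {self.family!r}")
        if self.n_variables < 1:
            raise ValueError(f"view {self.name!r} needs at least one variable")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-component generative model.

    ``support_fraction`` is the fraction of each view's variables carrying a
    nonzero loading on each component; nonzero loadings are ``±loading_scale``.
    ``confound_effects`` maps view names to the amplitude of the additive
    age/sex/site effect (0 disables). ``skip_zero_prob`` is the probability
    that a non-gate clinical item is forced to 0 given its section's gate item
    is 0 (1.0 reproduces deterministic skip rules).
    """

    n_participants: int
    view_specs: tuple[ViewSpec, ...]
    n_true_components: int = 2
    support_fraction: float = 0.05
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    confound_effects: dict = field(default_factory=dict)
    n_sites: int = 3
    section_map: dict = field(default_factory=dict)
    skip_zero_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        if not 0 < self.support_fraction <= 1:
            raise ValueError("support_fraction must be in (0, 1]")
        if self.loading_scale <= 0 or self.noise_sd < 0:
            raise ValueError("loading_scale must be positive, noise_sd nonnegative")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.n_true_components < 0:
            raise ValueError("n_true_components must be nonnegative")
        if self.n_true_components > 0:
            for vs in self.view_specs:
                if self.support_fraction * vs.n_variables < 1:
                    raise ValueError(
                        f"support_fraction*{vs.n_variables} < 1 for view {vs.name!r}: "
                        "no variable would carry signal"
                    )

    def support_size(self, view: ViewSpec) -> int:
        return max(1, int(round(self.support_fraction * view.n_variables)))


@dataclass
class GroundTruth:
    """Planted structure: latent scores, sparse loadings, supports, confounds."""

    latent_scores: np.ndarray  # n x K
    true_loadings: dict[str, np.ndarray]  # view -> p x K
    true_support: dict[str, list[list[int]]]  # view -> per-component index lists
    confound_values: CovariateTable

    def to_json(self, path: str | Path) -> None:
        obj = {
            "latent_scores": self.latent_scores.tolist(),
            "true_loadings": {k: v.tolist() for k, v in self.true_loadings.items()},
            "true_support": self.true_support,
            "confounds": {
                "participant_id": self.confound_values.participant_ids,
                "age": self.confound_values.age.tolist(),
                "sex": self.confound_values.sex.tolist(),
                "site": list(self.confound_values.site),
            },
        }
        Path(path).write_text(json.dumps(obj))


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of ``spec`` with no shared components: views are noise + confounds."""
    return replace(spec, n_true_components=0)


def default_study_spec(
    n_participants: int = 794,
    n_true_components: int = 2,
    support_fraction: float = 0.05,
    loading_scale: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Eight-view layout mirroring the emulated study design.

    One ordinal clinical view of 60 items in 12 five-item sections (the first
    item of each section is the gate) plus seven continuous imaging views.
    Confound amplitudes default to 0.5 on every view. The default planted
    loading of 0.4 against unit noise puts item-component correlations near
    0.37 and cross-view canonical correlations in the 0.2-0.5 band, the
    effect-size range typical of brain-behavior covariation studies; much
    stronger loadings would make every selection problem trivial.
    """
    imaging = [
        ViewSpec("faces_task", 24),
        ViewSpec("reward_task", 24),
        ViewSpec("stop_task", 24),
        ViewSpec("cortical_thickness", 34),
        ViewSpec("surface_area", 34),
        ViewSpec("rest_connectivity", 28),
        ViewSpec("wm_anisotropy", 24),
    ]
    n_items, per_section = 60, 5
    clinical = ViewSpec("clinical", n_items, ORDINAL)
    section_map = {
        f"section_{s:02d}": [f"clinical_v{s * per_section + i}" for i in range(per_section)]
        for s in range(n_items // per_section)
    }
    views = (clinical, *imaging)
    return SyntheticSpec(
        n_participants=n_participants,
        view_specs=views,
        n_true_components=n_true_components,
        support_fraction=support_fraction,
        loading_scale=loading_scale,
        noise_sd=noise_sd,
        confound_effects={v.name: 0.5 for v in views},
        n_sites=3,
        section_map=section_map,
        skip_zero_prob=1.0,
        seed=seed,
    )


def _latent_scores(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Exactly zero-mean, mutually orthogonal, unit-variance latent columns."""
    if k == 0:
        return np.zeros((n, 0))
    g = rng.standard_normal((n, k))
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), g]))
    return q[:, 1 : k + 1] * np.sqrt(n - 1)


def _sparse_loadings(
    rng: np.random.Generator, p: int, k: int, m: int, scale: float
) -> tuple[np.ndarray, list[list[int]]]:
    a = np.zeros((p, k))
    support: list[list[int]] = []
    for comp in range(k):
        idx = np.sort(rng.choice(p, size=m, replace=False))
        signs = rng.choice([-1.0, 1.0], size=m)
        a[idx, comp] = signs * scale
        support.append(idx.tolist())
    return a, support


def _confound_effect(
    rng: np.random.Generator, cov: CovariateTable, p: int, amplitude: float, n_sites: int
) -> np.ndarray:
    """Additive linear effect: per-column random age/sex slopes + site offsets."""
    n = len(cov.participant_ids)
    if amplitude == 0:
        return np.zeros((n, p))
    age_c = (cov.age - cov.age.mean()) / cov.age.std()
    sex_c = cov.sex - cov.sex.mean()
    b_age = rng.standard_normal(p)
    b_sex = rng.standard_normal(p)
    site_levels = sorted(set(cov.site))
    offsets = rng.standard_normal((len(site_levels), p))
    site_idx = np.array([site_levels.index(s) for s in cov.site])
    return amplitude * (np.outer(age_c, b_age) + np.outer(sex_c, b_sex) + offsets[site_idx])


def _discretize_tertiles(x: np.ndarray) -> np.ndarray:
    """Map each column to {0,1,2} by its tertile cuts."""
    out = np.zeros_like(x)
    for j in range(x.shape[1]):
        lo, hi = np.quantile(x[:, j], [1 / 3, 2 / 3])
        out[:, j] = np.digitize(x[:, j], [lo, hi])
    return out


def _apply_skip_rules(
    rng: np.random.Generator, x: np.ndarray, variable_names: list[str], section_map: dict, prob: float
) -> np.ndarray:
    """Zero the non-gate items of a section where the gate (first item) is 0."""
    col = {v: i for i, v in enumerate(variable_names)}
    x = x.copy()
    for members in section_map.values():
        gate = col[members[0]]
        gated = x[:, gate] == 0
        for name in members[1:]:
            j = col[name]
            if prob >= 1.0:
                forced = gated
            else:
                forced = gated & (rng.random(x.shape[0]) < prob)
            x[forced, j] = 0.0
    return x


def generate_multiview(spec: SyntheticSpec) -> tuple[MultiViewDataset, GroundTruth]:
    """Draw one dataset from the planted-component model.

    Each view is ``Z @ A.T + confounds + noise``; ordinal views are then
    discretized to {0,1,2} by per-column tertiles and skip-rule zeroed per
    section. Bit-identical output under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_participants, spec.n_true_components
    ids = [f"sub-{i:05d}" for i in range(n)]

    age = rng.uniform(18.0, 28.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    site = np.array([f"site{s + 1}" for s in rng.integers(0, spec.n_sites, size=n)], dtype=object)
    covariates = CovariateTable(ids, age, sex, site)

    z = _latent_scores(rng, n, k)
    views: list[ViewMatrix] = []
    loadings: dict[str, np.ndarray] = {}
    support: dict[str, list[list[int]]] = {}

    for vs in spec.view_specs:
        p = vs.n_variables
        a, sup = _sparse_loadings(rng, p, k, spec.support_size(vs), spec.loading_scale)
        x = z @ a.T if k else np.zeros((n, p))
        x = x + _confound_effect(
            rng, covariates, p, float(spec.confound_effects.get(vs.name, 0.0)), spec.n_sites
        )
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal((n, p))
        names = [f"{vs.name}_v{i}" for i in range(p)]
        if vs.family == ORDINAL:
            if spec.section_map:
                mapped = [v for members in spec.section_map.values() for v in members]
                if sorted(mapped) != sorted(names):
                    raise ValueError(
                        f"section_map does not cover view {vs.name!r} exactly: "
                        f"{len(mapped)} mapped vs {p} variables"
                    )
            x = _discretize_tertiles(x)
            if spec.section_map:
                x = _apply_skip_rules(rng, x, names, spec.section_map, spec.skip_zero_prob)
        views.append(ViewMatrix(vs.name, ids, names, x))
        loadings[vs.name] = a
        support[vs.name] = sup

    dataset = MultiViewDataset(views=views, covariates=covariates)
    truth = GroundTruth(z, loadings, support, covariates)
    return dataset, truth
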