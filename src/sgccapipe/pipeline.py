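"""Staged pipeline orchestration with on-disk caching.

Stage order: simulate -> preprocess -> tune -> components -> stability ->
refit -> significance -> regression -> loadings -> report. Each stage writes
its outputs under the config's output directory; a later stage reloads
whatever earlier artifacts it needs, so individual stages can be rerun from
cache. Identical config => byte-identical outputs (the run record's
timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference as inf
from . import model_selection as ms
from .config import PipelineConfig
from .data import (
    MultiViewDataset,
    read_covariates_tsv,
    read_view_tsv,
    write_covariates_tsv,
    write_view_tsv,
)
from .preprocess import preprocess_train_test
from .sgcca import SGCCAModel, compute_ave, transform, uniform_design
from .synthetic import SyntheticSpec, default_study_spec, generate_multiview

STAGES = (
    "simulate",
    "preprocess",
    "tune",
    "components",
    "stability",
    "refit",
    "significance",
    "regression",
    "loadings",
    "report",
)


@dataclass
class RunRecord:
    config: dict
    version: str
    stage_seconds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _log(cfg: PipelineConfig, stage: str, msg: str) -> None:
    if cfg.verbosity > 0:
        print(f"[{stage}] {msg}", file=sys.stderr)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name!r}: run the {producer!r} stage first"
        )
    return path


class Pipeline:
    """Executes the configured stages, caching every artifact in output_dir."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._section_map: dict | None = None

    # -- data loading -------------------------------------------------------

    def _spec(self) -> SyntheticSpec:
        sim = dict(self.cfg.simulate or {})
        amp = sim.pop("confound_amplitude", None)
        spec = default_study_spec(**sim)
        if amp is not None:
            spec = type(spec)(**{**spec.__dict__, "confound_effects": {
                v.name: float(amp) for v in spec.view_specs}})
        return spec

    def _view_names(self) -> list[str]:
        if self.cfg.dataset is not None:
            return list(self.cfg.dataset["views"])
        return [v.name for v in self._spec().view_specs]

    def _load_raw(self) -> MultiViewDataset:
        if self.cfg.dataset is not None:
            manifest = self.cfg.dataset
            views = [read_view_tsv(name, path) for name, path in manifest["views"].items()]
            cov = read_covariates_tsv(manifest["covariates"])
            self._section_map = json.loads(Path(manifest["section_map"]).read_text()) \
                if manifest.get("section_map") else {}
            return MultiViewDataset(views=views, covariates=cov)
        views = [
            read_view_tsv(name, _require(self.out / f"raw_{name}.tsv", "simulate"))
            for name in self._view_names()
        ]
        cov = read_covariates_tsv(_require(self.out / "covariates.tsv", "simulate"))
        self._section_map = json.loads(
            _require(self.out / "section_map.json", "simulate").read_text()
        )
        return MultiViewDataset(views=views, covariates=cov)

    def section_map(self) -> dict:
        if self._section_map is None:
            if self.cfg.dataset is not None:
                p = self.cfg.dataset.get("section_map")
                self._section_map = json.loads(Path(p).read_text()) if p else {}
            else:
                self._section_map = json.loads(
                    _require(self.out / "section_map.json", "simulate").read_text()
                )
        return self._section_map

    def _load_split(self, which: str) -> MultiViewDataset:
        views = [
            read_view_tsv(name, _require(self.out / f"{which}_{name}.tsv", "preprocess"))
            for name in self._view_names()
        ]
        cov = read_covariates_tsv(_require(self.out / "covariates.tsv", "preprocess")
                                  if self.cfg.dataset is None
                                  else Path(self.cfg.dataset["covariates"]))
        ids = views[0].participant_ids
        return MultiViewDataset(views=views, covariates=cov.subset(ids))

    def _design(self, n_views: int) -> np.ndarray:
        if self.cfg.design == "uniform":
            return uniform_design(n_views)
        return np.asarray(self.cfg.design, dtype=float)

    def _retained(self) -> dict:
        return json.loads(_require(self.out / "retained.json", "stability").read_text())

    def _model(self) -> SGCCAModel:
        return SGCCAModel.from_json(_require(self.out / "model.json", "refit"))

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        if self.cfg.simulate is None:
            _log(self.cfg, "simulate", "external dataset configured; nothing to do")
            return
        spec = self._spec()
        dataset, truth = generate_multiview(spec)
        for v in dataset.views:
            write_view_tsv(v, self.out / f"raw_{v.name}.tsv")
        write_covariates_tsv(dataset.covariates, self.out / "covariates.tsv")
        truth.to_json(self.out / "ground_truth.json")
        (self.out / "section_map.json").write_text(json.dumps(spec.section_map))
        self._section_map = dict(spec.section_map)
        _log(self.cfg, "simulate", f"{dataset.n} participants, {len(dataset.views)} views")

    def preprocess(self) -> None:
        raw = self._load_raw()
        train, test = preprocess_train_test(
            raw, float(self.cfg.split["fraction"]), int(self.cfg.split["seed"])
        )
        for which, ds in (("train", train), ("test", test)):
            for v in ds.views:
                write_view_tsv(v, self.out / f"{which}_{v.name}.tsv")
        _log(self.cfg, "preprocess", f"train n={train.n}, test n={test.n}")

    def tune(self) -> None:
        train = self._load_split("train")
        t = self.cfg.tuning
        result = ms.tune_sparsity(
            train,
            design=self._design(len(train.views)),
            lambda_grid=np.asarray(t["grid"], dtype=float),
            n_components_for_tuning=int(t["n_components"]),
            n_perm=int(t["n_perm"]),
            seed=int(t["seed"]),
            scheme=self.cfg.scheme,
        )
        result.to_frame().to_csv(self.out / "tuning.tsv", sep="\t", index=False)
        (self.out / "tuning.json").write_text(json.dumps(
            {"chosen_lambda": result.chosen_lambda,
             "z_at_chosen": float(result.z_per_lambda.max())}))
        _log(self.cfg, "tune", f"chosen lambda = {result.chosen_lambda}")

    def components(self) -> None:
        train = self._load_split("train")
        lam = json.loads(_require(self.out / "tuning.json", "tune").read_text())["chosen_lambda"]
        c = self.cfg.components
        curve = ms.select_n_components(
            train,
            design=self._design(len(train.views)),
            sparsity=ms.clipped_lambdas(lam, [v.p for v in train.views]),
            k_max=int(c["k_max"]),
            epsilon=float(c["epsilon"]),
            scheme=self.cfg.scheme,
            override_k=c.get("override"),
        )
        pd.DataFrame({
            "k": np.arange(1, curve.cumulative_outer_ave.size + 1),
            "cumulative_outer_ave": curve.cumulative_outer_ave,
        }).to_csv(self.out / "component_curve.tsv", sep="\t", index=False)
        (self.out / "components.json").write_text(json.dumps(
            {"chosen_k": curve.chosen_k,
             "cumulative_outer_ave_at_k": float(
                 curve.cumulative_outer_ave[curve.chosen_k - 1])}))
        _log(self.cfg, "components", f"chosen K = {curve.chosen_k}")

    def stability(self) -> None:
        train = self._load_split("train")
        lam = json.loads(_require(self.out / "tuning.json", "tune").read_text())["chosen_lambda"]
        k = json.loads(_require(self.out / "components.json", "components").read_text())["chosen_k"]
        s = self.cfg.stability
        result = ms.stability_selection(
            train,
            design=self._design(len(train.views)),
            sparsity=ms.clipped_lambdas(lam, [v.p for v in train.views]),
            n_components=k,
            n_subsamples=int(s["n_subsamples"]),
            subsample_fraction=float(s["fraction"]),
            retention_threshold=float(s["threshold"]),
            seed=int(s["seed"]),
            scheme=self.cfg.scheme,
            skip_views=tuple(s.get("skip_views") or ()),
        )
        result.to_frame().to_csv(self.out / "stability.tsv", sep="\t", index=False)
        (self.out / "retained.json").write_text(json.dumps(result.retained))
        _log(self.cfg, "stability", f"retained {sum(len(v) for v in result.retained.values())} variables")

    def refit(self) -> None:
        train = self._load_split("train")
        retained = self._retained()
        k = json.loads(_require(self.out / "components.json", "components").read_text())["chosen_k"]
        # a view none of whose variables survives stability screening carries
        # no stable signal: it is excluded from the final unified model
        kept = {v: names for v, names in retained.items() if names}
        dropped = [v for v in train.view_names if not retained.get(v)]
        if dropped:
            _log(self.cfg, "refit", f"view(s) without stable variables dropped: {dropped}")
        clinical = train.view_names[0]
        if clinical in dropped:
            raise ValueError(
                f"no stable variables in the clinical view {clinical!r}; "
                "the final model would have no psychopathology score"
            )
        if len(kept) < 2:
            raise ValueError("fewer than two views retain stable variables")
        train = train.select_views([v for v in train.view_names if v in kept])
        model, ave = ms.refit_final(
            train, kept, n_components=k,
            design=self._design(len(train.views)), scheme=self.cfg.scheme,
        )
        model.to_json(self.out / "model.json")
        pd.DataFrame({
            "component": np.arange(1, k + 1),
            "inner_ave": ave.inner_ave,
            "cumulative_outer_ave": ave.cumulative_outer_ave,
        }).to_csv(self.out / "final_ave.tsv", sep="\t", index=False)
        _log(self.cfg, "refit",
             f"final model cumulative outer AVE = {ave.cumulative_outer_ave[-1]:.3f}")

    def _model_dataset(self, model: SGCCAModel, which: str) -> MultiViewDataset:
        """The split restricted to the final model's views and variables."""
        retained = {v: names for v, names in self._retained().items() if names}
        return self._load_split(which).select_views(model.view_names).subset_variables(retained)

    def significance(self) -> None:
        model = self._model()
        train = self._model_dataset(model, "train")
        test = self._model_dataset(model, "test")
        i = self.cfg.inference
        res = inf.permutation_significance(
            model, train, test, n_perm=int(i["n_perm"]), seed=int(i["seed"])
        )
        tab = pd.concat([res["train"].to_frame(), res["test"].to_frame()], ignore_index=True)
        tab.to_csv(self.out / "significance.tsv", sep="\t", index=False)
        n_sig = int((res["test"].p_perm < 0.05).sum())
        _log(self.cfg, "significance", f"{n_sig} test-significant component(s) at alpha=0.05")

    def regression(self) -> None:
        model = self._model()
        i = self.cfg.inference
        clinical = model.view_names[0]
        frames = []
        fits = []
        for which in ("train", "test"):
            ds = self._model_dataset(model, which)
            scores = transform(model, ds)
            for comp in range(1, model.n_components + 1):
                # a view with fewer retained variables than components deflates
                # to zero; its later-component scores carry no information
                predictors = [
                    v for v in model.view_names
                    if v != clinical and scores.view(v)[:, comp - 1].any()
                ]
                if not predictors or not scores.view(clinical)[:, comp - 1].any():
                    _log(self.cfg, "regression",
                         f"component {comp} ({which}): no informative scores, skipped")
                    continue
                r = inf.component_regression(
                    scores, scores, comp, clinical_view=clinical,
                    imaging_views=predictors,
                    n_boot=int(i["n_boot"]), seed=int(i["seed"]),
                    alpha_coef=float(i["alpha_coef"]),
                )
                fits.append({"context": which, "component": comp, "r": r.r,
                             "ci_low": r.r_ci[0], "ci_high": r.r_ci[1], "p_boot": r.r_p})
                frames.append(r.to_frame().assign(context=which))
        pd.DataFrame(fits).to_csv(self.out / "regression_fit.tsv", sep="\t", index=False)
        pd.concat(frames, ignore_index=True).to_csv(
            self.out / "regression_coefficients.tsv", sep="\t", index=False)
        _log(self.cfg, "regression", f"{len(fits)} score regressions")

    def loadings(self) -> None:
        model = self._model()
        retained = self._retained()
        i = self.cfg.inference
        train = self._model_dataset(model, "train")
        scores = transform(model, train)
        table = inf.structural_coefficients(
            scores, train, n_boot=int(i["n_boot"]), seed=int(i["seed"]),
            fdr_alpha=float(i["fdr_alpha"]),
        )
        table.to_csv(self.out / "structural_coefficients.tsv", sep="\t", index=False)
        clinical = model.view_names[0]
        tops = pd.concat(
            [inf.top_items(table, comp, view=clinical)
             for comp in range(1, model.n_components + 1)],
            ignore_index=True,
        )
        tops.to_csv(self.out / "top_items.tsv", sep="\t", index=False)
        section_map = self.section_map()
        if section_map:
            retained_clin = set(retained.get(clinical, []))
            smap = {
                sec: [m for m in members if not retained_clin or m in retained_clin]
                for sec, members in section_map.items()
            }
            smap = {sec: mem for sec, mem in smap.items() if mem}
            agg = inf.aggregated_loadings(table, smap, view=clinical)
            agg.to_csv(self.out / "aggregated_loadings.tsv", sep="\t", index=False)
        _log(self.cfg, "loadings", f"{len(table)} structural coefficients")

    def report(self) -> None:
        sig = pd.read_csv(_require(self.out / "significance.tsv", "significance"), sep="\t")
        fit = pd.read_csv(_require(self.out / "regression_fit.tsv", "regression"), sep="\t")
        tuning = json.loads(_require(self.out / "tuning.json", "tune").read_text())
        comps = json.loads(_require(self.out / "components.json", "components").read_text())
        ave = pd.read_csv(_require(self.out / "final_ave.tsv", "refit"), sep="\t")
        test = sig[sig["context"] == "test"]
        report = {
            "chosen_lambda": tuning["chosen_lambda"],
            "tuning_z": tuning["z_at_chosen"],
            "chosen_k": comps["chosen_k"],
            "cumulative_outer_ave_at_chosen_k": comps["cumulative_outer_ave_at_k"],
            "final_model_cumulative_outer_ave": float(ave["cumulative_outer_ave"].iloc[-1]),
            "n_test_significant_components": int((test["p_perm"] < 0.05).sum()),
            "per_component": [
                {
                    "component": int(row["component"]),
                    "test_inner_ave": float(row["observed_inner_ave"]),
                    "test_z": float(row["z"]),
                    "test_p_perm": float(row["p_perm"]),
                }
                for _, row in test.iterrows()
            ],
            "regression": fit.to_dict(orient="records"),
        }
        (self.out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        _log(self.cfg, "report", "report.json written")


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> RunRecord:
    """Run the requested stages in canonical order; returns the run record."""
    stages = STAGES if stages is None else tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
    pipe = Pipeline(config)
    record = RunRecord(
        config=dict(config.__dict__),
        version=_version(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    record.write(pipe.out / "run_record.json")
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        getattr(pipe, stage)()
        record.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    if config.dataset is not None:
        for name, path in config.dataset.get("views", {}).items():
            record.input_checksums[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    record.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    record.write(pipe.out / "run_record.json")
    return record


def _version() -> str:
    from . import __version__

    return __version__
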