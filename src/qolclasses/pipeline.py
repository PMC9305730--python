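"""End-to-end pipeline: simulate -> score -> describe -> select -> fit -> validate.

One YAML configuration drives the whole analysis; every stage reads only
prior-stage outputs, all randomness flows through stage-local generators
spawned from a single master seed, and a run manifest (config hash, stage
timings, seeds, file inventory) is written even when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import CovariateTable, read_covariates_csv
from .errors import ConfigError, QolClassesError
from .imputation import impute_covariates
from .lca import classify_modal, fit_em, rank_classes_by_utility
from .descriptives import mds_layout, polychoric_matrix
from .regression import rrr_report
from .responses import complete_case_filter, read_items_csv
from .scoring import UtilitySpec, score_cohort, standardise_dimension
from .selection import cross_validate, make_folds, select_k
from .synthetic import generate_cohort, load_profile, write_cohort

STAGES = ("simulate", "score", "describe", "select", "fit", "validate")


@dataclass
class PipelineConfig:
    """Validated run configuration (exactly one input source)."""

    out_dir: Path
    profile: str | None = None
    items_csv: Path | None = None
    covariates_csv: Path | None = None
    utility_spec: Path | None = None
    seed: int = 0
    k_range: tuple = (1, 6)
    k_final: int | None = None
    cv_schemes: tuple = ("kfold", "loso", "splithalf")
    n_folds: int = 10
    n_restarts: int = 20
    n_imputations: int = 20
    stages: tuple = STAGES

    def validate(self) -> None:
        has_files = self.items_csv is not None
        has_profile = self.profile is not None
        if has_files == has_profile:
            raise ConfigError(
                "input", "supply exactly one of items_csv or profile"
            )
        if has_files and "simulate" in self.stages:
            raise ConfigError("stages", "simulate stage requires a profile")
        lo, hi = self.k_range
        if not (1 <= lo <= hi):
            raise ConfigError("k_range", "must satisfy 1 <= min <= max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "qolclasses_run")),
            profile=raw.get("profile"),
            items_csv=Path(raw["items_csv"]) if raw.get("items_csv") else None,
            covariates_csv=Path(raw["covariates_csv"]) if raw.get("covariates_csv") else None,
            utility_spec=Path(raw["utility_spec"]) if raw.get("utility_spec") else None,
            seed=int(raw.get("seed", 0)),
            k_range=tuple(raw.get("k_range", (1, 6))),
            k_final=raw.get("k_final"),
            cv_schemes=tuple(raw.get("cv_schemes", ("kfold", "loso", "splithalf"))),
            n_folds=int(raw.get("n_folds", 10)),
            n_restarts=int(raw.get("n_restarts", 20)),
            n_imputations=int(raw.get("n_imputations", 20)),
            stages=tuple(raw.get("stages", STAGES)),
        )
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    output_hash: str | None = None
    failed_stage: str | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "seed": self.seed,
            "stage_seconds": self.stage_seconds,
            "stage_seeds": self.stage_seeds,
            "outputs": sorted(self.outputs),
            "output_hash": self.output_hash,
            "failed_stage": self.failed_stage,
            "error": self.error,
        }


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order; see module docstring."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        version=__version__,
        seed=config.seed,
    )

    def record(path: Path):
        manifest.outputs.append(str(path.relative_to(out)))

    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            seed = _stage_seed(config.seed, stage)
            manifest.stage_seeds[stage] = seed
            _run_stage(stage, config, state, out, seed, record)
            manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    except QolClassesError as e:
        manifest.failed_stage = stage
        manifest.error = str(e)
    finally:
        digest = hashlib.sha256()
        for rel in sorted(manifest.outputs):
            digest.update(rel.encode())
            digest.update((out / rel).read_bytes())
        manifest.output_hash = digest.hexdigest()[:16]
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=1)
    if manifest.failed_stage:
        raise QolClassesError(
            f"pipeline failed at stage {manifest.failed_stage!r}: {manifest.error}"
        )
    return manifest


def _load_inputs(config: PipelineConfig, state: dict, seed: int | None = None):
    if "items" in state:
        return
    if config.profile is not None:
        profile = load_profile(config.profile)
        cohort = generate_cohort(profile, seed=seed if seed is not None else profile.seed)
        state["items"] = cohort.items
        state["covariates"] = cohort.covariates
        state["utility_spec"] = profile.utility
        state["cohort"] = cohort
    else:
        from .metadata import aqol_metadata

        state["items"] = read_items_csv(config.items_csv, aqol_metadata())
        if config.covariates_csv:
            state["covariates"] = read_covariates_csv(config.covariates_csv)
        state["utility_spec"] = (
            UtilitySpec.from_yaml(config.utility_spec) if config.utility_spec else None
        )


def _run_stage(stage, config, state, out, seed, record):
    if stage == "simulate":
        _load_inputs(config, state, seed=seed)
        for path in write_cohort(state["cohort"], out).values():
            record(path)
        return

    _load_inputs(config, state)
    if "complete" not in state:
        state["complete"], state["cc_report"] = complete_case_filter(state["items"])

    items = state["complete"]
    if stage == "score":
        spec = state.get("utility_spec")
        if spec is None:
            raise ConfigError("utility_spec", "scoring requires a utility spec")
        scores = score_cohort(items, spec)
        state["scores"] = scores
        df = scores.standardised.copy()
        df["utility"] = scores.utility
        path = out / "scores.csv"
        df.to_csv(path)
        record(path)
    elif stage == "describe":
        pm = polychoric_matrix(items)
        layout = mds_layout(pm)
        state["polychoric"] = pm
        for name, frame in (
            ("polychoric.csv", pm.to_frame()),
            ("mds_layout.csv", layout.to_frame()),
            ("mds_edges.csv", layout.edges),
        ):
            path = out / name
            frame.to_csv(path)
            record(path)
    elif stage == "select":
        lo, hi = config.k_range
        frames = []
        sites = None
        if "covariates" in state and "site" in state["covariates"].data.columns:
            keep = state["items"].complete_rows()
            sites = state["covariates"].data["site"].to_numpy()[keep]
        for scheme in config.cv_schemes:
            if scheme == "loso" and sites is None:
                continue
            folds = make_folds(
                items.n_persons, scheme, sites=sites,
                n_folds=config.n_folds, seed=seed,
            )
            frames.append(
                cross_validate(
                    items, range(lo, hi + 1), folds=folds,
                    n_restarts=config.n_restarts, seed=seed,
                )
            )
        cv = pd.concat(frames, ignore_index=True)
        path = out / "cv_table.csv"
        cv.to_csv(path, index=False)
        record(path)
        selections = {
            scheme: select_k(cv[cv["scheme"] == scheme]).selected_k
            for scheme in cv["scheme"].unique()
        }
        state["selected_k"] = selections
        path = out / "selection.json"
        with open(path, "w") as fh:
            json.dump({"selected_k": selections}, fh, indent=1)
        record(path)
    elif stage == "fit":
        K = config.k_final
        if K is None:
            picks = state.get("selected_k")
            K = int(pd.Series(picks).mode()[0]) if picks else 4
        fit = fit_em(items, K, n_restarts=config.n_restarts, seed=seed)
        utility = state["scores"].utility.to_numpy() if "scores" in state else None
        if utility is not None:
            pain = standardise_dimension(items, "pain")
            fit = rank_classes_by_utility(fit, utility, pain_scores=pain)
        state["fit"] = fit
        path = out / "fit.json"
        fit.to_json(path)
        record(path)
        labels = classify_modal(fit.posteriors)
        state["labels"] = labels
        path = out / "classes.csv"
        pd.DataFrame(
            {"person_id": items.ids, "class": labels},
        ).to_csv(path, index=False)
        record(path)
        path = out / "posteriors.csv"
        pd.DataFrame(
            fit.posteriors,
            index=pd.Index(items.ids, name="person_id"),
            columns=fit.class_names or [f"class_{k+1}" for k in range(K)],
        ).to_csv(path)
        record(path)
    elif stage == "validate":
        if "covariates" not in state:
            raise ConfigError("covariates", "validate stage requires covariates")
        if "fit" not in state:
            raise ConfigError("stages", "validate requires the fit stage")
        cov: CovariateTable = state["covariates"]
        keep = state["items"].complete_rows()
        cov_cc = cov.copy()
        cov_cc.data = cov_cc.data.loc[keep].reset_index(drop=True)
        labels = state["labels"]
        fit = state["fit"]
        from .covariates import profile_classes

        utility = state["scores"].utility.to_numpy() if "scores" in state else None
        profile = profile_classes(
            labels, cov_cc, utility=utility, class_names=fit.class_names
        )
        for name, frame in (
            ("profile_continuous.csv", profile.continuous),
            ("profile_categorical.csv", profile.categorical),
        ):
            path = out / name
            frame.to_csv(path)
            record(path)
        imps = impute_covariates(
            cov_cc, m=config.n_imputations, seed=seed,
            extra_predictors=pd.get_dummies(pd.Series(labels).astype(str)),
        )
        names = dict(enumerate(fit.class_names or [], start=1))
        report = rrr_report(labels, imps, reference_class=1, class_names=names)
        for tag, frame in report.tables.items():
            path = out / f"rrr_{tag}.csv"
            frame.to_csv(path, index=False)
            record(path)
        path = out / "rrr_accuracy.json"
        with open(path, "w") as fh:
            json.dump(report.accuracy, fh, indent=1)
        record(path)
    else:
        raise ConfigError("stages", f"unknown stage {stage!r}")
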