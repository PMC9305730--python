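"""Synthetic-cohort generator with known latent-class ground truth.

Cohorts emulate a multi-site sample of help-seeking young people completing
the AQoL-6D at service entry: a latent class is drawn per person, item
responses are conditionally independent given class (the LCA assumption),
covariates follow class-conditional models, and a configured number of rows
receive item-level missingness.  The packaged ``aqol_paper_profile``
describes four classes of graded QoL impairment across 1107 persons and
five recruitment sites (three metropolitan, two regional).

Everything is driven by one seeded random stream, so identical
configurations reproduce byte-identical cohorts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import CovariateTable
from .errors import ConfigError
from .metadata import ItemMetadata
from .responses import ItemResponseMatrix
from .scoring import UtilitySpec

_PROB_TOL = 1e-12


@dataclass
class CovariateModel:
    """Class-conditional model for one covariate.

    Families: ``continuous-normal`` (per-class mean/sd, optional clip range
    and integer rounding), ``binary`` (per-class probability of 1) and
    ``categorical`` (per-class probability vector over ``levels``).
    ``missing_rate`` is a missing-completely-at-random rate applied after
    generation.
    """

    name: str
    family: str
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    clip: tuple | None = None
    integer: bool = False
    probs: np.ndarray | None = None  # binary: (K,); categorical: (K, L)
    levels: tuple = ()
    missing_rate: float = 0.0

    def validate(self, n_classes: int) -> None:
        f = f"covariates.{self.name}"
        if self.family == "continuous-normal":
            if self.means is None or self.sds is None:
                raise ConfigError(f, "continuous-normal needs means and sds")
            if len(self.means) != n_classes or len(self.sds) != n_classes:
                raise ConfigError(f, "means/sds length must equal n_classes")
            if np.any(np.asarray(self.sds) <= 0):
                raise ConfigError(f, "sds must be positive")
        elif self.family == "binary":
            if self.probs is None or len(self.probs) != n_classes:
                raise ConfigError(f, "binary needs a probability per class")
            if np.any((self.probs < 0) | (self.probs > 1)):
                raise ConfigError(f, "probabilities outside [0, 1]")
        elif self.family == "categorical":
            if self.probs is None or self.probs.shape != (n_classes, len(self.levels)):
                raise ConfigError(f, "categorical needs (n_classes, n_levels) probs")
            if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > _PROB_TOL):
                raise ConfigError(f, "category probabilities must sum to 1")
        else:
            raise ConfigError(f, f"unknown family {self.family!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f, "missing_rate outside [0, 1)")


@dataclass
class GeneratorConfig:
    """Full generative specification of a synthetic cohort."""

    name: str
    n_subjects: int
    class_names: list[str]
    prevalences: np.ndarray  # (K,)
    metadata: list[ItemMetadata]
    item_profiles: np.ndarray  # (K, J, Cmax), padded with zeros
    covariate_models: dict[str, CovariateModel]
    site_names: list[str]
    site_metro: np.ndarray  # (S,) bool
    site_probs: np.ndarray  # (K, S); identical rows = independent of class
    missing_rows: int = 0
    missing_count_probs: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    seed: int = 0
    utility: UtilitySpec | None = None

    @property
    def n_classes(self) -> int:
        return len(self.prevalences)

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ConfigError("n_classes", "must be at least 1")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects", "must be at least 1")
        if len(self.class_names) != self.n_classes:
            raise ConfigError("class_names", "length must equal n_classes")
        if abs(self.prevalences.sum() - 1.0) > _PROB_TOL:
            raise ConfigError(
                "prevalences", f"sum {self.prevalences.sum()!r} != 1"
            )
        if np.any(self.prevalences < 0):
            raise ConfigError("prevalences", "must be non-negative")
        K, J = self.n_classes, len(self.metadata)
        if self.item_profiles.shape[:2] != (K, J):
            raise ConfigError("items", "item_profiles shape mismatch")
        for j, item in enumerate(self.metadata):
            C = item.n_categories
            rows = self.item_profiles[:, j, :C]
            if np.any(np.abs(rows.sum(axis=1) - 1.0) > _PROB_TOL):
                raise ConfigError(
                    f"items.{item.item_id}.class_probs", "rows must sum to 1"
                )
            if np.any(rows < 0):
                raise ConfigError(
                    f"items.{item.item_id}.class_probs", "negative probability"
                )
            if np.any(self.item_profiles[:, j, C:] != 0):
                raise ConfigError(
                    f"items.{item.item_id}.class_probs", "probability beyond n_categories"
                )
        for model in self.covariate_models.values():
            model.validate(K)
        if self.site_probs.shape != (K, len(self.site_names)):
            raise ConfigError("sites", "site_probs shape mismatch")
        if np.any(np.abs(self.site_probs.sum(axis=1) - 1.0) > _PROB_TOL):
            raise ConfigError("sites", "site probabilities must sum to 1")
        if not (0 <= self.missing_rows <= self.n_subjects):
            raise ConfigError("item_missingness.n_rows", "outside [0, n_subjects]")
        cp = self.missing_count_probs
        if cp and (abs(sum(cp.values()) - 1.0) > 1e-9 or min(cp) < 1):
            raise ConfigError(
                "item_missingness.count_probs",
                "counts must be >= 1 and probabilities sum to 1",
            )


@dataclass
class SyntheticCohort:
    items: ItemResponseMatrix
    covariates: CovariateTable
    true_class: np.ndarray  # 1-based labels
    site: np.ndarray
    config: GeneratorConfig


def _parse_per_class(value, class_names: list[str], fld: str) -> np.ndarray:
    """Accept either a list in class order or a {class_name: value} mapping."""
    if isinstance(value, dict):
        missing = set(class_names) - set(value)
        if missing:
            raise ConfigError(fld, f"missing classes {sorted(missing)}")
        return np.array([value[c] for c in class_names], dtype=float)
    arr = np.array(value, dtype=float)
    if len(arr) != len(class_names):
        raise ConfigError(fld, "length must equal number of classes")
    return arr


def load_profile(path_or_name) -> GeneratorConfig:
    """Load and validate a generator profile from YAML.

    ``path_or_name`` is either a filesystem path or the name of a packaged
    profile (e.g. ``"aqol_paper_profile"``).
    """
    p = Path(str(path_or_name))
    if not p.exists():
        res = importlib.resources.files("qolclasses") / "profiles" / f"{p.name}.yaml"
        if not res.is_file():
            raise ConfigError("profile", f"no such file or packaged profile: {path_or_name}")
        raw = yaml.safe_load(res.read_text())
    else:
        with open(p) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("profile", "top level must be a mapping")

    def need(key):
        if key not in raw:
            raise ConfigError(key, "missing field")
        return raw[key]

    class_names = [str(c) for c in need("class_names")]
    K = len(class_names)
    prevalences = np.array(need("prevalences"), dtype=float)

    metadata, profiles = [], []
    for entry in need("items"):
        try:
            item = ItemMetadata(
                str(entry["item_id"]),
                str(entry["dimension"]),
                int(entry.get("n_categories", 5)),
            )
        except KeyError as e:
            raise ConfigError(f"items.{e.args[0]}", "missing field") from e
        metadata.append(item)
        cp = entry.get("class_probs")
        if cp is None:
            raise ConfigError(f"items.{item.item_id}.class_probs", "missing field")
        if isinstance(cp, dict):
            rows = [cp.get(c) for c in class_names]
            if any(r is None for r in rows):
                raise ConfigError(
                    f"items.{item.item_id}.class_probs", "missing class row"
                )
        else:
            rows = cp
        profiles.append(np.array(rows, dtype=float))
    Cmax = max(m.n_categories for m in metadata)
    item_profiles = np.zeros((K, len(metadata), Cmax))
    for j, (item, rows) in enumerate(zip(metadata, profiles)):
        if rows.shape != (K, item.n_categories):
            raise ConfigError(
                f"items.{item.item_id}.class_probs",
                f"expected shape {(K, item.n_categories)}, got {rows.shape}",
            )
        item_profiles[:, j, : item.n_categories] = rows

    models = {}
    for name, spec in raw.get("covariates", {}).items():
        fld = f"covariates.{name}"
        family = spec.get("family")
        model = CovariateModel(
            name=name,
            family=str(family),
            missing_rate=float(spec.get("missing_rate", 0.0)),
        )
        if family == "continuous-normal":
            model.means = _parse_per_class(spec.get("means"), class_names, f"{fld}.means")
            model.sds = _parse_per_class(spec.get("sds"), class_names, f"{fld}.sds")
            model.clip = tuple(spec["clip"]) if "clip" in spec else None
            model.integer = bool(spec.get("integer", False))
        elif family == "binary":
            model.probs = _parse_per_class(spec.get("probs"), class_names, f"{fld}.probs")
        elif family == "categorical":
            model.levels = tuple(str(x) for x in spec.get("levels", ()))
            if not model.levels:
                raise ConfigError(f"{fld}.levels", "missing field")
            probs = spec.get("probs")
            if isinstance(probs, dict):
                probs = [probs[c] for c in class_names]
            model.probs = np.array(probs, dtype=float)
        models[name] = model

    site_names, site_metro, site_rows = [], [], []
    for entry in need("sites"):
        site_names.append(str(entry["name"]))
        site_metro.append(bool(entry["metro"]))
        if "probs" in entry:
            site_rows.append(_parse_per_class(entry["probs"], class_names, "sites.probs"))
        else:
            site_rows.append(np.full(K, float(entry["prob"])))
    site_probs = np.stack(site_rows, axis=1)  # (K, S)

    miss = raw.get("item_missingness", {}) or {}
    count_probs = {int(k): float(v) for k, v in (miss.get("count_probs") or {1: 1.0}).items()}

    util = raw.get("utility")
    config = GeneratorConfig(
        name=str(raw.get("name", "unnamed")),
        n_subjects=int(need("n_subjects")),
        class_names=class_names,
        prevalences=prevalences,
        metadata=metadata,
        item_profiles=item_profiles,
        covariate_models=models,
        site_names=site_names,
        site_metro=np.array(site_metro, dtype=bool),
        site_probs=site_probs,
        missing_rows=int(miss.get("n_rows", 0)),
        missing_count_probs=count_probs,
        seed=int(raw.get("seed", 0)),
        utility=UtilitySpec.from_dict(util) if util else None,
    )
    config.validate()
    return config


def config_to_dict(config: GeneratorConfig) -> dict:
    """Serialisable form of a config (inverse of :func:`load_profile`)."""
    items = []
    for j, item in enumerate(config.metadata):
        items.append(
            {
                "item_id": item.item_id,
                "dimension": item.dimension,
                "n_categories": item.n_categories,
                "class_probs": [
                    [float(x) for x in config.item_profiles[k, j, : item.n_categories]]
                    for k in range(config.n_classes)
                ],
            }
        )
    covs = {}
    for name, m in config.covariate_models.items():
        d: dict = {"family": m.family}
        if m.missing_rate:
            d["missing_rate"] = float(m.missing_rate)
        if m.family == "continuous-normal":
            d["means"] = [float(x) for x in m.means]
            d["sds"] = [float(x) for x in m.sds]
            if m.clip is not None:
                d["clip"] = [float(x) for x in m.clip]
            if m.integer:
                d["integer"] = True
        elif m.family == "binary":
            d["probs"] = [float(x) for x in m.probs]
        else:
            d["levels"] = list(m.levels)
            d["probs"] = [[float(x) for x in row] for row in m.probs]
        covs[name] = d
    sites = [
        {
            "name": nm,
            "metro": bool(metro),
            "probs": [float(x) for x in config.site_probs[:, s]],
        }
        for s, (nm, metro) in enumerate(zip(config.site_names, config.site_metro))
    ]
    out = {
        "name": config.name,
        "seed": int(config.seed),
        "n_subjects": int(config.n_subjects),
        "class_names": list(config.class_names),
        "prevalences": [float(x) for x in config.prevalences],
        "items": items,
        "covariates": covs,
        "sites": sites,
        "item_missingness": {
            "n_rows": int(config.missing_rows),
            "count_probs": {int(k): float(v) for k, v in config.missing_count_probs.items()},
        },
    }
    if config.utility is not None:
        out["utility"] = config.utility.to_dict()
    return out


def save_profile(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Draw one cohort from a validated generator configuration.

    Draw order (fixed for reproducibility): classes, items, sites,
    covariates (config order), item missingness, covariate missingness.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K, J = config.n_subjects, config.n_classes, len(config.metadata)

    true_class = rng.choice(K, size=n, p=config.prevalences) + 1

    values = np.zeros((n, J), dtype=np.int64)
    u = rng.random((n, J))
    for j, item in enumerate(config.metadata):
        cum = np.cumsum(config.item_profiles[:, j, : item.n_categories], axis=1)
        # searchsorted per person against their class's cdf
        cdf = cum[true_class - 1]  # (n, C)
        values[:, j] = item.min_code + (u[:, j : j + 1] > cdf[:, :-1]).sum(axis=1)

    site_cdf = np.cumsum(config.site_probs, axis=1)[true_class - 1]
    site_idx = (rng.random((n, 1)) > site_cdf[:, :-1]).sum(axis=1)
    site = np.array(config.site_names)[site_idx]
    region = np.where(config.site_metro[site_idx], "metropolitan", "regional")

    cols: dict[str, np.ndarray | pd.Series] = {}
    continuous, binary, categorical = [], [], {}
    for name, m in config.covariate_models.items():
        kidx = true_class - 1
        if m.family == "continuous-normal":
            x = rng.normal(np.asarray(m.means)[kidx], np.asarray(m.sds)[kidx])
            if m.clip is not None:
                x = np.clip(x, *m.clip)
            if m.integer:
                x = np.round(x)
            cols[name] = x
            continuous.append(name)
        elif m.family == "binary":
            cols[name] = (rng.random(n) < np.asarray(m.probs)[kidx]).astype(float)
            binary.append(name)
        else:
            cdf = np.cumsum(m.probs, axis=1)[kidx]
            idx = (rng.random((n, 1)) > cdf[:, :-1]).sum(axis=1)
            cols[name] = pd.Series(np.array(m.levels)[idx])
            categorical[name] = m.levels

    mask = np.zeros((n, J), dtype=bool)
    if config.missing_rows:
        rows = rng.choice(n, size=config.missing_rows, replace=False)
        counts = np.array(sorted(config.missing_count_probs))
        probs = np.array([config.missing_count_probs[c] for c in counts])
        per_row = rng.choice(counts, size=config.missing_rows, p=probs)
        for r, c in zip(rows, per_row):
            miss_items = rng.choice(J, size=min(int(c), J), replace=False)
            mask[r, miss_items] = True
    mins = np.array([m.min_code for m in config.metadata])
    values = np.where(mask, mins[None, :], values)

    df = pd.DataFrame(cols)
    df["site"] = site
    df["region"] = region
    df.index.name = "person_id"
    for name, m in config.covariate_models.items():
        if m.missing_rate > 0:
            hole = rng.random(n) < m.missing_rate
            df.loc[hole, name] = np.nan
    categorical["site"] = tuple(config.site_names)
    categorical["region"] = ("metropolitan", "regional")

    items = ItemResponseMatrix(values, mask, list(config.metadata))
    covariates = CovariateTable(
        df, tuple(continuous), tuple(binary), categorical
    )
    return SyntheticCohort(items, covariates, true_class, site, config)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write items, covariates and ground-truth labels as CSV (empty = missing)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "items": out / "items.csv",
        "covariates": out / "covariates.csv",
        "true_classes": out / "true_classes.csv",
    }
    cohort.items.to_frame().to_csv(paths["items"])
    cov = cohort.covariates.data.copy()
    cov.index.name = "person_id"
    cov.to_csv(paths["covariates"])
    pd.DataFrame(
        {"true_class": cohort.true_class, "site": cohort.site},
        index=pd.RangeIndex(len(cohort.true_class), name="person_id"),
    ).to_csv(paths["true_classes"])
    return paths
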