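"""Demographic/clinical covariate table, standardisation and class profiling.

The covariate battery mirrors what youth primary mental-health services
collect at intake: age, sex, LGBTIQ and NEET status, recruitment region,
primary diagnosis, clinical stage (0, 1a, 1b, 2-4) and self-report symptom
totals (PHQ-9 depression, GAD-7 anxiety, SIQ-JR suicidal ideation, PSQI
sleep quality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedStatisticError

#: admissible ranges for the symptom totals
CLINICAL_RANGES = {
    "phq9": (0, 27),
    "gad7": (0, 21),
    "siq_jr": (0, 90),
    "psqi": (0, 21),
}

CLINICAL_VARS = tuple(CLINICAL_RANGES)

STAGE_LEVELS = ("0-1a", "1b", "2-4")


@dataclass
class CovariateTable:
    """Per-person covariates with variable-kind metadata.

    ``standardisation`` records, per variable, the (mean, sd) that was
    subtracted/divided so standardisation is reproducible and reversible.
    """

    data: pd.DataFrame
    continuous: tuple = ()
    binary: tuple = ()
    categorical: dict = field(default_factory=dict)  # name -> tuple of levels
    standardisation: dict = field(default_factory=dict)  # name -> (mean, sd)

    def __post_init__(self):
        for name in (*self.continuous, *self.binary, *self.categorical):
            if name not in self.data.columns:
                raise ConfigError(f"covariates.{name}", "declared but not in table")
        for name, (lo, hi) in CLINICAL_RANGES.items():
            if name in self.data.columns and name not in self.standardisation:
                col = self.data[name].dropna()
                if len(col) and ((col < lo) | (col > hi)).any():
                    raise ConfigError(
                        f"covariates.{name}", f"values outside [{lo}, {hi}]"
                    )
        if "clinical_stage" in self.categorical:
            observed = set(self.data["clinical_stage"].dropna().unique())
            if not observed <= set(self.categorical["clinical_stage"]):
                raise ConfigError(
                    "covariates.clinical_stage",
                    f"levels {observed} outside {self.categorical['clinical_stage']}",
                )

    @property
    def variables(self) -> tuple:
        return (*self.continuous, *self.binary, *self.categorical)

    def copy(self) -> "CovariateTable":
        return replace(
            self,
            data=self.data.copy(),
            standardisation=dict(self.standardisation),
            categorical=dict(self.categorical),
        )

    def missing_counts(self) -> pd.Series:
        return self.data[list(self.variables)].isna().sum()


def standardise_covariates(
    table: CovariateTable,
    variables: tuple = CLINICAL_VARS,
    sds: dict | None = None,
    means: dict | None = None,
) -> CovariateTable:
    """Centre and scale the named continuous variables to unit s.d.

    ``sds``/``means`` allow fixed, externally supplied values (e.g. published
    whole-cohort statistics); otherwise observed-case statistics are used.
    Dummies and age are left untouched by the default variable list.
    Already-standardised variables (recorded in ``standardisation``) pass
    through unchanged, making the operation idempotent.
    """
    out = table.copy()
    for name in variables:
        if name not in out.data.columns:
            continue
        if name in out.standardisation:
            continue
        col = out.data[name].astype(float)
        mean = means.get(name) if means else None
        sd = sds.get(name) if sds else None
        if mean is None:
            mean = float(col.mean())
        if sd is None:
            sd = float(col.std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise UndefinedStatisticError(
                f"cannot standardise {name!r}: s.d. is {sd}"
            )
        out.data[name] = (col - mean) / sd
        out.standardisation[name] = (mean, sd)
    return out


@dataclass
class ClassProfile:
    """Per-class covariate and score summaries (Table-1 style)."""

    continuous: pd.DataFrame  # (variable, stat) x class: median, q1, q3, n
    categorical: pd.DataFrame  # (variable, level, stat) x class: n, pct
    utility: pd.DataFrame | None  # class x (mean, sd, n)
    class_sizes: pd.Series

    def formatted(self) -> pd.DataFrame:
        """Human-readable 'median (IQR)' / 'n (%)' table."""
        rows = {}
        for var in self.continuous.index.get_level_values(0).unique():
            med = self.continuous.loc[(var, "median")]
            q1 = self.continuous.loc[(var, "q1")]
            q3 = self.continuous.loc[(var, "q3")]
            rows[var] = [
                f"{m:.1f} ({a:.1f}-{b:.1f})" for m, a, b in zip(med, q1, q3)
            ]
        for var, level in {
            (v, l)
            for v, l, _ in self.categorical.index
        }:
            n = self.categorical.loc[(var, level, "n")]
            pct = self.categorical.loc[(var, level, "pct")]
            rows[f"{var}={level}"] = [
                f"{int(c)} ({p:.0f}%)" for c, p in zip(n, pct)
            ]
        return pd.DataFrame(rows, index=self.class_sizes.index).T


def profile_classes(
    labels: np.ndarray,
    table: CovariateTable,
    utility: np.ndarray | pd.Series | None = None,
    class_names: list[str] | None = None,
) -> ClassProfile:
    """Summarise covariates per class on available (non-missing) cases.

    Continuous variables get median and quartiles, categorical/binary get
    counts and percentages of non-missing cases; utility (if given) gets
    mean and s.d. per class.  Empty classes yield zero-count rows.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table.data):
        raise ConfigError("labels", "length does not match covariate table")
    classes = sorted(np.unique(labels))
    if class_names is None:
        class_names = [f"class_{k}" for k in classes]
    name_of = dict(zip(classes, class_names))

    cont_rows, cat_rows = {}, {}
    sizes = pd.Series(
        [int((labels == k).sum()) for k in classes], index=class_names, name="n"
    )
    for var in table.continuous:
        col = table.data[var].astype(float)
        for stat in ("median", "q1", "q3", "n"):
            cont_rows[(var, stat)] = []
        for k in classes:
            sub = col[labels == k].dropna()
            cont_rows[(var, "median")].append(sub.median() if len(sub) else np.nan)
            cont_rows[(var, "q1")].append(sub.quantile(0.25) if len(sub) else np.nan)
            cont_rows[(var, "q3")].append(sub.quantile(0.75) if len(sub) else np.nan)
            cont_rows[(var, "n")].append(len(sub))
    binary_levels = {v: (1,) for v in table.binary}
    cat_levels = {v: tuple(lv) for v, lv in table.categorical.items()}
    for var, levels in {**binary_levels, **cat_levels}.items():
        col = table.data[var]
        for level in levels:
            for k in classes:
                sub = col[labels == k].dropna()
                n = int((sub == level).sum())
                pct = 100.0 * n / len(sub) if len(sub) else 0.0
                cat_rows.setdefault((var, level, "n"), []).append(n)
                cat_rows.setdefault((var, level, "pct"), []).append(pct)

    cont = pd.DataFrame(cont_rows, index=class_names).T
    cat = pd.DataFrame(cat_rows, index=class_names).T
    util_df = None
    if utility is not None:
        utility = np.asarray(utility, dtype=float)
        util_df = pd.DataFrame(
            {
                "mean": [np.nanmean(utility[labels == k]) if (labels == k).any() else np.nan for k in classes],
                "sd": [np.nanstd(utility[labels == k], ddof=1) if (labels == k).sum() > 1 else np.nan for k in classes],
                "n": [(labels == k).sum() for k in classes],
            },
            index=class_names,
        )
    return ClassProfile(cont, cat, util_df, sizes)


def read_covariates_csv(
    path,
    continuous: tuple = ("age", *CLINICAL_VARS),
    binary: tuple = ("female", "lgbtiq", "neet"),
    categorical: dict | None = None,
) -> CovariateTable:
    df = pd.read_csv(path, index_col=0)
    if categorical is None:
        categorical = {}
        for var in ("diagnosis", "clinical_stage", "region", "site"):
            if var in df.columns:
                levels = tuple(pd.unique(df[var].dropna()))
                if var == "clinical_stage":
                    levels = STAGE_LEVELS
                categorical[var] = levels
    continuous = tuple(v for v in continuous if v in df.columns)
    binary = tuple(v for v in binary if v in df.columns)
    return CovariateTable(df, continuous, binary, categorical)
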