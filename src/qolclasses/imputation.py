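"""Multiple imputation of covariates by chained equations.

Each incomplete variable is imputed from all the others (plus optional
extra predictors such as assigned class) with a family-appropriate
conditional model: predictive-mean matching for continuous variables,
logistic draws for binary, multinomial-logistic draws for categorical.
The chain runs a fixed number of sweeps per copy; ``m`` independent,
seeded chains yield the imputation set, on which Rubin's rules are applied
downstream.  Non-missing cells are identical across copies by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .covariates import CovariateTable
from .errors import ConfigError, EmptyDataError


@dataclass
class ImputationSet:
    tables: list[CovariateTable]
    seed: int
    n_iterations: int
    method: dict  # variable -> conditional-model family

    @property
    def m(self) -> int:
        return len(self.tables)


def _encode(df: pd.DataFrame, table: CovariateTable, exclude: str) -> np.ndarray:
    """Numeric design from all variables except ``exclude`` (dummies for
    categoricals, reference level dropped).  Continuous columns are scaled
    to unit variance so the conditional-model solvers stay well conditioned;
    this does not change the imputations' distribution."""
    parts = []
    for v in table.continuous + table.binary:
        if v != exclude:
            col = df[v].to_numpy(dtype=float)
            if v in table.continuous:
                sd = col.std()
                col = (col - col.mean()) / (sd if sd > 0 else 1.0)
            parts.append(col[:, None])
    for v, levels in table.categorical.items():
        if v == exclude:
            continue
        col = df[v]
        for level in levels[1:]:
            parts.append((col == level).to_numpy(dtype=float)[:, None])
    return np.hstack(parts) if parts else np.empty((len(df), 0))


def _pmm_draw(rng, model, x_obs, y_obs, x_mis, k_donors=5):
    pred_obs = model.predict(x_obs)
    pred_mis = model.predict(x_mis)
    out = np.empty(len(pred_mis))
    for i, p in enumerate(pred_mis):
        nearest = np.argsort(np.abs(pred_obs - p))[:k_donors]
        out[i] = y_obs[rng.choice(nearest)]
    return out


def impute_covariates(
    table: CovariateTable,
    m: int = 20,
    seed: int = 0,
    n_iterations: int = 10,
    extra_predictors: pd.DataFrame | None = None,
) -> ImputationSet:
    """Build ``m`` completed copies of a covariate table.

    ``extra_predictors`` (fully observed, index-aligned) are used in every
    conditional model but never imputed — typically the assigned latent
    class, keeping the imputation model congenial with the analysis model.
    """
    if m < 2:
        raise ConfigError("m", "need at least 2 imputations")
    work_base = table.data[list(table.variables)].copy()
    missing = work_base.isna()
    rates = missing.mean()
    all_missing = rates[rates >= 1.0]
    if len(all_missing):
        raise EmptyDataError(
            f"variable(s) entirely missing: {list(all_missing.index)}"
        )
    heavy = rates[rates > 0.5]
    if len(heavy):
        warnings.warn(
            f"variable(s) over 50% missing: {list(heavy.index)}", RuntimeWarning
        )
    incomplete = [v for v in table.variables if missing[v].any()]
    method = {}
    for v in incomplete:
        if v in table.continuous:
            method[v] = "pmm"
        elif v in table.binary:
            method[v] = "logistic"
        else:
            method[v] = "multinomial"

    extra = None
    if extra_predictors is not None:
        extra = pd.get_dummies(
            extra_predictors, drop_first=True, dtype=float
        ).to_numpy()

    ss = np.random.SeedSequence(seed)
    tables = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        df = work_base.copy()
        # initial fill: random draws from the observed values
        for v in incomplete:
            obs = df[v].dropna().to_numpy()
            df.loc[missing[v], v] = rng.choice(obs, size=int(missing[v].sum()))
        for _ in range(n_iterations if incomplete else 0):
            for v in incomplete:
                x = _encode(df, table, exclude=v)
                if extra is not None:
                    x = np.hstack([x, extra])
                mis = missing[v].to_numpy()
                x_obs, x_mis = x[~mis], x[mis]
                y_obs = work_base.loc[~missing[v], v]
                if method[v] == "pmm":
                    model = LinearRegression().fit(x_obs, y_obs.to_numpy(dtype=float))
                    df.loc[mis, v] = _pmm_draw(
                        rng, model, x_obs, y_obs.to_numpy(dtype=float), x_mis
                    )
                else:
                    y_cat = y_obs.astype(str).to_numpy()
                    classes = np.unique(y_cat)
                    if len(classes) < 2:
                        df.loc[mis, v] = y_obs.iloc[0]
                        continue
                    model = LogisticRegression(max_iter=500).fit(x_obs, y_cat)
                    probs = model.predict_proba(x_mis)
                    draws = [
                        model.classes_[rng.choice(len(model.classes_), p=p)]
                        for p in probs
                    ]
                    if method[v] == "logistic":
                        df.loc[mis, v] = np.array(draws, dtype=float)
                    else:
                        df.loc[mis, v] = draws
        out = table.copy()
        out.data[list(table.variables)] = df
        tables.append(out)
    return ImputationSet(tables, seed, n_iterations, method)
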