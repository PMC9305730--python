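"""AQoL-6D scoring: unweighted totals, standardised dimension scores,
utility index and internal consistency.

Dimension totals are plain sums of item codes (higher = poorer QoL).  The
standardised dimension score reverse min-max scales the total onto 0 (worst
health state, all items at their maximum code) to 100 (best health state,
all items at their minimum code).  The utility index maps the full response
pattern onto 0 (worst) to 1 (best) through a pluggable :class:`UtilitySpec`;
the packaged surrogate combines dimension disvalues multiplicatively, the
standard form for multi-attribute utility instruments.  Persons with any
missing item in a dimension get no score for that dimension (no pro-rating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, UndefinedStatisticError
from .metadata import DIMENSIONS, ItemMetadata, dimension_indices
from .responses import ItemResponseMatrix


def unweighted_totals(items: ItemResponseMatrix) -> pd.DataFrame:
    """Per-person, per-dimension sums of item codes (NaN if any item missing)."""
    dims = dimension_indices(items.metadata)
    vals = items.values.astype(float)
    vals[items.mask] = np.nan
    out = {}
    for dim, cols in dims.items():
        out[dim] = vals[:, cols].sum(axis=1)  # NaN propagates
    return pd.DataFrame(out, index=items.ids)


def standardise_dimension(items: ItemResponseMatrix, dimension: str) -> np.ndarray:
    """Reverse min-max scaled dimension total on 0 (worst) .. 100 (best)."""
    dims = dimension_indices(items.metadata)
    if dimension not in dims:
        raise ConfigError("dimension", f"unknown dimension {dimension!r}")
    cols = dims[dimension]
    meta = [items.metadata[j] for j in cols]
    min_total = sum(m.min_code for m in meta)
    max_total = sum(m.max_code for m in meta)
    vals = items.values.astype(float)
    vals[items.mask] = np.nan
    total = vals[:, cols].sum(axis=1)
    return 100.0 * (max_total - total) / (max_total - min_total)


def standardised_scores(items: ItemResponseMatrix) -> pd.DataFrame:
    dims = dimension_indices(items.metadata)
    data = {d: standardise_dimension(items, d) for d in dims}
    return pd.DataFrame(data, index=items.ids)


@dataclass
class UtilitySpec:
    """Dimension-weighted utility on 0 (worst health state) .. 1 (best).

    ``rule`` is either ``"multiplicative"`` — utility is one minus a
    rescaled product of per-dimension disvalue factors, so deficits compound
    — or ``"additive"`` — a weight-normalised sum of disvalues.  Both forms
    are anchored exactly at 1 for the best state and 0 for the worst.  The
    weights are per dimension in (0, 1].
    """

    name: str
    weights: dict[str, float] = field(default_factory=dict)
    rule: str = "multiplicative"

    def __post_init__(self):
        if self.rule not in ("multiplicative", "additive"):
            raise ConfigError("utility.rule", f"unknown rule {self.rule!r}")
        for dim, w in self.weights.items():
            if not (0.0 < w <= 1.0):
                raise ConfigError(
                    f"utility.weights.{dim}", f"weight {w} outside (0, 1]"
                )
        missing = set(DIMENSIONS) - set(self.weights)
        if missing:
            raise ConfigError(
                "utility.weights", f"missing dimensions: {sorted(missing)}"
            )

    def evaluate(self, disvalues: np.ndarray, dims: list[str]) -> np.ndarray:
        """Utility from per-dimension disvalues (0 best .. 1 worst), shape (n, D)."""
        w = np.array([self.weights[d] for d in dims])
        if self.rule == "additive":
            return 1.0 - disvalues @ w / w.sum()
        worst = np.prod(1.0 - w)
        raw = 1.0 - np.prod(1.0 - w[None, :] * disvalues, axis=1)
        return 1.0 - raw / (1.0 - worst)

    def validate_endpoints(self) -> None:
        dims = list(self.weights)
        best = self.evaluate(np.zeros((1, len(dims))), dims)[0]
        worst = self.evaluate(np.ones((1, len(dims))), dims)[0]
        if abs(best - 1.0) > 1e-9 or abs(worst) > 1e-9:
            raise ConfigError(
                "utility",
                f"endpoint invariant violated: best={best!r}, worst={worst!r}",
            )

    def to_dict(self) -> dict:
        return {"name": self.name, "rule": self.rule, "weights": dict(self.weights)}

    @classmethod
    def from_dict(cls, d: dict) -> "UtilitySpec":
        try:
            return cls(name=d["name"], weights=dict(d["weights"]), rule=d.get("rule", "multiplicative"))
        except KeyError as e:
            raise ConfigError(f"utility.{e.args[0]}", "missing field") from e

    @classmethod
    def from_yaml(cls, path) -> "UtilitySpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_utility(items: ItemResponseMatrix, spec: UtilitySpec) -> np.ndarray:
    """Per-person utility in [0, 1]; NaN for persons with missing items."""
    spec.validate_endpoints()
    scores = standardised_scores(items)
    dims = list(scores.columns)
    dis = 1.0 - scores.to_numpy() / 100.0
    return spec.evaluate(dis, dims)


@dataclass
class DimensionScoreSet:
    unweighted_total: pd.DataFrame
    standardised: pd.DataFrame
    utility: pd.Series


def score_cohort(items: ItemResponseMatrix, spec: UtilitySpec) -> DimensionScoreSet:
    totals = unweighted_totals(items)
    std = standardised_scores(items)
    util = pd.Series(compute_utility(items, spec), index=items.ids, name="utility")
    return DimensionScoreSet(totals, std, util)


def cronbach_alpha(items: ItemResponseMatrix, dimension: str) -> float:
    """Cronbach's alpha for one dimension, listwise complete within dimension.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total)).
    """
    dims = dimension_indices(items.metadata)
    if dimension not in dims:
        raise ConfigError("dimension", f"unknown dimension {dimension!r}")
    cols = dims[dimension]
    k = len(cols)
    if k < 2:
        raise UndefinedStatisticError("alpha needs at least 2 items")
    complete = ~items.mask[:, cols].any(axis=1)
    if complete.sum() < 2:
        raise UndefinedStatisticError("alpha needs at least 2 complete rows")
    x = items.values[np.ix_(complete, cols)].astype(float)
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError(
            f"total score variance is zero in dimension {dimension!r}"
        )
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
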