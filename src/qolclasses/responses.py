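"""Ordinal item-response containers, validation and the complete-case filter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDataError, RangeError, SchemaError
from .metadata import ItemMetadata


@dataclass
class ItemResponseMatrix:
    """N persons by J ordinal items with an explicit missingness mask.

    ``values`` holds integer codes; cells flagged in ``mask`` are missing and
    their stored value is a placeholder (the item's ``min_code``).  ``ids``
    are row identifiers that survive filtering, so dropped-row reports can
    name the original persons.
    """

    values: np.ndarray
    mask: np.ndarray
    metadata: list[ItemMetadata]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D array")
        if self.values.shape != self.mask.shape:
            raise SchemaError("values and mask shapes differ")
        if self.values.shape[1] != len(self.metadata):
            raise SchemaError(
                f"{self.values.shape[1]} columns but {len(self.metadata)} items"
            )
        if self.ids is None:
            self.ids = np.arange(self.values.shape[0])
        else:
            self.ids = np.asarray(self.ids)
        for j, item in enumerate(self.metadata):
            col = self.values[:, j]
            ok = self.mask[:, j] | ((col >= item.min_code) & (col <= item.max_code))
            if not ok.all():
                i = int(np.argmin(ok))
                raise RangeError(
                    f"value {col[i]} out of range [{item.min_code}, "
                    f"{item.max_code}] for item {item.item_id} at row "
                    f"{self.ids[i]!r}"
                )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return [m.item_id for m in self.metadata]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([m.n_categories for m in self.metadata])

    def codes0(self) -> np.ndarray:
        """Zero-based codes (missing cells read 0; mask before use)."""
        mins = np.array([m.min_code for m in self.metadata])
        return self.values - mins[None, :]

    def complete_rows(self) -> np.ndarray:
        return ~self.mask.any(axis=1)

    def subset(self, rows) -> "ItemResponseMatrix":
        rows = np.asarray(rows)
        return ItemResponseMatrix(
            self.values[rows], self.mask[rows], self.metadata, self.ids[rows]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids, index=self.ids)
        df = df.astype("Int64")
        df[self.mask] = pd.NA
        df.index.name = "person_id"
        return df


@dataclass
class CompleteCaseReport:
    n_input: int
    n_retained: int
    dropped_ids: list

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_ids)


def validate_responses(
    raw: pd.DataFrame, metadata: list[ItemMetadata]
) -> ItemResponseMatrix:
    """Check a person-by-item table against item metadata.

    Columns must match the metadata item ids exactly (any order); empty cells
    become masked missing values; out-of-range values raise
    :class:`RangeError` naming the row and item.
    """
    expected = [m.item_id for m in metadata]
    missing_cols = set(expected) - set(raw.columns)
    extra_cols = set(raw.columns) - set(expected)
    if missing_cols or extra_cols:
        raise SchemaError(
            f"item columns do not match metadata (missing: {sorted(missing_cols)}, "
            f"unknown: {sorted(extra_cols)})"
        )
    raw = raw[expected]
    mask = raw.isna().to_numpy()
    values = raw.to_numpy(dtype=float)
    non_missing = values[~mask]
    if non_missing.size and not np.allclose(non_missing, np.round(non_missing)):
        bad = np.argwhere(~mask & (values != np.round(values)))[0]
        raise RangeError(
            f"non-integer response {values[bad[0], bad[1]]!r} for item "
            f"{expected[bad[1]]} at row {raw.index[bad[0]]!r}"
        )
    filled = np.where(mask, 0, np.nan_to_num(values)).astype(np.int64)
    mins = np.array([m.min_code for m in metadata])
    filled = np.where(mask, mins[None, :], filled)
    return ItemResponseMatrix(filled, mask, list(metadata), raw.index.to_numpy())


def complete_case_filter(
    items: ItemResponseMatrix,
) -> tuple[ItemResponseMatrix, CompleteCaseReport]:
    """Drop every person with at least one missing item.

    Mirrors the analysis convention of retaining only fully answered AQoL-6D
    questionnaires.  Raises :class:`EmptyDataError` if nothing survives.
    """
    keep = items.complete_rows()
    report = CompleteCaseReport(
        n_input=items.n_persons,
        n_retained=int(keep.sum()),
        dropped_ids=list(items.ids[~keep]),
    )
    if report.n_retained == 0:
        raise EmptyDataError("complete-case filter dropped every row")
    return items.subset(keep), report


def read_items_csv(path, metadata: list[ItemMetadata]) -> ItemResponseMatrix:
    """Read a person-by-item CSV (first column = person id, empty = missing)."""
    df = pd.read_csv(path, index_col=0)
    return validate_responses(df, metadata)


def write_items_csv(items: ItemResponseMatrix, path) -> None:
    items.to_frame().to_csv(path)
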