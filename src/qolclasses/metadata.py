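"""AQoL-6D instrument metadata.

The Assessment of Quality of Life - 6 dimensions (adolescent version) has 20
ordinal items grouped into six dimensions: independent living (4 items),
social and family relationships (3), mental health (4), coping (3), pain (3)
and senses (3).  Item codes run from ``min_code`` (best health) upward, so
higher codes mean poorer quality of life.

The container types in this package are generic over any item set (small
instruments are used heavily in tests); :func:`aqol_metadata` builds the
canonical 20-item AQoL-6D layout and :func:`check_aqol_structure` asserts the
4/3/4/3/3/3 dimension counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

DIMENSION_ITEM_COUNTS = {
    "independent_living": 4,
    "relationships": 3,
    "mental_health": 4,
    "coping": 3,
    "pain": 3,
    "senses": 3,
}

DIMENSIONS = tuple(DIMENSION_ITEM_COUNTS)


@dataclass(frozen=True)
class ItemMetadata:
    """One ordinal questionnaire item.

    Codes are integers in ``[min_code, max_code]``; ``min_code`` is the best
    response (e.g. 1 "very happy") and ``max_code`` the worst.
    """

    item_id: str
    dimension: str
    n_categories: int = 5
    min_code: int = 1

    def __post_init__(self):
        if self.n_categories < 2:
            raise ConfigError(
                f"items.{self.item_id}.n_categories", "must be at least 2"
            )
        if self.dimension not in DIMENSION_ITEM_COUNTS:
            raise ConfigError(
                f"items.{self.item_id}.dimension",
                f"unknown dimension {self.dimension!r}; expected one of {DIMENSIONS}",
            )

    @property
    def max_code(self) -> int:
        return self.min_code + self.n_categories - 1


def aqol_metadata(n_categories: int = 5) -> list[ItemMetadata]:
    """Canonical AQoL-6D layout: items Q1..Q20 in dimension order."""
    items = []
    q = 1
    for dim, count in DIMENSION_ITEM_COUNTS.items():
        for _ in range(count):
            items.append(ItemMetadata(f"Q{q}", dim, n_categories))
            q += 1
    return items


def check_aqol_structure(metadata: list[ItemMetadata]) -> None:
    """Raise unless the item set has the AQoL-6D 4/3/4/3/3/3 dimension counts."""
    counts: dict[str, int] = {}
    for item in metadata:
        counts[item.dimension] = counts.get(item.dimension, 0) + 1
    if counts != DIMENSION_ITEM_COUNTS:
        raise ConfigError(
            "items",
            f"dimension item counts {counts} do not match AQoL-6D "
            f"{DIMENSION_ITEM_COUNTS}",
        )


def dimension_indices(metadata: list[ItemMetadata]) -> dict[str, list[int]]:
    """Column indices of each dimension's items, in metadata order."""
    out: dict[str, list[int]] = {}
    for j, item in enumerate(metadata):
        out.setdefault(item.dimension, []).append(j)
    return out
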