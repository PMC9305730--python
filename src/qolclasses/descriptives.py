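"""Polychoric item structure and multidimensional-scaling network layout.

Polychoric correlations assume each pair of ordinal items discretises a
latent bivariate normal; estimation is two-step: thresholds from the
univariate margins (normal quantiles of cumulative proportions), then a 1-D
likelihood maximisation over the latent correlation with thresholds fixed.
Bivariate-normal rectangle probabilities are computed from Owen's T
function, accurate to well below the 1e-7 tolerance the estimates rely on.

The network layout applies classical (Torgerson) MDS to the dissimilarity
``d_ij = sqrt(2 (1 - r_ij))``, so strongly associated items sit close
together; the embedding is deterministic up to rigid motion under a fixed
eigenvector sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import owens_t
from scipy.stats import norm

from .errors import DegenerateItemError, EstimationError
from .responses import ItemResponseMatrix


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's T representation; zero arguments are nudged by 1e-14, an error
    far below the 1e-7 accuracy floor documented for this module.
    """
    if np.isposinf(h) and np.isposinf(k):
        return 1.0
    if np.isneginf(h) or np.isneginf(k):
        return 0.0
    if np.isposinf(h):
        return float(norm.cdf(k))
    if np.isposinf(k):
        return float(norm.cdf(h))
    if rho >= 1.0:
        return float(norm.cdf(min(h, k)))
    if rho <= -1.0:
        return float(max(0.0, norm.cdf(h) + norm.cdf(k) - 1.0))
    if h == 0.0:
        h = 1e-14
    if k == 0.0:
        k = 1e-14
    r = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    delta = 0.0 if h * k > 0 else 0.5
    val = (
        0.5 * (norm.cdf(h) + norm.cdf(k))
        - owens_t(h, a_h)
        - owens_t(k, a_k)
        - delta
    )
    return float(min(1.0, max(0.0, val)))


def cell_probabilities(
    thr_x: np.ndarray, thr_y: np.ndarray, rho: float
) -> np.ndarray:
    """Rectangle probabilities of the discretised bivariate normal.

    ``thr_x``/``thr_y`` are the interior thresholds; the returned matrix has
    shape (len(thr_x)+1, len(thr_y)+1).
    """
    tx = np.concatenate([[-np.inf], thr_x, [np.inf]])
    ty = np.concatenate([[-np.inf], thr_y, [np.inf]])
    grid = np.array([[bvn_cdf(a, b, rho) for b in ty] for a in tx])
    cells = np.diff(np.diff(grid, axis=0), axis=1)
    return np.clip(cells, 0.0, 1.0)


def estimate_thresholds(x: np.ndarray, n_categories: int | None = None) -> np.ndarray:
    """Step 1: thresholds as normal quantiles of cumulative category proportions.

    ``x`` holds zero-based category codes.  A category with zero margin
    collapses its adjacent thresholds (allowed); a single observed category
    raises :class:`DegenerateItemError`.
    """
    x = np.asarray(x, dtype=int)
    if n_categories is None:
        n_categories = int(x.max()) + 1
    counts = np.bincount(x, minlength=n_categories)
    if (counts > 0).sum() < 2:
        raise DegenerateItemError(
            "variable has fewer than two observed categories"
        )
    cum = np.cumsum(counts[:-1]) / counts.sum()
    return norm.ppf(cum)


def polychoric_pair(
    x: np.ndarray,
    y: np.ndarray,
    n_cat_x: int | None = None,
    n_cat_y: int | None = None,
    bound: float = 0.999,
) -> float:
    """Two-step polychoric correlation of two zero-based ordinal vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    thr_x = estimate_thresholds(x, n_cat_x)
    thr_y = estimate_thresholds(y, n_cat_y)
    Cx, Cy = len(thr_x) + 1, len(thr_y) + 1
    table = np.zeros((Cx, Cy))
    np.add.at(table, (x, y), 1.0)

    def nll(rho: float) -> float:
        p = cell_probabilities(thr_x, thr_y, rho)
        return -float(np.sum(table * np.log(np.maximum(p, 1e-12))))

    res = minimize_scalar(
        nll, bounds=(-bound, bound), method="bounded", options={"xatol": 1e-5}
    )
    if not res.success:
        raise EstimationError(
            "polychoric likelihood optimisation failed", last_iterate=res.x
        )
    return float(np.clip(res.x, -bound, bound))


@dataclass
class PolychoricMatrix:
    """Symmetric polychoric correlation matrix with per-item thresholds."""

    r: np.ndarray  # (J, J), unit diagonal
    thresholds: list[np.ndarray]
    item_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.item_ids, columns=self.item_ids)


def polychoric_matrix(items: ItemResponseMatrix) -> PolychoricMatrix:
    """All pairwise polychoric correlations (pairwise-complete observations)."""
    J = items.n_items
    codes = items.codes0()
    nC = items.n_categories
    r = np.eye(J)
    thresholds = []
    for j in range(J):
        obs = ~items.mask[:, j]
        thresholds.append(estimate_thresholds(codes[obs, j], int(nC[j])))
    for i in range(J):
        for j in range(i + 1, J):
            both = ~(items.mask[:, i] | items.mask[:, j])
            try:
                rij = polychoric_pair(
                    codes[both, i], codes[both, j], int(nC[i]), int(nC[j])
                )
            except (DegenerateItemError, EstimationError) as e:
                raise EstimationError(
                    f"polychoric estimation failed for pair "
                    f"({items.item_ids[i]}, {items.item_ids[j]}): {e}"
                ) from e
            r[i, j] = r[j, i] = rij
    return PolychoricMatrix(r, thresholds, items.item_ids)


@dataclass
class NetworkLayout:
    """2-D MDS coordinates plus the edge list above a display threshold."""

    coordinates: np.ndarray  # (J, 2)
    edges: pd.DataFrame  # item_i, item_j, weight
    eigenvalues: np.ndarray
    item_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.item_ids, columns=["x", "y"]
        )


def mds_layout(
    pm: PolychoricMatrix, edge_threshold: float = 0.3
) -> NetworkLayout:
    """Classical MDS on ``d = sqrt(2 (1 - r))`` with 2 retained dimensions.

    Negative eigenvalues of the double-centred matrix (the dissimilarity is
    not always Euclidean-embeddable) are truncated with a warning.  Sign
    convention: each coordinate axis is flipped so its largest-magnitude
    entry is positive.
    """
    r = np.asarray(pm.r, dtype=float)
    J = r.shape[0]
    d2 = 2.0 * (1.0 - r)  # squared dissimilarities
    Jc = np.eye(J) - np.ones((J, J)) / J
    B = -0.5 * Jc @ d2 @ Jc
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.min() < -1e-8 * max(1.0, abs(vals).max()):
        warnings.warn(
            "double-centred matrix is not positive semidefinite; negative "
            "eigenvalues truncated",
            RuntimeWarning,
        )
    top = np.clip(vals[:2], 0.0, None)
    coords = vecs[:, :2] * np.sqrt(top)[None, :]
    for axis in range(2):
        imax = int(np.argmax(np.abs(coords[:, axis])))
        if coords[imax, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    ii, jj = np.triu_indices(J, k=1)
    keep = r[ii, jj] >= edge_threshold
    edges = pd.DataFrame(
        {
            "item_i": [pm.item_ids[a] for a in ii[keep]],
            "item_j": [pm.item_ids[b] for b in jj[keep]],
            "weight": r[ii, jj][keep],
        }
    )
    return NetworkLayout(coords, edges, vals, pm.item_ids)
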