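"""Cross-validated choice of the number of latent classes.

Three schemes mirror common practice for stabilising class enumeration in
clinical cohorts: seeded 10-fold CV, leave-one-site-out (one fold per
recruitment centre) and split-half CV (a 50/50 split evaluated in both
directions, i.e. 2-fold).  For each candidate K the model is fitted on the
training portion; the CV table records the fitting indices of the training
models (BIC, AIC, log-likelihood) together with held-out analogues
(held-out log-likelihood, and held-out BIC/AIC penalised with ``ln
N_test``).  The default selection index is the mean training-model BIC
across CV sets — averaging the main fitting index over resamples is what
stabilises class enumeration, while the held-out likelihood is reported as
an overfitting guard; any recorded index can be selected on instead.

A k-means-on-principal-components sensitivity analysis cross-checks the
latent classes with a distribution-free clustering of the same items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, QolClassesError
from .lca import fit_em, loglikelihood
from .responses import ItemResponseMatrix

SCHEMES = ("kfold", "loso", "splithalf")


@dataclass
class FoldSpec:
    """A partition of persons into evaluation folds."""

    scheme: str
    assignments: np.ndarray  # fold index per person
    n_folds: int
    seed: int
    fold_names: list[str]

    def check_partition(self) -> None:
        a = self.assignments
        if a.min() < 0 or a.max() >= self.n_folds:
            raise ConfigError("folds", "fold index out of range")
        # disjoint by construction (one label per person); require exhaustive
        if set(np.unique(a)) != set(range(self.n_folds)):
            raise ConfigError("folds", "some fold is empty")


def make_folds(
    n: int,
    scheme: str,
    sites: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> FoldSpec:
    """Build a fold assignment for one CV scheme.

    ``kfold``: seeded random near-equal partition.  ``loso``: one fold per
    distinct site label.  ``splithalf``: seeded 50/50 split (2 folds, so the
    CV loop evaluates both directions).
    """
    if scheme not in SCHEMES:
        raise ConfigError("scheme", f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    if scheme == "loso":
        if sites is None:
            raise ConfigError("sites", "loso requires site labels")
        sites = np.asarray(sites)
        uniq = sorted(pd.unique(sites))
        if len(uniq) < 2:
            raise ConfigError("sites", "loso needs at least 2 distinct sites")
        index = {s: f for f, s in enumerate(uniq)}
        assignments = np.array([index[s] for s in sites])
        spec = FoldSpec(scheme, assignments, len(uniq), seed, [str(s) for s in uniq])
    else:
        k = 2 if scheme == "splithalf" else n_folds
        if k > n:
            raise ConfigError("n_folds", f"{k} folds but only {n} persons")
        if k < 2:
            raise ConfigError("n_folds", "need at least 2 folds")
        assignments = np.empty(n, dtype=int)
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            assignments[chunk] = f
        spec = FoldSpec(scheme, assignments, k, seed, [f"fold_{f + 1}" for f in range(k)])
    spec.check_partition()
    return spec


def holdout_indices(
    train: ItemResponseMatrix,
    test: ItemResponseMatrix,
    K: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Fit on the training rows, score likelihood-based indices on held-out rows.

    Held-out BIC penalises with ``ln(N_test)`` (documented, configurable by
    recomputing from the returned cells).  Categories unseen in training are
    kept finite by the fitting smoothing floor and flagged.
    """
    fit = fit_em(train, K, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed)
    test_ll = loglikelihood(test, fit.params)
    unseen = False
    codes_tr, codes_te = train.codes0(), test.codes0()
    for j in range(train.n_items):
        if not set(np.unique(codes_te[:, j])) <= set(np.unique(codes_tr[:, j])):
            unseen = True
            break
    p = fit.n_params
    n_test = test.n_persons
    return {
        "k": K,
        "train_loglik": fit.loglik,
        "train_bic": fit.bic,
        "train_aic": fit.aic,
        "holdout_loglik": test_ll,
        "holdout_bic": -2.0 * test_ll + p * np.log(n_test),
        "holdout_aic": -2.0 * test_ll + 2.0 * p,
        "n_params": p,
        "n_train": train.n_persons,
        "n_test": n_test,
        "converged": fit.converged,
        "unseen_category": unseen,
    }


def cross_validate(
    items: ItemResponseMatrix,
    k_range=range(1, 7),
    folds: FoldSpec | None = None,
    scheme: str = "kfold",
    sites: np.ndarray | None = None,
    n_folds: int = 10,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """CV table: one row per (K, fold) with train/held-out indices.

    Failed cells (non-convergence) are recorded with their reason rather
    than aborting the sweep.
    """
    if folds is None:
        folds = make_folds(items.n_persons, scheme, sites=sites, n_folds=n_folds, seed=seed)
    folds.check_partition()
    rows = []
    for K in k_range:
        for f in range(folds.n_folds):
            test_rows = folds.assignments == f
            train = items.subset(~test_rows)
            test = items.subset(test_rows)
            cell_seed = int(np.random.SeedSequence([seed, K, f]).generate_state(1)[0] % (2**31))
            try:
                cell = holdout_indices(
                    train, test, K,
                    n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=cell_seed,
                )
                cell.update(failed=False, reason="")
            except QolClassesError as e:
                cell = {
                    "k": K, "train_loglik": np.nan, "train_bic": np.nan,
                    "train_aic": np.nan, "holdout_loglik": np.nan,
                    "holdout_bic": np.nan, "holdout_aic": np.nan,
                    "n_params": np.nan, "n_train": train.n_persons,
                    "n_test": test.n_persons, "converged": False,
                    "unseen_category": False, "failed": True, "reason": str(e),
                }
            cell.update(scheme=folds.scheme, fold=folds.fold_names[f])
            rows.append(cell)
    cols = [
        "scheme", "k", "fold", "train_loglik", "train_bic", "train_aic",
        "holdout_loglik", "holdout_bic", "holdout_aic", "n_params", "n_train",
        "n_test", "converged", "unseen_category", "failed", "reason",
    ]
    return pd.DataFrame(rows)[cols]


#: indices where *larger* is better (negated before averaging/argmin)
_MAXIMISE = {"train_loglik", "holdout_loglik"}


def summarise_cv(cv: pd.DataFrame, index: str = "train_bic") -> pd.DataFrame:
    ok = cv[~cv["failed"]]
    sign = -1.0 if index in _MAXIMISE else 1.0
    out = ok.groupby("k")[index].agg(["mean", "std", "count"])
    out["score"] = sign * out["mean"]
    return out


@dataclass
class SelectionResult:
    selected_k: int
    index: str
    summary: pd.DataFrame
    elbow_k: int | None
    boundary_warning: bool
    excluded_k: list[int]


def select_k(
    cv: pd.DataFrame,
    k_range=None,
    index: str = "train_bic",
    elbow_fraction: float = 0.1,
) -> SelectionResult:
    """Pick K as the optimiser of the mean CV index (default: training BIC).

    Diagnostics: an elbow indicator (first K whose *next* improvement falls
    below ``elbow_fraction`` of the largest improvement) and a boundary
    warning when the minimum sits at the top of the range (suggesting the
    range should be widened).  K values whose cells all failed are excluded
    with a warning.
    """
    if k_range is not None:
        cv = cv[cv["k"].isin(list(k_range))]
    all_k = sorted(cv["k"].unique())
    summary = summarise_cv(cv, index)
    excluded = [k for k in all_k if k not in summary.index]
    if excluded:
        warnings.warn(
            f"K excluded (all folds failed): {excluded}", RuntimeWarning
        )
    if summary.empty:
        raise ConfigError("cv", "no successful cells in the CV table")
    means = summary["score"]
    selected = int(means.idxmin())
    boundary = selected == max(means.index) and means.is_monotonic_decreasing
    elbow = None
    ks = list(means.index)
    if len(ks) >= 3:
        imp = {ks[i]: means[ks[i - 1]] - means[ks[i]] for i in range(1, len(ks))}
        largest = max(imp.values())
        if largest > 0:
            for i in range(1, len(ks) - 1):
                if imp[ks[i + 1]] < elbow_fraction * largest:
                    elbow = ks[i]
                    break
            if elbow is None:
                elbow = ks[-1]
    return SelectionResult(selected, index, summary, elbow, boundary, excluded)


def kmeans_pca_sensitivity(
    items: ItemResponseMatrix,
    K: int,
    seed: int = 0,
    lca_labels: np.ndarray | None = None,
    var_explained: float = 0.8,
    n_init: int = 25,
):
    """k-means on principal components of centred/scaled item codes.

    Items are treated as numeric; components are retained up to
    ``var_explained`` cumulative variance; k-means uses ``n_init`` seeded
    restarts.  Returns ``(labels, ari, info)`` where ``ari`` is the adjusted
    Rand index against ``lca_labels`` (or None).
    """
    if K > items.n_persons:
        raise ConfigError("K", "more clusters than persons")
    if items.mask.any():
        raise ConfigError("items", "sensitivity analysis requires complete cases")
    x = StandardScaler().fit_transform(items.values.astype(float))
    pca = PCA(random_state=seed).fit(x)
    n_comp = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), var_explained) + 1)
    z = pca.transform(x)[:, :n_comp]
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(z)
    labels = km.labels_ + 1
    ari = None
    if lca_labels is not None:
        ari = float(adjusted_rand_score(np.asarray(lca_labels), labels))
    info = {"n_components": n_comp, "explained": float(np.cumsum(pca.explained_variance_ratio_)[n_comp - 1])}
    return labels, ari, info
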