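"""Multinomial latent class analysis fitted by EM with multiple restarts.

The model: person ``i`` belongs to one of ``K`` unobserved classes with
prevalence ``pi_k``; given the class, the ``J`` ordinal items are
independent, item ``j`` following a class-specific multinomial with
category probabilities ``rho[k, j, c]``.  The observed-data log-likelihood
is ``sum_i log sum_k pi_k prod_j rho[k, j, x_ij]``, computed in log space.

Fitting uses the standard EM iteration from random-responsibility starts,
keeping the best of ``n_restarts`` by final log-likelihood.  A smoothing
floor of 1e-6 is applied to the category probabilities after each M step
(with renormalisation) so that sampling zeros never drive the likelihood to
minus infinity; this is a small, documented deviation from raw maximum
likelihood.  Fitting requires complete cases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigError, ConvergenceError
from .responses import ItemResponseMatrix

_FLOOR = 1e-6


@dataclass
class LCAParameters:
    """Class prevalences and class-conditional item-category probabilities."""

    prevalences: np.ndarray  # (K,)
    item_probs: np.ndarray  # (K, J, Cmax), zero-padded past each item's C_j
    n_categories: np.ndarray  # (J,)

    def __post_init__(self):
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        self.item_probs = np.asarray(self.item_probs, dtype=float)
        self.n_categories = np.asarray(self.n_categories, dtype=int)

    @property
    def n_classes(self) -> int:
        return len(self.prevalences)

    @property
    def n_items(self) -> int:
        return len(self.n_categories)

    def validate(self, tol: float = 1e-10) -> None:
        if abs(self.prevalences.sum() - 1.0) > tol:
            raise ConfigError("prevalences", "must sum to 1")
        if np.any(self.prevalences < 0) or np.any(self.item_probs < 0):
            raise ConfigError("parameters", "negative probability")
        for j, C in enumerate(self.n_categories):
            if np.any(np.abs(self.item_probs[:, j, :C].sum(axis=1) - 1.0) > tol):
                raise ConfigError(f"item_probs[:, {j}]", "rows must sum to 1")
            if np.any(self.item_probs[:, j, C:] != 0):
                raise ConfigError(f"item_probs[:, {j}]", "mass beyond n_categories")

    def n_parameters(self) -> int:
        K = self.n_classes
        return (K - 1) + K * int((self.n_categories - 1).sum())

    def permuted(self, order) -> "LCAParameters":
        order = np.asarray(order)
        return LCAParameters(
            self.prevalences[order], self.item_probs[order], self.n_categories
        )


@dataclass
class FitResult:
    """One fitted LCA model with likelihood-based indices and provenance."""

    params: LCAParameters
    posteriors: np.ndarray  # (N, K)
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_obs: int
    seed: int | None = None
    n_restarts: int = 1
    best_restart: int = 0
    class_names: list[str] | None = None

    @property
    def n_params(self) -> int:
        return self.params.n_parameters()

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    def to_json(self, path) -> None:
        payload = {
            "prevalences": self.params.prevalences.tolist(),
            "item_probs": self.params.item_probs.tolist(),
            "n_categories": self.params.n_categories.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "best_restart": self.best_restart,
            "class_names": self.class_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _require_complete(items: ItemResponseMatrix) -> None:
    if items.mask.any():
        raise ConfigError(
            "items", "LCA requires complete cases; run complete_case_filter first"
        )


def _flat_layout(items: ItemResponseMatrix):
    """One-hot layout: item j occupies columns offset[j] .. offset[j]+C_j."""
    C = items.n_categories
    offsets = np.concatenate([[0], np.cumsum(C)[:-1]])
    idx = items.codes0() + offsets[None, :]
    onehot = np.zeros((items.n_persons, int(C.sum())))
    onehot[np.arange(items.n_persons)[:, None], idx] = 1.0
    return onehot, offsets


def _log_rho_flat(params: LCAParameters) -> np.ndarray:
    K = params.n_classes
    cols = []
    with np.errstate(divide="ignore"):
        for j, C in enumerate(params.n_categories):
            cols.append(np.log(params.item_probs[:, j, :C]))
    return np.concatenate(cols, axis=1).reshape(K, -1)


def _rho_from_flat(flat: np.ndarray, n_categories: np.ndarray) -> np.ndarray:
    K = flat.shape[0]
    Cmax = int(n_categories.max())
    rho = np.zeros((K, len(n_categories), Cmax))
    pos = 0
    for j, C in enumerate(n_categories):
        rho[:, j, :C] = flat[:, pos : pos + C]
        pos += C
    return rho


def _log_components(items, params, onehot=None) -> np.ndarray:
    if onehot is None:
        onehot, _ = _flat_layout(items)
    logrho = _log_rho_flat(params)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.prevalences)
    # -inf * 0 would give nan through matmul; substitute a sentinel that keeps
    # zero-probability components unambiguously below any legitimate value
    logrho = np.where(np.isneginf(logrho), -1e30, logrho)
    logpi = np.where(np.isneginf(logpi), -1e30, logpi)
    return onehot @ logrho.T + logpi[None, :]


def loglikelihood(items: ItemResponseMatrix, params: LCAParameters) -> float:
    """Observed-data log-likelihood; -inf (with a warning naming the first
    offending class/item/category) if an observed response pattern has zero
    probability under every class."""
    _require_complete(items)
    logB = _log_components(items, params)
    if logB.max(axis=1).min() < -1e29:
        _warn_zero_cells(items, params)
        return float("-inf")
    return float(logsumexp(logB, axis=1).sum())


def _warn_zero_cells(items, params):
    codes = items.codes0()
    for j in range(items.n_items):
        observed = np.unique(codes[:, j])
        for k in range(params.n_classes):
            zero = observed[params.item_probs[k, j, observed] == 0]
            if zero.size:
                warnings.warn(
                    f"zero probability for observed cell (class {k + 1}, "
                    f"item {items.item_ids[j]}, category {int(zero[0]) + 1})",
                    RuntimeWarning,
                )
                return


def posterior(items: ItemResponseMatrix, params: LCAParameters):
    """E step: responsibilities gamma (N, K) and the log-likelihood."""
    _require_complete(items)
    logB = _log_components(items, params)
    norm = logsumexp(logB, axis=1, keepdims=True)
    gamma = np.exp(logB - norm)
    return gamma, float(norm.sum())


def _m_step(
    onehot: np.ndarray, gamma: np.ndarray, n_categories: np.ndarray, floor: float
) -> LCAParameters:
    n = gamma.shape[0]
    Nk = gamma.sum(axis=0)
    empty = Nk < 1e-8
    if empty.any():
        warnings.warn(
            f"class collapse: class(es) {np.where(empty)[0] + 1} have "
            "negligible posterior mass",
            RuntimeWarning,
        )
    pi = Nk / n
    counts = gamma.T @ onehot  # (K, sumC)
    flat = counts / np.maximum(Nk, 1e-12)[:, None]
    if floor > 0:
        flat = np.maximum(flat, floor)
    pos = 0
    for C in n_categories:
        block = flat[:, pos : pos + C]
        flat[:, pos : pos + C] = block / block.sum(axis=1, keepdims=True)
        pos += C
    return LCAParameters(pi, _rho_from_flat(flat, np.asarray(n_categories)), n_categories)


def em_step(
    items: ItemResponseMatrix, params: LCAParameters, floor: float = _FLOOR
):
    """One EM iteration: returns (updated params, responsibilities).

    The responsibilities are those of the *input* parameters (the E step);
    the log-likelihood never decreases across the update apart from
    perturbations at the smoothing-floor scale.
    """
    onehot, _ = _flat_layout(items)
    gamma, _ = posterior(items, params)
    new = _m_step(onehot, gamma, items.n_categories, floor)
    return new, gamma


def fit_em(
    items: ItemResponseMatrix,
    K: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    floor: float = _FLOOR,
) -> FitResult:
    """Best-of-restarts EM fit of a K-class model.

    Each restart initialises from Dirichlet(1) random responsibilities.
    Convergence: relative log-likelihood change below ``tol``.  Deterministic
    given ``seed``.  Raises :class:`ConvergenceError` (carrying the best
    trace) if no restart converges.
    """
    _require_complete(items)
    if K < 1:
        raise ConfigError("K", "must be at least 1")
    onehot, _ = _flat_layout(items)
    nC = items.n_categories
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts if K > 1 else 1):
        gamma0 = rng.dirichlet(np.ones(K), size=items.n_persons)
        if K == 1:
            gamma0 = np.ones((items.n_persons, 1))
        params = _m_step(onehot, gamma0, nC, floor)
        trace = []
        converged = False
        prev = np.nan
        for _ in range(max_iter):
            logB = _log_components(items, params, onehot)
            norm = logsumexp(logB, axis=1, keepdims=True)
            ll = float(norm.sum())
            trace.append(ll)
            if (
                np.isfinite(ll)
                and np.isfinite(prev)
                and abs(ll - prev) <= tol * (abs(prev) + 1e-12)
            ):
                converged = True
                break
            prev = ll
            gamma = np.exp(logB - norm)
            params = _m_step(onehot, gamma, nC, floor)
        gamma, ll = posterior(items, params)
        candidate = FitResult(
            params=params,
            posteriors=gamma,
            loglik=ll,
            loglik_trace=np.array(trace),
            converged=converged,
            n_obs=items.n_persons,
            seed=seed,
            n_restarts=n_restarts,
            best_restart=r,
        )
        if best is None or (candidate.converged and not best.converged) or (
            candidate.converged == best.converged and candidate.loglik > best.loglik
        ):
            best = candidate
    assert best is not None
    if not best.converged:
        raise ConvergenceError(
            f"no restart converged within {max_iter} iterations",
            last_iterate=best,
        )
    return best


def classify_modal(posteriors: np.ndarray) -> np.ndarray:
    """Modal class per person (1-based); ties break to the lowest index."""
    return np.argmax(posteriors, axis=1) + 1


DEFAULT_CLASS_NAMES = ["no_mild", "moderate_psy", "moderate_phy", "severe"]


def rank_classes_by_utility(
    fit: FitResult,
    utilities: np.ndarray,
    items: ItemResponseMatrix | None = None,
    pain_scores: np.ndarray | None = None,
) -> FitResult:
    """Permute classes into the canonical severity order.

    Class 1 gets the highest modal-member mean utility and class K the
    lowest.  For four-class fits the middle pair is ordered by mean
    standardised pain score: the class with *less* pain impairment (higher
    pain score) comes second ("moderate-psy"), the one with worse pain third
    ("moderate-phy").  ``pain_scores`` may be supplied directly or computed
    from ``items``.  Invariant under any relabelling of the input fit.
    """
    K = fit.params.n_classes
    if K < 2:
        return replace(fit, class_names=["class_1"])
    utilities = np.asarray(utilities, dtype=float)
    labels = classify_modal(fit.posteriors)
    means = np.full(K, -np.inf)
    for k in range(K):
        member = labels == k + 1
        if member.any():
            means[k] = np.nanmean(utilities[member])
    order = np.argsort(-means, kind="stable")
    if K == 4:
        if pain_scores is None and items is not None:
            from .scoring import standardise_dimension

            pain_scores = standardise_dimension(items, "pain")
        if pain_scores is not None:
            pain_scores = np.asarray(pain_scores, dtype=float)
            pain_means = np.full(K, np.nan)
            for k in range(K):
                member = labels == k + 1
                if member.any():
                    pain_means[k] = np.nanmean(pain_scores[member])
            mid = list(order[1:3])
            mid.sort(key=lambda k: -pain_means[k])
            order[1:3] = mid
    names = (
        list(DEFAULT_CLASS_NAMES)
        if K == 4
        else [f"class_{k + 1}" for k in range(K)]
    )
    return replace(
        fit,
        params=fit.params.permuted(order),
        posteriors=fit.posteriors[:, order],
        class_names=names,
    )
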