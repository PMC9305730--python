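"""3-step class validation: multinomial logistic regression of assigned
class on covariates, Rubin pooling over imputations and RRR reporting.

The regression is fitted by Newton-Raphson on the multinomial logit with an
explicit reference outcome class; Wald covariances come from the inverse
observed information.  If separation is detected (diverging coefficients or
non-convergence) the fit falls back to a small ridge penalty (1e-4, on
non-intercept terms) with a warning — a documented approximation whose
covariance is the penalised information inverse.

Relative risk ratios (RRR) are exponentiated coefficients: the multiplier
on the risk of landing in an outcome class relative to the reference class
for a one-unit (or one-s.d., for standardised inputs) change in a
predictor.  Two nested models mirror the usual split between
administrative/clinician information and self-reported symptoms:

* model 1 — demographics, diagnosis, clinical staging;
* model 2 — model 1 plus PHQ-9, GAD-7, SIQ-JR and PSQI totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.stats import norm, t as student_t

from .covariates import CLINICAL_VARS, CovariateTable, standardise_covariates
from .errors import ConfigError, EstimationError, RankDeficiencyError
from .imputation import ImputationSet

MODEL1_PREDICTORS = (
    "age", "female", "lgbtiq", "neet", "region", "diagnosis", "clinical_stage",
)
MODEL2_PREDICTORS = MODEL1_PREDICTORS + CLINICAL_VARS


@dataclass
class MultinomialFit:
    """ML (or ridge-fallback) multinomial logit fit.

    ``coef`` has one row per non-reference class, in ``classes[1:]`` order
    (``classes[0]`` is the reference); ``cov`` covers the flattened
    coefficient vector, class-major.
    """

    coef: np.ndarray  # (K-1, p)
    cov: np.ndarray  # ((K-1) p, (K-1) p)
    classes: list
    columns: list[str]
    converged: bool
    ridge: float
    loglik: float
    n_obs: int

    def coef_vector(self) -> np.ndarray:
        return self.coef.ravel()

    def variance_vector(self) -> np.ndarray:
        return np.diag(self.cov).copy()


def _check_rank(x: np.ndarray, columns: list[str]) -> None:
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        aliased = [columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(aliased)


def _nll_grad_hess(beta, x, y_onehot, ridge):
    n, p = x.shape
    K = y_onehot.shape[1]
    eta = np.hstack([np.zeros((n, 1)), x @ beta.T])  # reference first
    eta -= eta.max(axis=1, keepdims=True)
    expe = np.exp(eta)
    prob = expe / expe.sum(axis=1, keepdims=True)
    ll = float(np.sum(y_onehot * np.log(np.maximum(prob, 1e-300))))
    pen = 0.5 * ridge * float((beta[:, 1:] ** 2).sum()) if ridge else 0.0
    grad = np.empty_like(beta)
    for k in range(1, K):
        grad[k - 1] = x.T @ (y_onehot[:, k] - prob[:, k])
    if ridge:
        grad[:, 1:] -= ridge * beta[:, 1:]
    dim = (K - 1) * p
    hess = np.empty((dim, dim))
    for k in range(1, K):
        for l in range(1, K):
            w = prob[:, k] * ((k == l) - prob[:, l])
            block = x.T @ (x * w[:, None])
            hess[(k - 1) * p : k * p, (l - 1) * p : l * p] = block
    if ridge:
        mask = np.tile(np.r_[0.0, np.ones(p - 1)], K - 1)
        hess[np.diag_indices(dim)] += ridge * mask
    return ll - pen, grad, hess


def fit_multinomial(
    labels: np.ndarray,
    design: pd.DataFrame,
    reference,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
    _fallback: bool = True,
) -> MultinomialFit:
    """Maximum-likelihood multinomial logit with the stated reference class.

    ``design`` must include any intercept column explicitly (see
    :func:`build_design`).  Raises :class:`RankDeficiencyError` for aliased
    columns and :class:`EstimationError` if even the ridge fallback fails.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels), key=str)
    if reference not in classes:
        raise ConfigError("reference", f"{reference!r} is not an observed class")
    classes = [reference] + [c for c in classes if c != reference]
    if len(classes) < 2:
        raise ConfigError("labels", "need at least 2 classes")
    x = design.to_numpy(dtype=float)
    columns = list(design.columns)
    _check_rank(x, columns)
    n, p = x.shape
    K = len(classes)
    y_onehot = np.zeros((n, K))
    for k, c in enumerate(classes):
        y_onehot[labels == c, k] = 1.0
    if (y_onehot[:, 0] == 0).all():
        raise ConfigError("reference", "reference class is empty")

    beta = np.zeros((K - 1, p))
    ll_prev = -np.inf
    converged = False
    diverged = False
    for _ in range(max_iter):
        ll, grad, hess = _nll_grad_hess(beta, x, y_onehot, ridge)
        try:
            step = np.linalg.solve(hess, grad.ravel()).reshape(K - 1, p)
        except np.linalg.LinAlgError:
            diverged = True
            break
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _nll_grad_hess(cand, x, y_onehot, ridge)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.abs(beta).max() > 30.0:
            diverged = True
            break
        if abs(ll_new - ll_prev) < tol * (abs(ll_prev) + 1.0) and np.abs(grad).max() < 1e-6:
            converged = True
            break
        ll_prev = ll_new
    if (diverged or not converged) and ridge == 0.0 and _fallback:
        warnings.warn(
            "possible separation in multinomial fit; refitting with ridge 1e-4",
            RuntimeWarning,
        )
        return fit_multinomial(
            labels, design, reference, ridge=1e-4, max_iter=max_iter, tol=tol
        )
    if not converged:
        raise EstimationError("multinomial fit did not converge", last_iterate=beta)
    ll, _, hess = _nll_grad_hess(beta, x, y_onehot, ridge)
    cov = np.linalg.inv(hess)
    return MultinomialFit(
        beta, cov, classes, columns, converged, ridge, ll, n
    )


def predict_proba(fit: MultinomialFit, design: pd.DataFrame) -> np.ndarray:
    """Class probabilities in ``fit.classes`` order."""
    x = design[fit.columns].to_numpy(dtype=float)
    eta = np.hstack([np.zeros((len(x), 1)), x @ fit.coef.T])
    eta -= eta.max(axis=1, keepdims=True)
    expe = np.exp(eta)
    return expe / expe.sum(axis=1, keepdims=True)


@dataclass
class PooledEstimates:
    """Rubin's-rules combination of per-imputation fits."""

    estimate: np.ndarray
    total_variance: np.ndarray
    within: np.ndarray
    between: np.ndarray
    df: np.ndarray
    m: int


def pool_rubin(estimates: list[np.ndarray], variances: list[np.ndarray]) -> PooledEstimates:
    """Pool per-imputation estimates and variances.

    Pooled estimate = mean; total variance ``T = W + (1 + 1/m) B`` with
    within-variance ``W`` the mean variance and between-variance ``B`` the
    sample variance of the estimates.  Degrees of freedom follow Rubin
    (infinite when ``B = 0``, recovering single-fit inference).
    """
    if len(estimates) < 2:
        raise ConfigError("fits", "need at least 2 imputation fits to pool")
    shapes = {np.shape(e) for e in estimates} | {np.shape(v) for v in variances}
    if len(shapes) != 1:
        raise ConfigError("fits", "non-conformable estimates/variances")
    q = np.stack([np.asarray(e, dtype=float) for e in estimates])
    w = np.stack([np.asarray(v, dtype=float) for v in variances])
    m = q.shape[0]
    qbar = q.mean(axis=0)
    wbar = w.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    total = wbar + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", over="ignore"):
        r = (1.0 + 1.0 / m) * b / wbar
        df = np.where(b > 0, (m - 1) * (1.0 + 1.0 / np.maximum(r, 1e-300)) ** 2, np.inf)
    return PooledEstimates(qbar, total, wbar, b, df, m)


def _ci(pooled: PooledEstimates, level: float = 0.95):
    alpha = 1.0 - level
    crit = np.where(
        np.isinf(pooled.df),
        norm.ppf(1 - alpha / 2),
        student_t.ppf(1 - alpha / 2, np.where(np.isinf(pooled.df), 1.0, pooled.df)),
    )
    half = crit * np.sqrt(pooled.total_variance)
    return pooled.estimate - half, pooled.estimate + half


def build_design(
    table: CovariateTable,
    predictors: tuple,
    categorical_refs: dict | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept; dummies drop the reference level.

    Default references: first declared level of each categorical variable
    (for ``clinical_stage`` that is the mildest, "0-1a"); binary variables
    enter as 0/1; ``region`` enters as a regional dummy (metropolitan
    reference).
    """
    categorical_refs = categorical_refs or {}
    cols = {"intercept": np.ones(len(table.data))}
    for v in predictors:
        if v in table.continuous or v in table.binary:
            cols[v] = table.data[v].to_numpy(dtype=float)
        elif v in table.categorical:
            levels = list(table.categorical[v])
            ref = categorical_refs.get(v, levels[0])
            for level in levels:
                if level == ref:
                    continue
                cols[f"{v}[{level}]"] = (
                    (table.data[v] == level).to_numpy(dtype=float)
                )
        else:
            raise ConfigError(f"predictors.{v}", "not in covariate table")
    return pd.DataFrame(cols, index=table.data.index)


@dataclass
class RRRReport:
    """Pooled RRR tables and in-sample prediction accuracy per model."""

    tables: dict[str, pd.DataFrame]  # model tag -> RRR table
    accuracy: dict[str, float]
    reference_class: object


def rrr_report(
    labels: np.ndarray,
    imputations: ImputationSet,
    reference_class,
    models: dict[str, tuple] | None = None,
    class_names: dict | None = None,
    standardise: tuple = CLINICAL_VARS,
    sds: dict | None = None,
    categorical_refs: dict | None = None,
    level: float = 0.95,
) -> RRRReport:
    """Fit each model on every imputed table, pool, and report RRRs with CIs.

    Clinical symptom totals are standardised per imputed copy using either
    supplied fixed s.d.s or the observed-case statistics of the first
    table (shared across copies, so coefficients stay comparable).
    Prediction accuracy is the in-sample share of persons whose
    highest-probability class matches their assigned class, averaged over
    imputations.
    """
    labels = np.asarray(labels)
    if models is None:
        models = {"model1": MODEL1_PREDICTORS, "model2": MODEL2_PREDICTORS}
    # shared standardisation statistics from the original (pre-imputation) data
    base = imputations.tables[0]
    stats_means, stats_sds = {}, {}
    for v in standardise:
        if v in base.data.columns and v not in base.standardisation:
            col = base.data[v].astype(float)
            stats_means[v] = float(col.mean())
            stats_sds[v] = float(sds[v]) if sds and v in sds else float(col.std(ddof=1))

    tables, accuracy = {}, {}
    for tag, predictors in models.items():
        ests, vars_, fits = [], [], []
        for tab in imputations.tables:
            std_tab = standardise_covariates(
                tab, variables=tuple(stats_sds), sds=stats_sds, means=stats_means
            )
            design = build_design(std_tab, predictors, categorical_refs)
            fit = fit_multinomial(labels, design, reference_class)
            ests.append(fit.coef_vector())
            vars_.append(fit.variance_vector())
            fits.append((fit, design))
        pooled = pool_rubin(ests, vars_)
        lo, hi = _ci(pooled, level)
        fit0 = fits[0][0]
        p = len(fit0.columns)
        rows = []
        for ci_, cls in enumerate(fit0.classes[1:]):
            name = class_names.get(cls, cls) if class_names else cls
            for pj, predictor in enumerate(fit0.columns):
                flat = ci_ * p + pj
                rows.append(
                    {
                        "model": tag,
                        "class": name,
                        "predictor": predictor,
                        "coef": pooled.estimate[flat],
                        "rrr": np.exp(pooled.estimate[flat]),
                        "ci_low": np.exp(lo[flat]),
                        "ci_high": np.exp(hi[flat]),
                        "se": np.sqrt(pooled.total_variance[flat]),
                    }
                )
        tables[tag] = pd.DataFrame(rows)
        accs = []
        for fit, design in fits:
            prob = predict_proba(fit, design)
            modal = np.array(fit.classes)[prob.argmax(axis=1)]
            accs.append(float((modal == labels).mean()))
        accuracy[tag] = float(np.mean(accs))
    return RRRReport(tables, accuracy, reference_class)
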