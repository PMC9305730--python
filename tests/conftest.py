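"""Shared fixtures: small item sets, simulated LCA cohorts, independent
oracles and the packaged paper-profile cohort (generated once per session)."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom

from qolclasses.lca import fit_em, rank_classes_by_utility
from qolclasses.metadata import ItemMetadata, aqol_metadata
from qolclasses.responses import ItemResponseMatrix, complete_case_filter
from qolclasses.scoring import score_cohort, standardise_dimension
from qolclasses.synthetic import generate_cohort, load_profile


def make_items(values, metadata=None, mask=None, n_categories=5):
    """ItemResponseMatrix from a plain integer array (helper for tiny cases)."""
    values = np.asarray(values)
    if metadata is None:
        metadata = aqol_metadata(n_categories)[: values.shape[1]]
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return ItemResponseMatrix(values, mask, metadata)


def binomial_profiles(severities, n_categories=5):
    """Class-conditional item profiles from binomial severity parameters.

    ``severities`` has shape (K, J); returns (K, J, C) category probabilities.
    """
    severities = np.asarray(severities, dtype=float)
    K, J = severities.shape
    rho = np.zeros((K, J, n_categories))
    for k in range(K):
        for j in range(J):
            rho[k, j] = binom.pmf(np.arange(n_categories), n_categories - 1, severities[k, j])
            rho[k, j] /= rho[k, j].sum()
    return rho


def simulate_lca(prevalences, severities, n, seed, metadata=None, n_categories=5):
    """Draw a complete-case LCA cohort with known truth.

    Returns (items, true_class 1-based, rho, prevalences).
    """
    prevalences = np.asarray(prevalences, dtype=float)
    rho = binomial_profiles(severities, n_categories)
    K, J, C = rho.shape
    rng = np.random.default_rng(seed)
    cls = rng.choice(K, size=n, p=prevalences)
    cdf = np.cumsum(rho, axis=2)[cls]
    u = rng.random((n, J, 1))
    values = 1 + (u > cdf[:, :, :-1]).sum(axis=2)
    items = make_items(values, metadata=metadata, n_categories=n_categories)
    return items, cls + 1, rho, prevalences


def brute_force_loglik(values, pi, rho):
    """LCA log-likelihood by direct enumeration (naive double loop)."""
    total = 0.0
    for row in values:
        mix = 0.0
        for k in range(len(pi)):
            term = pi[k]
            for j, code in enumerate(row):
                term *= rho[k][j][code - 1]
            mix += term
        total += math.log(mix)
    return total


def align_classes(est_rho, true_rho):
    """Permutation of estimated classes minimising total |rho| error."""
    K = est_rho.shape[0]
    best, best_err = None, np.inf
    for perm in itertools.permutations(range(K)):
        err = np.abs(est_rho[list(perm)] - true_rho).sum()
        if err < best_err:
            best, best_err = perm, err
    return list(best)


#: well-separated four-class severity patterns over 20 items
FOUR_CLASS_SEVERITIES = np.array(
    [
        [0.08] * 20,
        [0.15] * 8 + [0.55] * 7 + [0.20] * 5,
        [0.25] * 12 + [0.25] * 3 + [0.70] * 5,
        [0.65] * 20,
    ]
)


@pytest.fixture(scope="session")
def paper_profile():
    return load_profile("aqol_paper_profile")


@pytest.fixture(scope="session")
def paper_cohort(paper_profile):
    """Seeded paper-profile cohort with scores and the ranked 4-class fit."""
    cohort = generate_cohort(paper_profile, seed=1)
    complete, report = complete_case_filter(cohort.items)
    scores = score_cohort(complete, paper_profile.utility)
    fit = fit_em(complete, 4, n_restarts=20, seed=1)
    fit = rank_classes_by_utility(
        fit,
        scores.utility.to_numpy(),
        pain_scores=standardise_dimension(complete, "pain"),
    )
    keep = cohort.items.complete_rows()
    cov = cohort.covariates.copy()
    cov.data = cov.data.loc[keep].reset_index(drop=True)
    return {
        "cohort": cohort,
        "complete": complete,
        "report": report,
        "scores": scores,
        "fit": fit,
        "covariates_cc": cov,
        "sites_cc": cohort.site[keep],
        "true_class_cc": cohort.true_class[keep],
    }
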