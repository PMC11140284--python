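"""Shared fixtures: one paper-parameterised synthetic cohort per session.

The heavy objects (n=2235 cohort, its two-class EM fit) are session-scoped
so that recovery, screening and regression tests reuse a single draw.
"""

import numpy as np
import pytest

from vistraj import growth, mixture, synth


@pytest.fixture(scope="session")
def design():
    return growth.GrowthDesign()


@pytest.fixture(scope="session")
def paper_config():
    return synth.paper_like(seed=1)


@pytest.fixture(scope="session")
def paper_cohort(paper_config):
    """Full paper-like cohort: trajectories, predictors, outcomes."""
    return synth.simulate_cohort(paper_config)


@pytest.fixture(scope="session")
def paper_vision(paper_cohort):
    return paper_cohort.vision_matrix()


@pytest.fixture(scope="session")
def two_class_fit(paper_vision):
    """Multi-start EM two-class solution on the session cohort."""
    return mixture.em_fit(paper_vision, k=2, n_starts=10, seed=2)


@pytest.fixture(scope="session")
def one_class_fit(paper_vision):
    return growth.fit_lgcm(paper_vision)


@pytest.fixture(scope="session")
def true_labels(paper_cohort):
    return paper_cohort.data["true_class"].to_numpy()


def ols_se(config, class_index=None):
    """Monte-Carlo standard errors of growth-factor mean estimates.

    Per-subject OLS (intercept, slope) sampling variances are
    psi_jj + theta * [(L'L)^-1]_jj; dividing by the (expected) class size
    gives a slightly generous SE for the ML estimate of the class mean.
    """
    t = np.asarray(config.time_scores)
    lam = np.column_stack([np.ones_like(t), t])
    c = np.linalg.inv(lam.T @ lam)
    theta = float(np.mean(config.theta))
    psi = config.psi
    var = np.array([psi[0, 0] + theta * c[0, 0], psi[1, 1] + theta * c[1, 1]])
    if class_index is None:
        n = config.n_subjects
    else:
        n = config.n_subjects * config.class_proportions[class_index]
    return np.sqrt(var / n)
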