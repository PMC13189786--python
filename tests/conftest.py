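"""Shared fixtures: the study-emulation cohort and its two-class fit.

Session-scoped because generation and EM fitting are reused by many tests;
everything is seeded, so sharing does not couple test outcomes.
"""

import numpy as np
import pytest

import sonopattern as sp
from sonopattern.firth import build_design
from sonopattern.pipeline import _anchor_pattern_b


@pytest.fixture(scope="session")
def emul_config():
    return sp.paper_emulation_config()


@pytest.fixture(scope="session")
def emul_cohort(emul_config):
    """N=509 cohort with 22 planted non-responders (2 of them MP-assessed)."""
    return sp.generate_cohort(emul_config, seed=1, exact_n_events=22)


@pytest.fixture(scope="session")
def lca2_fit(emul_cohort):
    return sp.fit_lca(emul_cohort.features, 2, n_starts=50, seed=0)


@pytest.fixture(scope="session")
def emul_design(emul_cohort, lca2_fit):
    """(X, y, pattern_b) regression inputs from the fitted two-class solution."""
    pattern_b, _ = _anchor_pattern_b(
        lca2_fit.modal_assignment, emul_cohort, "angular_margins", lca2_fit
    )
    X = build_design(emul_cohort.data, pattern_b)
    return X, emul_cohort.outcome, pattern_b


def grid_loglik_2x2(x: np.ndarray, axes: list[np.ndarray]) -> float:
    """Vectorized dense grid search over (pi, rho) for 2 binary features, C=2.

    axes = [pi, r(c1,f1), r(c1,f2), r(c2,f1), r(c2,f2)] grids, where r(c,f)
    is P(feature f = 1 | class c). Returns the best grid log-likelihood.
    """
    pi, r11, r12, r21, r22 = [
        g.reshape([len(g) if j == i else 1 for j in range(5)]) for i, g in enumerate(axes)
    ]
    ll = 0.0
    pats, counts = np.unique(x, axis=0, return_counts=True)
    for (a, b), cnt in zip(pats, counts):
        p1 = (r11**a * (1 - r11) ** (1 - a)) * (r12**b * (1 - r12) ** (1 - b))
        p2 = (r21**a * (1 - r21) ** (1 - a)) * (r22**b * (1 - r22) ** (1 - b))
        ll = ll + cnt * np.log(pi * p1 + (1 - pi) * p2)
    return float(ll.max())


def loglik_lca(x: np.ndarray, pi: np.ndarray, rho_per_feature: list[np.ndarray]) -> float:
    """Independent log-likelihood evaluator used by the EM oracles."""
    n = x.shape[0]
    like = np.zeros((n, len(pi)))
    for c in range(len(pi)):
        lp = np.zeros(n)
        for j, m in enumerate(rho_per_feature):
            lp += np.log(np.maximum(m[c][x[:, j]], 1e-300))
        like[:, c] = np.log(max(pi[c], 1e-300)) + lp
    mx = like.max(axis=1, keepdims=True)
    return float((mx.ravel() + np.log(np.exp(like - mx).sum(axis=1))).sum())
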