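"""Firth-penalized logistic regression: oracles, invariances, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import sonopattern as sp
from sonopattern.firth import FirthFit, firth_fit, profile_ci, vif, wald_summary


def _two_by_two(n11, n10, n21, n20):
    """(x, y) for a 2x2 table: exposure 0 -> (n11 events, n10 non), exposure 1."""
    x = np.repeat([0.0, 1.0], [n11 + n10, n21 + n20])[:, None]
    y = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n21), np.zeros(n20)])
    return x, y


def test_firth_equals_half_cell_correction_on_2x2():
    # published two-class counts 6/251 vs 16/236: Firth on the saturated 2x2
    # equals the add-1/2-per-cell odds ratio (16.5*251.5)/(6.5*236.5)
    x, y = _two_by_two(6, 251, 16, 236)
    fit = firth_fit(x, y)
    assert fit.converged
    expected = (16.5 * 251.5) / (6.5 * 236.5)
    assert np.exp(fit.beta[1]) == pytest.approx(expected, abs=1e-3)


def test_firth_matches_dense_grid_on_penalized_likelihood():
    x, y = _two_by_two(6, 251, 16, 236)
    fit = firth_fit(x, y)
    X = np.column_stack([np.ones(len(y)), x])

    def pen_ll(b0, b1):
        eta = X @ np.array([b0, b1])
        p = 1 / (1 + np.exp(-eta))
        w = p * (1 - p)
        info = X.T @ (X * w[:, None])
        return np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * np.linalg.slogdet(info)[1]

    # iteratively refined dense grid around the fit
    b0s = np.linspace(fit.beta[0] - 0.5, fit.beta[0] + 0.5, 81)
    b1s = np.linspace(fit.beta[1] - 0.5, fit.beta[1] + 0.5, 81)
    for _ in range(3):
        vals = np.array([[pen_ll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        best = (b0s[i], b1s[j])
        w0 = b0s[1] - b0s[0]
        w1 = b1s[1] - b1s[0]
        b0s = np.linspace(best[0] - w0, best[0] + w0, 81)
        b1s = np.linspace(best[1] - w1, best[1] + w1, 81)
    assert fit.beta[0] == pytest.approx(best[0], abs=1e-4)
    assert fit.beta[1] == pytest.approx(best[1], abs=1e-4)


def test_zero_effect_under_symmetry():
    x, y = _two_by_two(10, 40, 10, 40)
    fit = firth_fit(x, y)
    assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)


def test_finite_estimates_under_complete_separation():
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)[:, None]
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    fit = firth_fit(x, y)
    assert fit.converged
    assert np.all(np.isfinite(fit.beta))
    tab = wald_summary(fit)
    assert np.all(np.isfinite(tab[["ci_low", "ci_high"]].to_numpy()))
    assert np.all(tab["ci_low"] <= tab["ci_high"])


def test_outcome_flip_flips_coefficient_signs():
    x, y = _two_by_two(6, 251, 16, 236)
    a = firth_fit(x, y)
    b = firth_fit(x, 1 - y)
    assert a.beta[1] == pytest.approx(-b.beta[1], abs=1e-6)


def test_firth_shrinks_toward_zero_relative_to_ml():
    # shrinkage relative to ML on 2x2 tables with a clearly non-null effect
    # (for near-null effects the half-cell correction can nudge either way)
    rng = np.random.default_rng(8)
    checked = 0
    while checked < 25:
        cells = rng.integers(1, 40, size=4)
        n11, n10, n21, n20 = cells
        beta_ml = np.log((n21 * n10) / (n11 * n20))  # saturated-2x2 MLE
        if abs(beta_ml) < 0.5:
            continue
        x, y = _two_by_two(*cells)
        fit = firth_fit(x, y)
        assert abs(fit.beta[1]) <= abs(beta_ml) + 1e-9, cells
        checked += 1


def test_penalized_loglik_monotone_path(emul_design):
    X, y, _ = emul_design
    fit = firth_fit(X, y)
    assert fit.converged
    assert np.all(np.diff(fit.loglik_path) >= -1e-10)


def test_wald_summary_arithmetic():
    fit = FirthFit(
        names=["intercept", "x"],
        beta=np.array([0.0, 0.0]),
        cov=np.diag([1.0, 1.0]),
        loglik_penalized=0.0,
        converged=True,
        n_iter=1,
        n_obs=10,
        n_events=5,
    )
    tab = wald_summary(fit).iloc[0]
    assert tab["or"] == pytest.approx(1.0)
    assert tab["ci_low"] == pytest.approx(np.exp(-1.959964), abs=1e-4)  # ~0.14
    assert tab["ci_high"] == pytest.approx(np.exp(1.959964), abs=1e-4)  # ~7.10
    # published effect: OR 2.51 with CI (1.05, 5.99) is Wald-consistent with p < 0.05
    se = (np.log(5.99) - np.log(1.05)) / (2 * 1.959964)
    fit2 = FirthFit(
        names=["intercept", "pattern_b"],
        beta=np.array([0.0, np.log(2.51)]),
        cov=np.diag([1.0, se**2]),
        loglik_penalized=0.0,
        converged=True,
        n_iter=1,
        n_obs=509,
        n_events=22,
    )
    row = wald_summary(fit2).iloc[0]
    assert row["ci_low"] == pytest.approx(1.05, abs=0.01)
    assert row["ci_high"] == pytest.approx(5.99, abs=0.06)
    assert row["p"] < 0.05


def test_or_sampling_distribution_covers_true_effect(emul_config):
    # pattern log-OR ln(2.5): the spread of OR-hats over seeds brackets 2.5
    ors = []
    for s in range(50):
        coh = sp.generate_cohort(emul_config, seed=300 + s)
        if coh.n_events < 3:
            continue
        pattern_b = (coh.data["true_class"] == 1).to_numpy().astype(float)
        X = sp.build_design(coh.data, pattern_b)
        fit = firth_fit(X, coh.outcome)
        ors.append(np.exp(fit.beta[fit.names.index("pattern_b")]))
    lo, hi = np.quantile(ors, [0.025, 0.975])
    assert lo <= 2.5 <= hi


def test_profile_ci_brackets_wald(emul_design):
    X, y, _ = emul_design
    j = list(X.columns).index("pattern_b")
    lo, hi = profile_ci(X, y, j)
    fit = firth_fit(X, y)
    assert lo < fit.beta[j + 1] < hi


def test_vif_identities():
    rng = np.random.default_rng(3)
    # mutually orthogonal, mean-zero columns -> all VIF = 1
    m = rng.normal(size=(50, 3))
    q, _ = np.linalg.qr(m - m.mean(axis=0))
    v = vif(pd.DataFrame(q, columns=list("abc")))
    assert np.allclose(v.to_numpy(), 1.0, atol=1e-8)
    # exact sample correlation 0.6 -> VIF = 1/(1-0.36) = 1.5625
    u1, u2 = q[:, 0], q[:, 1]
    x1 = u1
    x2 = 0.6 * u1 + np.sqrt(1 - 0.36) * u2
    v2 = vif(pd.DataFrame({"x1": x1, "x2": x2, "z": q[:, 2]}))
    assert v2["x1"] == pytest.approx(1.5625, abs=1e-8)
    assert v2["x2"] == pytest.approx(1.5625, abs=1e-8)
    # duplicated column -> infinite VIF
    v3 = vif(pd.DataFrame({"a": x1, "b": x1}))
    assert np.isinf(v3["a"]) and np.isinf(v3["b"])


def test_rank_deficient_design_names_aliased_column(emul_design):
    X, y, _ = emul_design
    X2 = X.copy()
    X2["dup"] = X2["pattern_b"]
    with pytest.raises(ValueError, match="aliased"):
        firth_fit(X2, y)


def test_vif_below_collinearity_threshold_on_emulation_design(emul_design):
    X, _, _ = emul_design
    assert vif(X).max() < 2.5
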