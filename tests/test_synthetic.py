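"""Generator contracts: configured probabilities are what the cohorts deliver."""

import numpy as np
import pytest

import sonopattern as sp
from sonopattern.synthetic import load_config, save_config


def test_emulation_config_matches_study_conditions(emul_config):
    cfg = emul_config
    assert cfg.n_patients == 509
    assert cfg.class_probs == (0.505, 0.495)
    # 18 binary + 5 three-level features -> 28 free category parameters
    K = cfg.dictionary.n_levels
    assert len(K) == 23
    assert int(np.sum(K - 1)) == 28
    assert cfg.item_probs["irregular_shape"][0, 1] == 1.0  # class A anchored at 100%
    assert cfg.mp_fraction == pytest.approx(48 / 509)
    assert np.isclose(np.exp(cfg.pattern_log_or), 2.5)


def test_same_seed_same_cohort(emul_config):
    a = sp.generate_cohort(emul_config, seed=42)
    b = sp.generate_cohort(emul_config, seed=42)
    assert a.data.equals(b.data)
    c = sp.generate_cohort(emul_config, seed=43)
    assert not c.data.equals(a.data)


@pytest.fixture(scope="module")
def big_cohort(emul_config):
    big = sp.paper_emulation_config(n_patients=50_000)
    return big, sp.generate_cohort(big, seed=7)


def test_feature_frequencies_converge_to_item_probs(big_cohort):
    cfg, coh = big_cohort
    cls = coh.data["true_class"].to_numpy()
    shares = np.bincount(cls) / len(cls)
    assert np.allclose(shares, cfg.class_probs, atol=0.01)
    for name in cfg.dictionary.feature_names:
        x = coh.data[name].to_numpy()
        K = len(cfg.dictionary.levels[name])
        for c in (0, 1):
            freq = np.bincount(x[cls == c], minlength=K) / np.sum(cls == c)
            assert np.allclose(freq, cfg.item_probs[name][c], atol=0.01), name


def test_marginal_nonresponse_rate_calibrated(big_cohort):
    _, coh = big_cohort
    rate = 100.0 * coh.n_events / coh.n
    assert abs(rate - 4.32) <= 0.5  # percentage points


def test_planted_event_and_mp_counts(emul_cohort):
    assert emul_cohort.n == 509
    assert emul_cohort.n_events == 22
    mp = emul_cohort.data["assessment_system"] == "MP"
    assert int(mp.sum()) == 48
    assert int(emul_cohort.outcome[mp].sum()) == 2


def test_degenerate_item_probs_give_deterministic_classes():
    base = sp.paper_emulation_config(n_patients=120)
    item_probs = {}
    for name, m in base.item_probs.items():
        K = m.shape[1]
        det = np.zeros((2, K))
        det[0, 0] = 1.0
        det[1, K - 1] = 1.0
        item_probs[name] = det
    cfg = sp.GeneratorConfig(
        n_patients=120,
        class_probs=(0.5, 0.5),
        item_probs=item_probs,
        dictionary=base.dictionary,
        outcome_intercept=base.outcome_intercept,
        pattern_log_or=base.pattern_log_or,
    )
    coh = sp.generate_cohort(cfg, seed=3)
    fit = sp.fit_lca(coh.features, 2, n_starts=10, seed=0)
    acc = np.mean(fit.modal_assignment == coh.data["true_class"].to_numpy())
    assert max(acc, 1 - acc) == 1.0


def test_null_pattern_effect_estimates_center_at_zero(emul_config):
    cfg = sp.paper_emulation_config()
    cfg.pattern_log_or = 0.0
    betas = []
    for s in range(40):
        coh = sp.generate_cohort(cfg, seed=100 + s)
        if coh.n_events < 2:
            continue
        pattern_b = (coh.data["true_class"] == 1).to_numpy().astype(float)
        X = sp.build_design(coh.data, pattern_b)
        fit = sp.firth_fit(X, coh.outcome)
        betas.append(fit.beta[fit.names.index("pattern_b")])
    assert abs(np.mean(betas)) < 0.2


def test_invalid_probability_vectors_rejected(emul_config):
    with pytest.raises(ValueError):
        sp.GeneratorConfig(
            n_patients=10,
            class_probs=(0.7, 0.7),
            item_probs=emul_config.item_probs,
            dictionary=emul_config.dictionary,
            outcome_intercept=-3.0,
            pattern_log_or=0.9,
        )
    bad = {k: np.asarray(v).copy() for k, v in emul_config.item_probs.items()}
    bad["irregular_shape"] = np.array([[0.5, 0.6], [0.5, 0.5]])
    with pytest.raises(ValueError):
        sp.GeneratorConfig(
            n_patients=10,
            class_probs=(0.5, 0.5),
            item_probs=bad,
            dictionary=emul_config.dictionary,
            outcome_intercept=-3.0,
            pattern_log_or=0.9,
        )


def test_config_yaml_roundtrip(tmp_path, emul_config):
    path = tmp_path / "gen.yaml"
    save_config(emul_config, path)
    back = load_config(path)
    assert back.n_patients == emul_config.n_patients
    assert back.class_probs == emul_config.class_probs
    for name in emul_config.dictionary.feature_names:
        assert np.allclose(back.item_probs[name], emul_config.item_probs[name])
    a = sp.generate_cohort(emul_config, seed=5)
    b = sp.generate_cohort(back, seed=5)
    assert a.data.equals(b.data)
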