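"""Deviance test, exact neutrality test, formula comparison, BH adjustment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2

from hubbell import (
    adjust_pvalues,
    apply_adjustment,
    compare_formulae,
    exact_neutrality_test,
    fit_etienne,
    fit_ewens,
    lrt_deviance,
    m_to_I,
    simulate_local_community,
)
from hubbell.synthetic import niche_community


# ---------------------------------------------------------------------------
# deviance


def test_identical_models_give_p_one():
    D, p = lrt_deviance(-10.0, -10.0)
    assert D == 0.0 and p == 1.0


def test_chi2_critical_value():
    # D = 3.8415 sits at the 95th percentile of chi2(1)
    crit = chi2.ppf(0.95, 1)
    D, p = lrt_deviance(-5.0 - crit / 2, -5.0)
    assert D == pytest.approx(crit, rel=1e-9)
    assert p == pytest.approx(0.05, abs=1e-6)


def test_negative_deviance_clamped_to_pass():
    D, p = lrt_deviance(-3.0, -8.0)  # null fits better than alternative
    assert D < 0 and p == 1.0


def test_nonfinite_inputs_rejected():
    with pytest.raises(ValueError):
        lrt_deviance(float("nan"), 0.0)


# ---------------------------------------------------------------------------
# exact test


def _neutral_sample(rep: int, theta=10.0, m=0.9, J=150):
    rng = np.random.default_rng([101, rep])
    return simulate_local_community(theta, m_to_I(m, J), J, rng, sample_id=f"n{rep}")


def test_verdict_reproducible():
    cfg = _neutral_sample(0)
    fit = fit_etienne(cfg)
    v1 = exact_neutrality_test(cfg, fit, n_sims=50, seed=9)
    v2 = exact_neutrality_test(cfg, fit, n_sims=50, seed=9)
    assert v1.p_value == v2.p_value
    assert (v1.logL_sims == v2.logL_sims).all()
    assert v1.deviance_D == v2.deviance_D


def test_neutral_samples_mostly_pass():
    """Self-consistency: data drawn from the fitted model should rarely be
    rejected (desk-scale version of the type-I calibration)."""
    passes = 0
    for rep in range(15):
        cfg = _neutral_sample(rep)
        v = exact_neutrality_test(cfg, fit_etienne(cfg), n_sims=60, seed=500 + rep)
        passes += v.p_value > 0.05
    assert passes >= 12


def test_niche_regularised_community_rejected():
    """A lognormal niche community carries less demographic randomness than
    neutrality predicts: its configuration is more probable than typical
    draws from the fitted neutral model, and the test must flag it."""
    rng = np.random.default_rng(404)
    cfg = niche_community("lognormal", {"S_star": 100, "sigma": 2.0}, 3000, rng)
    v = exact_neutrality_test(cfg, fit_etienne(cfg), n_sims=60, seed=7)
    assert v.deviance_D > 0
    assert v.p_value <= 0.05
    assert v.rank_p > 0.5  # observed logL sits in the sims' upper tail


def test_ewens_formula_variant_runs():
    cfg = _neutral_sample(3)
    v = exact_neutrality_test(cfg, fit_ewens(cfg), n_sims=40, seed=2)
    assert v.formula == "ewens" and v.m is None
    assert 0 <= v.p_value <= 1
    assert len(v.logL_sims) == 40


def test_refit_mode_differs_from_plugin_mode():
    cfg = _neutral_sample(4, J=80)
    fit = fit_etienne(cfg)
    v_plug = exact_neutrality_test(cfg, fit, n_sims=15, seed=3)
    v_refit = exact_neutrality_test(cfg, fit, n_sims=15, seed=3, refit_sims=True)
    # refit likelihoods are maximised per simulation, so never smaller
    assert (v_refit.logL_sims >= v_plug.logL_sims - 1e-9).all()


def test_single_simulation_identical_loglik_gives_p_one():
    cfg = _neutral_sample(5, J=60)
    fit = fit_etienne(cfg)
    v = exact_neutrality_test(cfg, fit, n_sims=1, seed=1)
    D, p = lrt_deviance(v.logL_sims[0], v.logL_obs)
    assert v.p_value == p
    if v.logL_sims[0] == v.logL_obs:
        assert v.p_value == 1.0


def test_more_simulations_rarely_flip_verdicts():
    """Raising the simulation count from 100 to 1000 should change pass/fail
    calls only for samples near the alpha boundary (flip rate <= 10%)."""
    I = m_to_I(0.9, 100)
    flips = 0
    for rep in range(30):
        rng = np.random.default_rng([7, rep])
        cfg = simulate_local_community(10.0, I, 100, rng)
        fit = fit_etienne(cfg)
        v100 = exact_neutrality_test(cfg, fit, n_sims=100, seed=1000 + rep)
        v1000 = exact_neutrality_test(cfg, fit, n_sims=1000, seed=1000 + rep)
        flips += (v100.p_value > 0.05) != (v1000.p_value > 0.05)
    assert flips <= 3


# ---------------------------------------------------------------------------
# formula comparison


def test_formulae_agree_on_high_migration_community():
    cfg = _neutral_sample(6, theta=15.0, m=0.999, J=400)
    D, p = compare_formulae(cfg, fit_ewens(cfg), fit_etienne(cfg))
    assert p > 0.05


def test_etienne_improves_on_dispersal_limited_community():
    rng = np.random.default_rng([13, 0])
    cfg = simulate_local_community(20.0, m_to_I(0.1, 1000), 1000, rng)
    ew, et = fit_ewens(cfg), fit_etienne(cfg)
    assert et.logL - ew.logL > 0  # nested model, strict improvement expected
    D, p = compare_formulae(cfg, ew, et)
    assert D > 0


def test_identical_logls_give_p_one(small_config):
    ew = fit_ewens(small_config)
    et = fit_etienne(small_config)
    et.logL = ew.logL
    D, p = compare_formulae(small_config, ew, et)
    assert D == 0.0 and p == 1.0


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_examples():
    assert adjust_pvalues([0.03]).tolist() == [0.03]
    np.testing.assert_allclose(
        adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_largest_p_unchanged():
    p = [0.5873, 0.01, 0.2, 0.44]
    adj = adjust_pvalues(p)
    assert adj[0] == pytest.approx(0.5873)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.2])
    with pytest.raises(ValueError):
        adjust_pvalues([-0.1])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_dominates_raw_and_preserves_order(pvals):
    adj = adjust_pvalues(pvals)
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()
    order = np.argsort(pvals)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_apply_adjustment_sets_family_and_passes():
    cfg = _neutral_sample(8, J=60)
    fit = fit_etienne(cfg)
    verdicts = [
        exact_neutrality_test(cfg, fit, n_sims=10, seed=s) for s in range(4)
    ]
    apply_adjustment(verdicts)
    for v in verdicts:
        assert v.p_adjusted is not None
        assert v.p_adjusted >= v.p_value - 1e-12
        assert v.passes == (v.p_adjusted > v.alpha)
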