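"""Etienne formula: Stirling machinery, K coefficients, likelihood, joint MLE."""

import math
from itertools import product

import numpy as np
import pytest
from sympy.functions.combinatorial.numbers import stirling

from hubbell import (
    AbundanceConfiguration,
    I_to_m,
    compute_K,
    etienne_log_likelihood,
    ewens_log_likelihood,
    ewens_theta_mle,
    fit_etienne,
    log_stirling_row,
    m_to_I,
    simulate_local_community,
)

from conftest import all_partitions


# ---------------------------------------------------------------------------
# Stirling numbers


def test_stirling_row_small_values():
    assert log_stirling_row(1).tolist() == [0.0]
    np.testing.assert_allclose(np.exp(log_stirling_row(3)), [2, 3, 1], rtol=1e-12)


@pytest.mark.parametrize("n", [2, 5, 9])
def test_stirling_row_matches_exact_integers(n):
    exact = [int(stirling(n, a, kind=1, signed=False)) for a in range(1, n + 1)]
    np.testing.assert_allclose(np.exp(log_stirling_row(n)), exact, rtol=1e-12)


def test_stirling_row_boundaries():
    row = log_stirling_row(20)
    assert row[0] == pytest.approx(math.lgamma(20), rel=1e-14)  # s(n,1) = (n-1)!
    assert row[-1] == 0.0  # s(n,n) = 1
    # cache must serve smaller rows correctly after a larger request
    np.testing.assert_allclose(np.exp(log_stirling_row(4)), [6, 11, 6, 1], rtol=1e-12)


# ---------------------------------------------------------------------------
# K(D, A)


def test_K_for_single_doubleton():
    K = compute_K(AbundanceConfiguration("x", [2]))
    np.testing.assert_allclose(np.exp(K.logK), [1.0, 1.0], rtol=1e-12)
    assert K.A.tolist() == [1, 2]


def test_K_singletons_force_A_equal_S():
    K = compute_K(AbundanceConfiguration("x", [1, 1]))
    np.testing.assert_allclose(np.exp(K.logK), [1.0], rtol=1e-12)
    assert K.A.tolist() == [2]


def test_K_matches_exact_brute_force():
    """K(D,A) for D=(3,2) against exact-integer summation over (a1, a2)."""
    cfg = AbundanceConfiguration("x", [3, 2])
    K = compute_K(cfg)
    from fractions import Fraction

    def s(n, a):
        return int(stirling(n, a, kind=1, signed=False))

    for idx, A in enumerate(K.A):
        total = Fraction(0)
        for a1, a2 in product(range(1, 4), range(1, 3)):
            if a1 + a2 == A:
                total += (
                    Fraction(s(3, a1) * s(a1, 1), s(3, 1))
                    * Fraction(s(2, a2) * s(a2, 1), s(2, 1))
                )
        assert math.exp(K.logK[idx]) == pytest.approx(float(total), rel=1e-10)


def test_K_independent_of_parameters_and_order():
    cfg = AbundanceConfiguration("x", [5, 3, 2, 1])
    K1 = compute_K(cfg)
    K2 = compute_K(AbundanceConfiguration("x", [1, 2, 3, 5]))
    np.testing.assert_allclose(K1.logK, K2.logK, rtol=1e-12)


# ---------------------------------------------------------------------------
# likelihood


def test_single_individual_likelihood_is_one():
    cfg = AbundanceConfiguration("x", [1])
    K = compute_K(cfg)
    assert etienne_log_likelihood(cfg, K, 3.0, 0.7) == pytest.approx(0.0, abs=1e-12)


def test_doubleton_closed_form():
    """Pr(D=(2) | theta, I) = 1/(I+1) + I/((I+1)(theta+1)): the second
    individual either copies the first or immigrates and draws the same
    metacommunity species."""
    cfg = AbundanceConfiguration("x", [2])
    K = compute_K(cfg)
    for theta, m in [(1.0, 0.5), (2.0, 0.3), (0.7, 0.9)]:
        I = m_to_I(m, 2)
        expected = 1 / (I + 1) + I / ((I + 1) * (theta + 1))
        got = math.exp(etienne_log_likelihood(cfg, K, theta, m))
        assert got == pytest.approx(expected, abs=1e-10)


def test_m_bounds_enforced(small_config):
    K = compute_K(small_config)
    for bad_m in (0.0, 1.0, -0.2, 1.3):
        with pytest.raises(ValueError):
            etienne_log_likelihood(small_config, K, 1.0, bad_m)


@pytest.mark.parametrize("J", range(2, 7))
@pytest.mark.parametrize("theta,m", list(product([1.0, 2.0], [0.3, 0.7])))
def test_normalization_over_all_partitions(J, theta, m):
    total = 0.0
    for ab in all_partitions(J):
        cfg = AbundanceConfiguration("p", ab)
        total += math.exp(etienne_log_likelihood(cfg, compute_K(cfg), theta, m))
    assert total == pytest.approx(1.0, abs=1e-8)


def test_reduces_to_ewens_as_m_approaches_one(neutral_config_300):
    K = compute_K(neutral_config_300)
    for theta in (2.0, 10.0, 40.0):
        et = etienne_log_likelihood(neutral_config_300, K, theta, 1 - 1e-9)
        ew = ewens_log_likelihood(neutral_config_300, theta)
        assert et == pytest.approx(ew, abs=1e-4)


def test_likelihood_invariant_under_abundance_permutation():
    a = AbundanceConfiguration("a", [7, 4, 2, 1])
    b = AbundanceConfiguration("b", [1, 2, 4, 7])
    assert etienne_log_likelihood(a, compute_K(a), 3.0, 0.6) == pytest.approx(
        etienne_log_likelihood(b, compute_K(b), 3.0, 0.6), rel=1e-12
    )


# ---------------------------------------------------------------------------
# conversions


def test_m_I_conversions():
    assert m_to_I(0.5, 2) == pytest.approx(1.0)
    assert I_to_m(1.0, 2) == pytest.approx(0.5)
    assert math.isinf(m_to_I(1.0, 10))
    rng = np.random.default_rng(3)
    for m in rng.uniform(0.01, 0.99, size=20):
        assert I_to_m(m_to_I(m, 100), 100) == pytest.approx(m, abs=1e-12)


# ---------------------------------------------------------------------------
# fitting


def test_fit_matches_grid_search_on_doubleton():
    cfg = AbundanceConfiguration("x", [2])
    K = compute_K(cfg)
    thetas = np.linspace(0.05, 5, 50)
    ms = np.linspace(0.02, 0.98, 50)
    grid = [
        (etienne_log_likelihood(cfg, K, t, m), t, m) for t in thetas for m in ms
    ]
    best_ll, _, _ = max(grid)
    fit = fit_etienne(cfg)
    assert fit.logL >= best_ll - 1e-6


def test_fit_beats_ewens_profile(neutral_config_300):
    """Optimality: the joint fit is at least as good as the Ewens theta with
    m pushed to the no-dispersal-limit boundary."""
    cfg = neutral_config_300
    fit = fit_etienne(cfg)
    theta_e = ewens_theta_mle(cfg.J, cfg.S)
    K = compute_K(cfg)
    assert fit.logL >= etienne_log_likelihood(cfg, K, theta_e, 1 - 1e-9) - 1e-6
    assert fit.converged
    assert fit.I == pytest.approx(m_to_I(fit.m, cfg.J), rel=1e-9)


def test_fit_recovers_parameters_small_batch():
    """Median of 12 seeded fits at (theta=20, m=0.9, J=500) lands near the
    generating values (full-scale recovery lives in the acceptance suite)."""
    I = m_to_I(0.9, 500)
    thetas, ms = [], []
    for rep in range(12):
        rng = np.random.default_rng([42, rep])
        cfg = simulate_local_community(20.0, I, 500, rng)
        f = fit_etienne(cfg)
        thetas.append(f.theta)
        ms.append(f.m)
    assert 10 <= np.median(thetas) <= 40
    assert 0.6 <= np.median(ms) <= 0.999


def test_fit_single_species_flagged_weakly_identified():
    f = fit_etienne(AbundanceConfiguration("x", [30]))
    assert f.weakly_identified
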