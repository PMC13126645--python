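"""Moment-equation kinetics: conservation, limits, oracles, hypothesis fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligokin import kinetics as K
from oligokin import synthetic
from oligokin.errors import (
    FitFailureError,
    NoCrossingError,
    NoPlateauError,
    ParameterError,
)

T_GRID = np.linspace(0.0, 30.0, 301)


@pytest.mark.parametrize(
    "params",
    [
        K.RateParameters(),
        K.RateParameters(k_n=1e-6, n_c=2.5, k_2=3e-4, n_2=3.0),
        K.RateParameters(active_seed_fraction=0.02),
        K.RateParameters(k_plus=10.0, k_2=1e-3, m_eq=0.0),
    ],
)
def test_mass_conservation(params):
    st_ = K.integrate_moments(params, T_GRID)
    assert np.max(np.abs(st_.m + st_.M - params.m_total)) < 1e-6 * params.m_total
    assert np.all(st_.P >= 0) and np.all(st_.M >= -1e-12)


def test_elongation_only_early_slope_matches_linearization():
    # With nucleation off, dM/dt(0) = 2 k+ P0 (m_total - M0 - m_eq).
    p = K.RateParameters(k_n=0.0, k_2=0.0)
    M0 = p.seed_mass_M0
    P0 = M0 / p.seed_mean_size_L0
    slope = 2 * p.k_plus * P0 * (p.m_total - M0 - p.m_eq)
    # first 1% of mass conversion
    t_end = 0.01 * (p.m_total - p.m_eq - M0) / slope
    t = np.linspace(0, t_end, 50)
    st_ = K.integrate_moments(p, t)
    num_slope = (st_.M[-1] - st_.M[0]) / t_end
    assert num_slope == pytest.approx(slope, rel=0.01)


def test_longtime_monomer_plateaus_at_solubility():
    p = K.RateParameters()
    st_ = K.integrate_moments(p, np.linspace(0.0, 300.0, 200))
    assert st_.m[-1] == pytest.approx(3.5, abs=1e-3)
    assert st_.M[-1] == pytest.approx(1.5, abs=1e-3)


def test_monotone_fibril_mass():
    p = K.RateParameters(k_n=1e-5, k_2=5e-4)
    st_ = K.integrate_moments(p, T_GRID)
    assert np.all(np.diff(st_.M) >= -1e-9)


def _rk4(params, t_grid):
    """Fixed-step classical RK4 reference at the grid's own resolution."""
    p = params
    M = p.seed_mass_M0 * p.active_seed_fraction
    P = M / p.seed_mean_size_L0
    out_M = [M]

    def f(y):
        P_, M_ = y
        m = max(p.m_total - M_, 0.0)
        return np.array(
            [p.k_n * m**p.n_c + p.k_2 * m**p.n_2 * M_,
             2 * p.k_plus * P_ * (m - p.m_eq)]
        )

    y = np.array([P, M])
    for i in range(len(t_grid) - 1):
        h = t_grid[i + 1] - t_grid[i]
        k1 = f(y)
        k2 = f(y + h / 2 * k1)
        k3 = f(y + h / 2 * k2)
        k4 = f(y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out_M.append(y[1])
    return np.array(out_M)


def test_against_rk4_reference():
    p = K.RateParameters()
    coarse = np.linspace(0.0, 20.0, 201)
    fine = np.linspace(0.0, 20.0, 2001)  # 10x finer step
    ref = _rk4(p, fine)[::10]
    st_ = K.integrate_moments(p, coarse)
    scale = np.maximum(np.abs(ref), p.seed_mass_M0)
    assert np.max(np.abs(st_.M - ref) / scale) < 1e-4


def test_invalid_time_grid_and_params():
    with pytest.raises(ParameterError):
        K.integrate_moments(K.RateParameters(), np.array([1.0, 2.0]))
    with pytest.raises(ParameterError):
        K.RateParameters(k_plus=-1.0)
    with pytest.raises(ParameterError):
        K.RateParameters(m_eq=6.0)
    with pytest.raises(ParameterError):
        K.RateParameters(active_seed_fraction=1.5)


# --- oligomer channel --------------------------------------------------

def test_oligomer_zero_without_secondary_nucleation():
    p = K.RateParameters(k_2=0.0, k_n=1e-5)
    st_ = K.integrate_moments(p, T_GRID)
    O = K.oligomer_population(st_, p, k_loss=3.5)
    assert np.max(O) < 1e-12


def test_oligomer_vanishes_at_fast_loss():
    p = K.RateParameters()
    st_ = K.integrate_moments(p, T_GRID)
    O_fast = K.oligomer_population(st_, p, k_loss=1e5)
    O_ref = K.oligomer_population(st_, p, k_loss=3.5)
    assert np.max(O_fast) < 1e-3 * np.max(O_ref)


def test_oligomer_negative_loss_rejected():
    p = K.RateParameters()
    st_ = K.integrate_moments(p, T_GRID)
    with pytest.raises(ParameterError):
        K.oligomer_population(st_, p, k_loss=-1.0)


def test_oligomer_peak_in_growth_window_and_convolution_oracle():
    p = K.RateParameters()
    t = np.linspace(0.0, 20.0, 2001)
    st_ = K.integrate_moments(p, t)
    k_loss = 3.5
    O = K.oligomer_population(st_, p, k_loss)
    # peak within the 20-80% conversion window of M
    conv = (st_.M - st_.M[0]) / (st_.M[-1] - st_.M[0])
    c_at_peak = conv[np.argmax(O)]
    assert 0.2 < c_at_peak < 0.8
    # quadrature of the convolution solution
    src = p.k_2 * np.maximum(st_.m - p.m_eq, 0.0) ** p.n_2 * st_.M
    for idx in (500, 1000, 1500, 2000):
        tt, ss = t[: idx + 1], src[: idx + 1]
        oracle = np.trapezoid(np.exp(-k_loss * (tt[-1] - tt)) * ss, tt)
        assert O[idx] == pytest.approx(oracle, rel=2e-3, abs=1e-12)


# --- normalization and half-times -------------------------------------

def _logistic_trace(t0=6.0, rate=2.0, lo=50.0, hi=950.0):
    t = np.linspace(0.0, 14.0, 400)
    y = lo + (hi - lo) / (1.0 + np.exp(-rate * (t - t0)))
    return K.KineticTrace(t=t, signal=y)


def test_normalize_rejects_constant_signal():
    t = np.linspace(0, 10, 100)
    with pytest.raises(NoPlateauError):
        K.normalize_trace(K.KineticTrace(t=t, signal=np.full(100, 7.0)))


def test_normalize_affine_invariance():
    tr = _logistic_trace()
    n1 = K.normalize_trace(tr)
    tr2 = K.KineticTrace(t=tr.t, signal=3.7 * tr.signal + 42.0)
    assert np.allclose(n1, K.normalize_trace(tr2), atol=1e-12)


def test_normalize_logistic_limits():
    n = K.normalize_trace(_logistic_trace())
    assert n[0] == pytest.approx(0.0, abs=0.01)
    assert n[-1] == pytest.approx(1.0, abs=0.01)


def test_halftime_logistic_center_and_shift():
    tr = _logistic_trace(t0=6.0)
    t_half = K.halftime(tr.t, K.normalize_trace(tr))
    assert t_half == pytest.approx(6.0, abs=0.02)
    tr2 = _logistic_trace(t0=7.5)
    assert K.halftime(tr2.t, K.normalize_trace(tr2)) - t_half == pytest.approx(
        1.5, abs=0.04
    )


def test_halftime_requires_crossing():
    with pytest.raises(NoCrossingError):
        K.halftime(np.linspace(0, 1, 10), np.full(10, 0.2))


@given(frac=st.floats(0.05, 0.5))
@settings(max_examples=10, deadline=None)
def test_halving_seed_fraction_increases_halftime(frac):
    # secondary-nucleation-dominated set: k_n = 0, k_2 > 0, seeds > 0
    t = np.linspace(0.0, 120.0, 600)

    def th(a):
        p = K.RateParameters(active_seed_fraction=a)
        st_ = K.integrate_moments(p, t)
        n = (st_.M - st_.M[0]) / (st_.M[-1] - st_.M[0])
        return K.halftime(t, n)

    assert th(frac / 2) > th(frac) + 1e-3


# --- hypothesis fitting -----------------------------------------------

def test_fit_recovers_k2_scaling_from_noiseless_reduce_k2_data():
    base = K.RateParameters()
    t = np.linspace(0.0, 60.0, 201)
    traces = []
    true_scale = {0.0: 1.0, 150.0: 0.25}
    for conc, s in true_scale.items():
        st_ = K.integrate_moments(base.with_(k_2=base.k_2 * s), t)
        traces.append(
            K.KineticTrace(t=t, signal=100 + 600 * st_.M, jb6_conc=conc)
        )
    fit = K.fit_hypothesis(traces, "reduce_k2", base_params=base)
    assert fit.per_group[150.0] / fit.per_group[0.0] == pytest.approx(0.25, rel=1e-3)


def test_baseline_only_fit_is_degenerate_estimation():
    base = K.RateParameters()
    t = np.linspace(0.0, 30.0, 201)
    st_ = K.integrate_moments(base, t)
    tr = K.KineticTrace(t=t, signal=100 + 600 * st_.M, jb6_conc=0.0)
    fit = K.fit_hypothesis([tr], "inactivate_seeds", base_params=base)
    assert fit.per_group == {0.0: 1.0}
    assert fit.base_params.k_2 == pytest.approx(base.k_2, rel=1e-2)
    assert fit.ess < 1e-4


def test_unknown_hypothesis_and_missing_anchor():
    t = np.linspace(0.0, 30.0, 301)
    st_ = K.integrate_moments(K.RateParameters(), t)
    tr = K.KineticTrace(t=t, signal=100 + 600 * st_.M, jb6_conc=50.0)
    with pytest.raises(ParameterError):
        K.fit_hypothesis([tr], "reduce_k2")  # no 0 nM anchor
    tr0 = K.KineticTrace(t=t, signal=100 + 600 * st_.M, jb6_conc=0.0)
    with pytest.raises(ParameterError):
        K.fit_hypothesis([tr0], "shake_vigorously")


def test_seed_inactivation_wins_on_seed_inactivated_data(fig3a_traces):
    """On traces synthesized under seed inactivation the inactivate_seeds
    hypothesis attains the lowest e.s.s. of the three."""
    fits = K.rank_hypotheses(fig3a_traces)
    assert fits[0].hypothesis == "inactivate_seeds"
    assert fits[0].ess < 0.5 * fits[1].ess
    # recovered active fractions decrease with chaperone concentration
    vals = [fits[0].per_group[c] for c in (0.0, 50.0, 150.0, 300.0, 1000.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
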