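"""Event detection, hyperdynamics time rescaling, and Poisson residence fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindkin.colvar import ColvarSeries
from bindkin.synthetic import gen_unbinding_times
from bindkin.unbinding import (bootstrap_t_half, detect_unbinding_event,
                               fit_poisson_mle, ks_reliability_test,
                               rescaled_time, unbinding_times_from_traces)
from bindkin.units import LN2, kT as thermal_kT


def _trace(z, bias=None, T=310.0, dt=0.1):
    n = len(z)
    t = dt * np.arange(1, n + 1)
    return ColvarSeries(time=t, cv=np.asarray(z, float),
                        bias=np.zeros(n) if bias is None
                        else np.asarray(bias, float), temperature=T)


def test_event_detection_monotone_escape():
    z = np.linspace(0, 20, 101)
    tr = _trace(z)
    k = detect_unbinding_event(tr, z_threshold=10.0, dwell=1)
    assert z[k] > 10.0 and z[k - 1] <= 10.0


def test_event_detection_no_crossing():
    assert detect_unbinding_event(_trace(np.full(50, 2.0)),
                                  z_threshold=10.0) is None


def test_single_spike_rejected_by_dwell():
    z = np.full(100, 2.0)
    z[40] = 15.0
    tr = _trace(z)
    assert detect_unbinding_event(tr, 10.0, dwell=5) is None
    assert detect_unbinding_event(tr, 10.0, dwell=1) == 40
    z[40:50] = 15.0
    assert detect_unbinding_event(_trace(z), 10.0, dwell=5) == 40


def test_event_detection_with_contact_condition():
    z = np.linspace(0, 20, 21)
    contacts = np.zeros(21, dtype=int)
    contacts[:15] = 5
    k = detect_unbinding_event(_trace(z), 5.0, contact_zero_required=True,
                               contacts=contacts, dwell=1)
    assert k == 15
    with pytest.raises(ValueError):
        detect_unbinding_event(_trace(z), 5.0, contact_zero_required=True)


def test_rescaled_time_identities():
    kT = thermal_kT(310.0)
    z = np.linspace(0, 20, 101)
    flat = _trace(z)
    # zero bias: physical time equals simulation time (ns → s)
    sim_ns = flat.time[-1] - flat.time[0]
    assert rescaled_time(flat, 100) == pytest.approx(sim_ns * 1e-9, rel=1e-12)
    # constant bias kT·ln10 multiplies time by exactly 10
    boosted = _trace(z, bias=np.full(101, kT * np.log(10.0)))
    assert rescaled_time(boosted, 100) == pytest.approx(
        10 * rescaled_time(flat, 100), rel=1e-9)


def test_rescaled_time_piecewise_matches_step_sum(rng):
    kT = thermal_kT(300.0)
    n = 60
    t = np.cumsum(rng.uniform(0.05, 0.3, n))      # irregular Δt, ns
    bias = rng.uniform(0, 5, n)
    tr = ColvarSeries(time=t, cv=np.zeros(n), bias=bias, temperature=300.0)
    # brute-force oracle: explicit loop over steps
    expected = 0.0
    for i in range(1, n):
        expected += (t[i] - t[i - 1]) * 1e-9 * np.exp(bias[i] / kT)
    assert rescaled_time(tr, n - 1) == pytest.approx(expected, rel=1e-10)


@given(seed=st.integers(0, 50))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_rescaled_time_monotone_in_bias(seed):
    rng = np.random.default_rng(seed)
    n = 30
    t = np.cumsum(rng.uniform(0.05, 0.2, n))
    bias = rng.uniform(0, 3, n)
    tr1 = ColvarSeries(time=t, cv=np.zeros(n), bias=bias, temperature=300.0)
    bump = bias.copy()
    bump[rng.integers(1, n)] += 1.0
    tr2 = ColvarSeries(time=t, cv=np.zeros(n), bias=bump, temperature=300.0)
    assert rescaled_time(tr2, n - 1) >= rescaled_time(tr1, n - 1)


def test_rescaled_time_overflow_guarded():
    # a 300 kcal/mol bias would overflow naive exp-of-sum at every step;
    # the log-space evaluation returns the exact (huge) value
    kT = thermal_kT(300.0)
    n = 10
    tr = ColvarSeries(time=np.arange(1.0, n + 1), cv=np.zeros(n),
                      bias=np.full(n, 300.0), temperature=300.0)
    val = rescaled_time(tr, n - 1)
    expected = 9.0 * 1e-9 * np.exp(300.0 / kT)
    assert np.isfinite(val) and val == pytest.approx(expected, rel=1e-9)


def test_poisson_mle_is_sample_mean():
    times = gen_unbinding_times(26.4, 15, seed=4)
    fit = fit_poisson_mle(times, seed=0)
    assert fit.tau == pytest.approx(times.mean(), rel=1e-12)
    assert fit.t_half == pytest.approx(fit.tau * LN2, rel=1e-12)
    assert fit.n == 15
    dup = fit_poisson_mle(np.full(5, 7.0), seed=0)
    assert dup.tau == 7.0 and dup.t_half == pytest.approx(7.0 * LN2)


def test_poisson_mle_rejects_bad_input():
    with pytest.raises(ValueError):
        fit_poisson_mle([3.0])
    with pytest.raises(ValueError):
        fit_poisson_mle([1.0, -2.0])
    with pytest.raises(ValueError):
        fit_poisson_mle([1.0, 0.0])


def test_ks_degenerate_sample_rejected_as_poisson():
    d, p = ks_reliability_test(np.full(10, 5.0), 5.0, n_boot=500, seed=0)
    assert p < 0.01


def test_ks_small_sample_valid_bounds():
    d, p = ks_reliability_test([1.0, 2.0], 1.5, n_boot=1000, seed=0)
    assert 0.0 <= p <= 1.0 and 0.0 <= d <= 1.0


def test_ks_plain_variant_more_conservative():
    times = gen_unbinding_times(10.0, 15, seed=9)
    tau = times.mean()
    _, p_boot = ks_reliability_test(times, tau, seed=0)
    _, p_plain = ks_reliability_test(times, tau, parametric=False)
    assert p_plain >= p_boot * 0.5   # plain KS with fitted tau is inflated


def test_bootstrap_se_properties():
    se0, _ = bootstrap_t_half(np.full(10, 4.0), seed=0)
    assert se0 == pytest.approx(0.0, abs=1e-12)
    ses = []
    for n in (10, 40, 160):
        se_n = np.mean([bootstrap_t_half(gen_unbinding_times(10.0, n, seed=s),
                                         n_boot=400, seed=s)[0]
                        for s in range(30)])
        ses.append(se_n)
    assert 1.5 < ses[0] / ses[1] < 2.7      # ideal 2 per 4x sample size
    assert 1.5 < ses[1] / ses[2] < 2.7
    a = bootstrap_t_half(gen_unbinding_times(5.0, 15, seed=1), seed=3)
    b = bootstrap_t_half(gen_unbinding_times(5.0, 15, seed=1), seed=3)
    assert a == b


def test_times_from_traces_end_to_end():
    kT = thermal_kT(310.0)
    traces = []
    for k in (30, 60):
        z = np.concatenate([np.full(k, 1.0), np.linspace(1, 20, 40)])
        n = len(z)
        traces.append(ColvarSeries(time=0.1 * np.arange(1, n + 1), cv=z,
                                   bias=np.full(n, kT * np.log(2.0)),
                                   temperature=310.0))
    never = ColvarSeries(time=np.arange(1.0, 11), cv=np.full(10, 1.0),
                         bias=np.zeros(10), temperature=310.0)
    times = unbinding_times_from_traces(traces + [never], z_threshold=10.0,
                                        dwell=1)
    assert len(times) == 2          # the non-escaping trace is skipped
    assert np.all(times > 0) and times[1] > times[0]
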