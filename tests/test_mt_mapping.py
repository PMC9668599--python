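"""MTR/MTsat estimators: exact self-consistency, invariances, robustness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gratiokit.flash import simulate_flash_signal
from gratiokit.mt_mapping import (
    compute_mtr,
    compute_mtsat,
    estimate_t1_amplitude,
    fit_mt_maps,
    sum_echoes,
)
from gratiokit.volume import VolumeMap


def _vol(value, shape=(2, 2, 2)):
    return VolumeMap(np.full(shape, float(value)))


def _forward_vols(a, r1, delta, acq, model="rational", shape=(2, 2, 2)):
    """MT_on / MT_off / MT_T1w volumes forward-simulated for one tissue."""
    s_on = simulate_flash_signal(a, r1, delta, acq.alpha1, acq.tr1, model, mt_on=True)
    s_off = simulate_flash_signal(a, r1, delta, acq.alpha1, acq.tr1, model, mt_on=False)
    s_t1w = simulate_flash_signal(a, r1, delta, acq.alpha2, acq.tr2, model, mt_on=False)
    return _vol(s_on, shape), _vol(s_off, shape), _vol(s_t1w, shape)


# ---- echo summation ------------------------------------------------------


def test_sum_echoes_is_voxelwise_sum():
    echoes = [_vol(2.0), _vol(3.0), _vol(5.0)]
    assert np.all(sum_echoes(echoes).data == 10.0)
    single = _vol(7.0)
    assert np.all(sum_echoes([single]).data == single.data)


def test_sum_echoes_rejects_mismatched_grids():
    with pytest.raises(ValueError):
        sum_echoes([_vol(1.0, (2, 2, 2)), _vol(1.0, (3, 3, 3))])
    with pytest.raises(ValueError):
        sum_echoes([])


def test_sum_echoes_snr_grows_like_sqrt_n(rng):
    """ROI-mean SNR of N summed iid-noise echoes grows ~ sqrt(N)."""
    n_draws, n_vox = 10_000, 16
    signal = 10.0

    def roi_snr(n_echoes):
        echoes = signal + rng.normal(0, 1.0, size=(n_draws, n_echoes, n_vox))
        summed = echoes.sum(axis=1)  # (draws, vox)
        roi_means = summed.mean(axis=1)
        return roi_means.mean() / roi_means.std(ddof=1)

    ratio = roi_snr(9) / roi_snr(1)
    assert ratio == pytest.approx(3.0, rel=0.1)


# ---- MTR -----------------------------------------------------------------


def test_mtr_simple_values():
    assert np.all(compute_mtr(_vol(0.5), _vol(1.0)).data == 50.0)
    assert np.all(compute_mtr(_vol(0.8), _vol(0.8)).data == 0.0)


def test_mtr_from_rational_signals(acq):
    on, off, _ = _forward_vols(1.0, 1.0, 0.037, acq)
    mtr = compute_mtr(on, off)
    assert mtr.data.flat[0] == pytest.approx(52.2542, abs=5e-4)


def test_mtr_zero_denominator_flagged():
    mtr = compute_mtr(_vol(0.0), _vol(0.0))
    assert np.all(np.isnan(mtr.data))


def test_mtr_invariant_to_global_scaling(acq):
    on, off, _ = _forward_vols(1.0, 1.0, 0.037, acq)
    scaled = compute_mtr(on.with_data(3.7 * on.data), off.with_data(3.7 * off.data))
    np.testing.assert_allclose(scaled.data, compute_mtr(on, off).data, rtol=1e-12)


# ---- dual-flip-angle estimators -----------------------------------------


def test_t1_amplitude_self_consistency(acq):
    _, off, t1w = _forward_vols(1.0, 1.0, 0.0, acq)
    a_app, r1_app = estimate_t1_amplitude(off, t1w, acq)
    np.testing.assert_allclose(a_app.data, 1.0, rtol=1e-12)
    np.testing.assert_allclose(r1_app.data, 1.0, rtol=1e-12)


def test_t1_amplitude_degenerate_inputs_flagged(acq):
    # S_T1w scaled so S_off/a1 == S_T1w/a2: singular denominator
    off = _vol(1.0)
    t1w = _vol(acq.alpha2 / acq.alpha1)
    a_app, r1_app = estimate_t1_amplitude(off, t1w, acq)
    assert np.all(np.isnan(a_app.data))
    assert np.all(np.isnan(r1_app.data))


def test_r1_recovery_from_exact_spgr_within_5_percent(acq):
    _, off, t1w = _forward_vols(1.0, 1.0, 0.0, acq, model="exact")
    _, r1_app = estimate_t1_amplitude(off, t1w, acq)
    assert r1_app.data.flat[0] == pytest.approx(1.0, rel=0.05)


# ---- MTsat ---------------------------------------------------------------


def test_mtsat_exact_recovery(acq):
    on, off, t1w = _forward_vols(1.0, 1.0, 0.037, acq)
    maps = fit_mt_maps(on, off, t1w, acq)
    np.testing.assert_allclose(maps.mtsat.data, 3.7, rtol=1e-10)


def test_mtsat_zero_when_no_saturation(acq):
    on, off, t1w = _forward_vols(1.0, 1.0, 0.0, acq)
    maps = fit_mt_maps(off, off, t1w, acq)
    assert on.data.flat[0] == pytest.approx(off.data.flat[0])
    np.testing.assert_allclose(maps.mtsat.data, 0.0, atol=1e-12)


def test_mtsat_invariant_to_global_scaling(acq):
    on, off, t1w = _forward_vols(1.0, 0.9, 0.03, acq)
    ref = fit_mt_maps(on, off, t1w, acq).mtsat.data
    c = 123.4
    scaled = fit_mt_maps(
        on.with_data(c * on.data), off.with_data(c * off.data), t1w.with_data(c * t1w.data), acq
    ).mtsat.data
    np.testing.assert_allclose(scaled, ref, rtol=1e-10)


@settings(max_examples=60, derandomize=True)
@given(
    a=st.floats(0.5, 2000.0),
    r1=st.floats(0.3, 2.5),
    delta=st.floats(0.0, 0.08),
)
def test_rational_round_trip_recovers_tissue_parameters(a, r1, delta):
    """delta/A/R1 recovery is exact on rational-model forward signals."""
    from gratiokit.acquisition import DEFAULT_PROTOCOL as acq

    on, off, t1w = _forward_vols(a, r1, delta, acq, shape=(1, 1, 1))
    maps = fit_mt_maps(on, off, t1w, acq)
    assert maps.a_app.data.flat[0] == pytest.approx(a, rel=1e-9)
    assert maps.r1_app.data.flat[0] == pytest.approx(r1, rel=1e-9)
    assert maps.mtsat.data.flat[0] == pytest.approx(100.0 * delta, rel=1e-8, abs=1e-9)


def test_mtsat_independent_of_t1_but_mtr_is_not(acq):
    """Two tissues, equal saturation, different R1: MTsat agrees, MTR differs."""
    delta = 0.037
    maps = {}
    for name, r1 in (("short_t1", 1.4), ("long_t1", 0.7)):
        on, off, t1w = _forward_vols(1.0, r1, delta, acq)
        maps[name] = fit_mt_maps(on, off, t1w, acq)
    mtsat_a = maps["short_t1"].mtsat.data.flat[0]
    mtsat_b = maps["long_t1"].mtsat.data.flat[0]
    mtr_a = maps["short_t1"].mtr.data.flat[0]
    mtr_b = maps["long_t1"].mtr.data.flat[0]
    assert mtsat_a == pytest.approx(mtsat_b, rel=1e-10)
    assert abs(mtr_a - mtr_b) > 1.0  # MTR shifts by percents with T1


def test_exact_model_bias_shrinks_with_flip_angle():
    """MTsat bias on exact-SPGR signals decreases toward the small-angle limit."""
    from gratiokit.acquisition import AcquisitionParams

    delta = 0.04

    def bias(flip1_deg, flip2_deg):
        acq = AcquisitionParams.from_degrees_ms(flip1_deg, flip2_deg, 30.0, 15.0)
        on, off, t1w = _forward_vols(1.0, 1.0, delta, acq, model="exact")
        est = fit_mt_maps(on, off, t1w, acq).mtsat.data.flat[0]
        return abs(est - 100.0 * delta)

    assert bias(3.0, 11.0) < bias(5.0, 18.0) < bias(8.0, 28.0)
    assert bias(5.0, 18.0) < 0.2  # bounded: < 0.2 MTsat percent
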