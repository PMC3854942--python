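"""Calibration stage: ratio computation, in-situ estimation, inversion,
normalization and hierarchical averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magflux.calibration import (
    CalibrationConstants,
    average_cells,
    calibrate_trace,
    compute_ratio,
    estimate_calibration,
    invert_ratio,
    normalize_single_wavelength,
)
from magflux.cohort import generate_cohort, traces_from_table
from magflux.errors import CalibrationError, ConfigError, DataError
from magflux.observe import ObservationModel, Probe, forward_ratio
from magflux.presets import (
    DEFAULT_EXCHANGER,
    DEFAULT_LEAK,
    INIT_LOADED,
    MAGFURA2_OBS,
    MAGGREEN_OBS,
)
from magflux.protocols import append_calibration_episode, extrusion_protocol
from magflux.traces import QC_CLAMPED_HIGH, QC_CLAMPED_LOW, FluorescenceTrace, ConcentrationTrace


def _ratiometric_trace(r_values, f2=100.0, times=None):
    r_values = np.asarray(r_values, dtype=float)
    times = (np.arange(len(r_values)) * 20.0 if times is None
             else np.asarray(times))
    return FluorescenceTrace(
        cell_id="c0", probe=Probe.MAGFURA2, times=times,
        channels={"F1": r_values * f2, "F2": np.full_like(r_values, f2)},
    )


def test_ratio_is_channel_quotient():
    tr = _ratiometric_trace([1.0, 1.0, 2.0])
    np.testing.assert_allclose(compute_ratio(tr), [1.0, 1.0, 2.0])


def test_ratio_rejects_single_channel():
    tr = FluorescenceTrace(cell_id="c0", probe=Probe.MAGNESIUM_GREEN,
                           times=[0.0, 20.0], channels={"F": np.array([1.0, 2.0])})
    with pytest.raises(ConfigError):
        compute_ratio(tr)


def test_invert_ratio_hand_example(example_calib):
    """c = 1.5*0.5*(1.8-0.4)/(3.2-1.8) = 0.75 mM."""
    assert invert_ratio(1.8, example_calib) == pytest.approx(0.75, abs=1e-12)
    assert invert_ratio(example_calib.rmin, example_calib) == 0.0


def test_inversion_scales_linearly_with_kd(example_calib):
    sbfi_like = CalibrationConstants(probe=Probe.SBFI, kd=11.3, q=0.5,
                                     rmin=0.4, rmax=3.2)
    assert invert_ratio(1.8, sbfi_like) == pytest.approx(0.75 * 11.3 / 1.5)


def test_out_of_range_ratio_clamped_or_rejected(example_calib):
    eps = 0.02 * (example_calib.rmax - example_calib.rmin)
    c, flag = invert_ratio(example_calib.rmin - 0.1, example_calib,
                           return_flags=True)
    assert c == 0.0 and flag == QC_CLAMPED_LOW
    c, flag = invert_ratio(example_calib.rmax + 0.5 * eps, example_calib,
                           return_flags=True)
    assert flag == QC_CLAMPED_HIGH and np.isfinite(c)
    with pytest.raises(DataError, match="saturated|misfit"):
        invert_ratio(example_calib.rmax + 2 * eps, example_calib)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    kd=st.floats(0.1, 50.0),
    q=st.floats(0.05, 1.0),
    rmin=st.floats(0.05, 2.0),
    span=st.floats(0.5, 10.0),
    c=st.floats(0.0, 200.0),
)
def test_round_trip_and_monotonicity_property(kd, q, rmin, span, c):
    """invert o forward = identity; inversion strictly increasing in R."""
    calib = CalibrationConstants(probe=Probe.MAGFURA2, kd=kd, q=q,
                                 rmin=rmin, rmax=rmin + span)
    obs = ObservationModel(probe=Probe.MAGFURA2, kd=kd, rmin=rmin,
                           rmax=rmin + span, q=q, noise_sigma=0.0)
    r = forward_ratio(c, obs)
    if r < calib.rmax - 0.03 * span:  # clear of the clamp region
        assert invert_ratio(r, calib) == pytest.approx(c, abs=1e-9, rel=1e-9)
        r2 = min(r + 1e-3 * span, calib.rmax - 0.025 * span)
        if r2 > r:
            assert invert_ratio(r2, calib) > invert_ratio(r, calib)


def test_estimate_calibration_noiseless_round_trip():
    """Plateau means recover the ground-truth (rmin, rmax, q) exactly."""
    sched = append_calibration_episode(extrusion_protocol(), Probe.MAGFURA2)
    ds = generate_cohort("WT", 1, extrusion_protocol(), MAGFURA2_OBS, seed=3,
                         noise_sigma=0.0, jitter_cv=0.0, gain_cv=0.0)
    trace = traces_from_table(ds.traces)[0]
    calib = estimate_calibration(trace, sched)
    assert calib.rmin == pytest.approx(MAGFURA2_OBS.rmin, abs=1e-9)
    assert calib.rmax == pytest.approx(MAGFURA2_OBS.rmax, abs=1e-9)
    assert calib.q == pytest.approx(MAGFURA2_OBS.q, abs=1e-9)
    assert calib.kd == 1.5  # probe lookup, not the trace


def test_degenerate_plateaus_flag_failed_calibration():
    sched = append_calibration_episode(extrusion_protocol(), Probe.MAGFURA2)
    n = int(sched.t_end // 20) + 1
    trace = _ratiometric_trace(np.full(n, 1.7), times=np.arange(n) * 20.0)
    with pytest.raises(CalibrationError, match="rmax"):
        estimate_calibration(trace, sched)


def test_noisy_calibration_recovers_rmin_within_two_percent(rng):
    """sigma = 0.01, k = 3, 10 cells: mean recovered Rmin within 2 % of truth."""
    ds = generate_cohort("WT", 10, extrusion_protocol(), MAGFURA2_OBS, seed=11,
                         noise_sigma=0.01, jitter_cv=0.0, gain_cv=0.2)
    sched = ds.schedules[Probe.MAGFURA2]
    rmins = [estimate_calibration(tr, sched, k=3).rmin
             for tr in traces_from_table(ds.traces)]
    assert abs(np.mean(rmins) - MAGFURA2_OBS.rmin) / MAGFURA2_OBS.rmin < 0.02


def test_calibrate_trace_recovers_ground_truth_and_excludes_episode():
    ds = generate_cohort("WT", 1, extrusion_protocol(), MAGFURA2_OBS, seed=4,
                         noise_sigma=0.0, jitter_cv=0.0, gain_cv=0.0)
    sched = ds.schedules[Probe.MAGFURA2]
    trace = traces_from_table(ds.traces)[0]
    calib = estimate_calibration(trace, sched)
    ct = calibrate_trace(trace, calib, sched)
    assert ct.times.max() <= sched.experimental_end()
    traj = next(iter(ds.truth.values()))
    for t, c in zip(ct.times, ct.conc):
        assert c == pytest.approx(traj.mg_i[traj.index_at(t)], abs=1e-6)


def test_gain_invariance_of_calibrated_concentration():
    """Scaling both channels by any gamma > 0 leaves concentrations unchanged."""
    ds = generate_cohort("WT", 1, extrusion_protocol(), MAGFURA2_OBS, seed=9,
                         noise_sigma=0.0, jitter_cv=0.0, gain_cv=0.0)
    sched = ds.schedules[Probe.MAGFURA2]
    trace = traces_from_table(ds.traces)[0]
    for gamma in (0.1, 7.7):
        scaled = FluorescenceTrace(
            cell_id="c0", probe=trace.probe, times=trace.times,
            channels={k: v * gamma for k, v in trace.channels.items()},
        )
        calib = estimate_calibration(scaled, sched)
        ct0 = calibrate_trace(trace, estimate_calibration(trace, sched), sched)
        ct1 = calibrate_trace(scaled, calib, sched)
        np.testing.assert_allclose(ct1.conc, ct0.conc, atol=1e-10)


def test_mock_cohort_calibrates_flat():
    """Calibrated mock traces stay within 3 sd of the noise floor."""
    ds = generate_cohort("mock", 10, extrusion_protocol(), MAGFURA2_OBS,
                         seed=21, noise_sigma=0.01, gain_cv=0.2)
    sched = ds.schedules[Probe.MAGFURA2]
    concs = []
    for tr in traces_from_table(ds.traces):
        calib = estimate_calibration(tr, sched)
        ct = calibrate_trace(tr, calib, sched)
        post = ct.times >= sched.depletion_onset()
        concs.append(ct.conc[post])
    mean = np.mean(np.stack(concs), axis=0)
    drift = mean - mean.mean()
    noise_sd = np.std(np.stack(concs), axis=0).mean() / np.sqrt(len(concs))
    assert np.max(np.abs(drift)) < 3.5 * noise_sd


def test_normalize_single_wavelength_properties():
    ds = generate_cohort("WT", 1, extrusion_protocol(), MAGGREEN_OBS, seed=2,
                         noise_sigma=0.0, jitter_cv=0.0, gain_cv=0.0,
                         with_calibration=False)
    sched = ds.schedules[Probe.MAGNESIUM_GREEN]
    trace = traces_from_table(ds.traces)[0]
    rel = normalize_single_wavelength(trace, sched)
    pre = rel.times < sched.depletion_onset()
    assert rel.values[pre].mean() == pytest.approx(1.0)
    post = rel.values[~pre]
    assert np.all(np.diff(post) <= 1e-12)  # monotone decline after depletion
    # doubling the gain changes nothing
    doubled = FluorescenceTrace(cell_id="c0", probe=trace.probe,
                                times=trace.times,
                                channels={"F": trace.channels["F"] * 2.0})
    rel2 = normalize_single_wavelength(doubled, sched)
    np.testing.assert_allclose(rel2.values, rel.values, atol=1e-12)


def test_average_cells_single_and_affine_pairs():
    t = np.arange(5) * 20.0
    a = ConcentrationTrace(cell_id="a", ion="Mg", times=t, conc=np.arange(5.0))
    mean = average_cells([a])
    np.testing.assert_allclose(mean.conc, a.conc)
    assert np.all(mean.sem == 0.0)
    b = ConcentrationTrace(cell_id="b", ion="Mg", times=t,
                           conc=-np.arange(5.0) + 6.0)
    mean2 = average_cells([a, b])
    np.testing.assert_allclose(mean2.conc, np.full(5, 3.0))


def test_grand_mean_weighs_experiments_not_cells():
    """With unequal cell counts the grand mean is the mean of experiment means."""
    t = np.arange(3) * 20.0
    traces = [ConcentrationTrace(cell_id=f"a{i}", ion="Mg", times=t,
                                 conc=np.full(3, 1.0), experiment_id="e1")
              for i in range(9)]
    traces.append(ConcentrationTrace(cell_id="b0", ion="Mg", times=t,
                                     conc=np.full(3, 3.0), experiment_id="e2"))
    mean = average_cells(traces)
    np.testing.assert_allclose(mean.conc, np.full(3, 2.0))  # not 1.2
    assert mean.n == 2


def test_grid_mismatch_rejected():
    a = ConcentrationTrace(cell_id="a", ion="Mg", times=np.arange(3) * 20.0,
                           conc=np.ones(3))
    b = ConcentrationTrace(cell_id="b", ion="Mg", times=np.arange(4) * 20.0,
                           conc=np.ones(4))
    with pytest.raises(DataError, match="grid"):
        average_cells([a, b])
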