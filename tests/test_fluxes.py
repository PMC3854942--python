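"""Initial velocities, flux-ratio stoichiometry and Hill fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magflux.errors import DataError
from magflux.fluxes import (
    build_na_titration,
    cnnm4_flux_ratio,
    electroneutrality_check,
    fit_hill,
    hill_model,
    initial_velocity,
)
from magflux.protocols import extrusion_protocol
from magflux.traces import ConcentrationTrace

from _oracles import hill_grid_oracle


def _trace(conc, ion="Mg", t0=40.0):
    conc = np.asarray(conc, dtype=float)
    times = t0 + np.arange(len(conc)) * 20.0
    return ConcentrationTrace(cell_id="c", ion=ion, times=times, conc=conc)


class TestInitialVelocity:
    def test_two_point_difference_quotient(self):
        """Mg falling 3.0 -> 2.5 mM in 20 s is 1.5 mM/min of efflux."""
        est = initial_velocity(_trace([3.0, 2.5, 2.2]), t0=40.0)
        assert est.v0 == pytest.approx(1.5)
        assert initial_velocity(_trace([2.0, 2.0, 2.0]), t0=40.0).v0 == 0.0
        na = initial_velocity(_trace([10.0, 11.0], ion="Na"), t0=40.0)
        assert na.v0 == pytest.approx(3.0)  # influx positive

    def test_missing_sample_or_boundary_crossing(self):
        with pytest.raises(DataError, match="required"):
            initial_velocity(_trace([3.0, 2.5]), t0=40.0, w=30.0)
        sched = extrusion_protocol(baseline_s=40.0, depletion_s=120.0)
        with pytest.raises(DataError, match="boundary"):
            initial_velocity(_trace([3.0] * 12, t0=0.0), t0=20.0, w=40.0,
                             schedule=sched)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity_in_the_trace(self, a, b):
        c1 = np.array([3.0, 2.4, 2.1])
        c2 = np.array([1.0, 1.4, 1.9])
        combo = np.abs(a) * c1 + np.abs(b) * c2 + 5.0
        v_combo = initial_velocity(_trace(combo), t0=40.0).v0
        v1 = initial_velocity(_trace(c1), t0=40.0).v0
        v2 = initial_velocity(_trace(c2), t0=40.0).v0
        assert v_combo == pytest.approx(np.abs(a) * v1 + np.abs(b) * v2,
                                        abs=1e-9)


class TestFluxRatio:
    def test_control_free_and_control_subtracted(self):
        assert cnnm4_flux_ratio(4.0, 0.0, 2.0, 0.0).ratio == pytest.approx(2.0)
        assert cnnm4_flux_ratio(4.4, 0.2, 2.1, 0.1).ratio == pytest.approx(2.10)

    def test_undefined_without_transporter_dependent_efflux(self):
        with pytest.raises(DataError, match="undefined"):
            cnnm4_flux_ratio(1.0, 0.0, 0.5, 0.6)

    def test_electroneutrality_check(self):
        assert electroneutrality_check(cnnm4_flux_ratio(4, 0, 2, 0)) == 0.0
        r = cnnm4_flux_ratio(2.14, 0.0, 1.0, 0.0)
        assert electroneutrality_check(r) == pytest.approx(0.14)
        r = cnnm4_flux_ratio(1.0, 0.0, 1.0, 0.0)
        assert electroneutrality_check(r) == pytest.approx(-1.0)


class TestTitrationCurve:
    def test_single_level_single_replicate(self):
        curve = build_na_titration({39.0: [1.25]})
        assert len(curve) == 1
        assert curve.v0_mg[0] == 1.25 and curve.sem[0] == 0.0

    def test_levels_sorted_regardless_of_input_order(self):
        shuffled = {78.1: [2.0], 0.0: [0.0], 19.5: [0.4], 138.1: [2.4]}
        curve = build_na_titration(shuffled)
        assert np.all(np.diff(curve.na_out) > 0)
        np.testing.assert_allclose(curve.v0_mg, [0.0, 0.4, 2.0, 2.4])


LEVELS = np.array([0.0, 9.8, 19.5, 39.0, 78.1, 138.1])


class TestHillFit:
    def test_noiseless_recovery_to_machine_precision(self):
        y = hill_model(LEVELS, 3.0, 50.0, 2.0)
        fit = fit_hill(build_na_titration(
            {float(s): [float(v)] for s, v in zip(LEVELS, y)}))
        assert fit.converged
        assert fit.vmax == pytest.approx(3.0, abs=1e-6)
        assert fit.ka == pytest.approx(50.0, abs=1e-6)
        assert fit.n == pytest.approx(2.0, abs=1e-6)

    def test_too_few_levels_and_no_activity(self):
        with pytest.raises(DataError, match="4 distinct"):
            fit_hill(build_na_titration({0.0: [0.0], 50.0: [1.0]}))
        with pytest.raises(DataError, match="no Na"):
            fit_hill(build_na_titration({float(s): [0.0] for s in LEVELS}))

    def test_scale_equivariance(self):
        """Scaling all velocities scales vmax and leaves (ka, n) alone."""
        y = hill_model(LEVELS, 2.0, 35.0, 1.7)
        fit1 = fit_hill(build_na_titration(
            {float(s): [float(v)] for s, v in zip(LEVELS, y)}))
        fit2 = fit_hill(build_na_titration(
            {float(s): [float(v) * 7.5] for s, v in zip(LEVELS, y)}))
        assert fit2.vmax == pytest.approx(7.5 * fit1.vmax, rel=1e-6)
        assert fit2.ka == pytest.approx(fit1.ka, rel=1e-6)
        assert fit2.n == pytest.approx(fit1.n, rel=1e-6)

    def test_fit_beats_grid_oracle_on_noisy_curves(self, rng):
        """LS solution RSS never exceeds the 200x200 profiled-grid optimum."""
        for _ in range(5):
            vmax = rng.uniform(0.5, 4.0)
            ka = rng.uniform(5.0, 120.0)
            n = rng.uniform(0.6, 3.2)
            y = hill_model(LEVELS, vmax, ka, n) + 0.05 * rng.standard_normal(
                len(LEVELS))
            curve = build_na_titration(
                {float(s): [float(v)] for s, v in zip(LEVELS, y)})
            fit = fit_hill(curve)
            rss_oracle, *_ = hill_grid_oracle(LEVELS, y)
            assert fit.rss <= rss_oracle + 1e-12


def test_hill_exponent_recovery_from_noisy_titrations():
    """Median |n_hat - n_true| over 20 seeded replicates stays within 0.1."""
    from magflux.pipelines import run_titration
    from magflux.presets import DEFAULT_EXCHANGER

    errs = [abs(run_titration(3100 + s)["fit"].n - DEFAULT_EXCHANGER.n_hill)
            for s in range(20)]
    assert np.median(errs) <= 0.1
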