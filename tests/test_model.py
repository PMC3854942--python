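"""Whole-cell model: fluxes, conservation, reverse mode, charge bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest

from magflux.errors import NumericError, ScheduleError
from magflux.model import (
    CellState,
    ExchangerParams,
    LeakPumpParams,
    exchanger_flux,
    predict_membrane_current,
    simulate_cell,
)
from magflux.protocols import (
    BufferSegment,
    ProtocolSchedule,
    extrusion_protocol,
    loading_protocol,
    phases_protocol,
)


def test_all_fluxes_off_state_is_constant(no_leak, loaded, schedule):
    exch = ExchangerParams(vmax_efflux=3.0, ka_na=50.0, n_hill=2.0, km_mg=1.0,
                           activity_scale=0.0)
    traj = simulate_cell(exch, no_leak, schedule, loaded)
    assert np.all(traj.mg_i == loaded.mg_i)
    assert np.all(traj.na_i == loaded.na_i)
    assert np.all(traj.j_ex == 0.0)


def test_sodium_free_buffer_silences_the_exchanger(exch, no_leak, loaded):
    """NMDG substitution (na_out = 0) abolishes Mg2+ extrusion."""
    sched = phases_protocol()
    traj = simulate_cell(exch, no_leak, sched, loaded)
    seg3 = sched.segments[3]  # the -Mg -Na phase
    assert seg3.na_out == 0.0
    in_phase3 = (traj.times >= seg3.t_start) & (traj.times < seg3.t_end)
    assert np.all(traj.j_ex[in_phase3] == 0.0)
    mg3 = traj.mg_i[in_phase3]
    assert np.all(np.diff(mg3) == 0.0)  # nothing moves Mg without Na or channels


@pytest.mark.parametrize("stoich", [1, 2, 3])
def test_closed_system_conserves_stoichiometry(no_leak, loaded, schedule, stoich):
    """With leaks and pump off, stoich * d[Mg]i + d[Na]i = 0 at every sample.

    Checked against a fine-step (dt = 0.05 s) integration to rule out
    step-size artifacts.
    """
    exch = ExchangerParams(vmax_efflux=3.0, ka_na=50.0, n_hill=2.0, km_mg=1.0,
                           stoich=stoich)
    for dt in (1.0, 0.05):
        traj = simulate_cell(exch, no_leak, schedule, loaded, dt=dt)
        resid = stoich * (traj.mg_i - traj.mg_i[0]) + (traj.na_i - traj.na_i[0])
        assert np.max(np.abs(resid)) < 1e-9
        # the exchanger actually ran
        assert traj.mg_i[-1] < loaded.mg_i - 0.1


def test_negative_concentration_aborts(no_leak, loaded, schedule):
    exch = ExchangerParams(vmax_efflux=4000.0, ka_na=50.0, n_hill=2.0,
                           km_mg=1e-6)
    with pytest.raises(NumericError, match="negative concentration"):
        simulate_cell(exch, no_leak, schedule, loaded, dt=5.0)


def test_non_contiguous_schedule_rejected():
    with pytest.raises(ScheduleError, match="gap"):
        ProtocolSchedule((
            BufferSegment(0, 100, mg_out=40, na_out=78.1),
            BufferSegment(120, 200, mg_out=0, na_out=138.1),
        ))


def test_reverse_mode_loads_and_unloads_mg():
    """In Na+-free, 10 mM Mg2+ buffer the exchanger runs backwards.

    Expressing cells accumulate Mg2+ above their mock counterpart and
    return toward baseline once Na+ is restored and Mg2+ removed.
    """
    from magflux.presets import DEFAULT_EXCHANGER, DEFAULT_LEAK, INIT_UNLOADED

    sched = loading_protocol(mg_load=10.0, na_load=0.0)
    init = INIT_UNLOADED
    wt = simulate_cell(DEFAULT_EXCHANGER, DEFAULT_LEAK, sched, init)
    mock = simulate_cell(replace(DEFAULT_EXCHANGER, activity_scale=0.0),
                         DEFAULT_LEAK, sched, init)
    end_load = sched.segments[1].t_end
    i = wt.index_at(end_load)
    assert wt.mg_i[i] > mock.mg_i[i] > init.mg_i  # reverse exchange adds Mg
    assert np.any(wt.j_ex[: i + 1] < 0.0)          # flux actually reversed
    assert wt.mg_i[-1] < wt.mg_i[i]                # efflux resumes with Na+


def test_reverse_mode_requires_inward_mg_gradient(exch):
    seg = BufferSegment(0, 10, mg_out=0.0, na_out=0.0)
    assert exchanger_flux(2.0, 10.0, seg, exch) == 0.0  # no Mg out, no Na in


def test_membrane_current_charge_balance(exch, no_leak, loaded, schedule):
    """2:1 exchange is electroneutral; 1:1 and 3:1 are mirror images."""
    currents = {}
    for stoich in (1, 2, 3):
        e = replace(exch, stoich=stoich)
        traj = simulate_cell(e, no_leak, schedule, loaded)
        currents[stoich] = predict_membrane_current(traj, e)
    assert np.all(currents[2] == 0.0)
    assert np.any(currents[3] != 0.0)
    # stoich enters only the charge factor, the flux is identical
    np.testing.assert_allclose(currents[1], -currents[3], rtol=1e-12)


def test_noiseless_flux_monotone_in_extracellular_na(exch, no_leak, loaded):
    """Mg2+ efflux during depletion is nondecreasing in buffer Na+."""
    from magflux.protocols import titration_protocol

    drops = []
    for na in (0.0, 9.8, 19.5, 39.0, 78.1, 138.1):
        sched = titration_protocol(na)
        traj = simulate_cell(exch, no_leak, sched, loaded)
        t0 = sched.depletion_onset()
        drops.append(traj.mg_i[traj.index_at(t0)]
                     - traj.mg_i[traj.index_at(t0 + 20.0)])
    assert np.all(np.diff(drops) >= -1e-12)
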