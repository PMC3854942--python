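"""Packaged fixture parameters for the shipped experiment presets.

The kinetic constants are conventions chosen to reproduce the published
phenomenology at the bench scale of the assays: a Hill exponent of 1.90
for the Na+ dependence, near-complete Mg2+ extrusion within 1-2 min of
depletion, channel-mediated refill in 40 mM Mg2+ that outpaces
extrusion, and residual mutant activity of 5 %.  See docs/methods.md
for the rationale behind each default.
"""

from __future__ import annotations

from .errors import ConfigError
from .model import CellState, ExchangerParams, LeakPumpParams
from .observe import ObservationModel, Probe

#: exchanger kinetics of the reference fixture
DEFAULT_EXCHANGER = ExchangerParams(
    vmax_efflux=6.0,   # mM/min at saturating Na+
    ka_na=30.0,        # mM
    n_hill=1.90,
    km_mg=0.6,         # mM
    stoich=2,
    activity_scale=1.0,
)

#: background fluxes; Mg channel sized so 40 mM Mg2+ refills loaded cells
DEFAULT_LEAK = LeakPumpParams(
    p_mg_channel=0.10,                       # min^-1
    cohex_inhibition={1.0: 0.4, 3.0: 0.15},  # residual at 1 / 3 mM CoHex
    p_na_leak=0.002,                         # min^-1
    na_pump_rate=0.002,                      # min^-1
    na_baseline=10.0,                        # mM
)

#: state after 40 mM Mg2+ loading / resting (unloaded) state
INIT_LOADED = CellState(mg_i=3.0, na_i=10.0)
INIT_UNLOADED = CellState(mg_i=0.8, na_i=10.0)

#: residual activity by transfection condition (Jalili mutants ~5 %)
CONDITION_ACTIVITY = {"WT": 1.0, "mock": 0.0, "S200Y": 0.05, "L324P": 0.05}

#: ground-truth observation models (calibration constants are fixture
#: choices with realistic dynamic ranges; Kd values are the literature
#: constants the calibration stage also uses)
MAGFURA2_OBS = ObservationModel(
    probe=Probe.MAGFURA2, kd=1.5, rmin=0.25, rmax=4.2, q=0.93,
    noise_sigma=0.01, sample_interval=20.0,
)
SBFI_OBS = ObservationModel(
    probe=Probe.SBFI, kd=11.3, rmin=0.2, rmax=3.6, q=0.9,
    noise_sigma=0.01, sample_interval=20.0,
)
MAGGREEN_OBS = ObservationModel(
    probe=Probe.MAGNESIUM_GREEN, kd=1.0, rmin=1.0, rmax=6.0, q=1.0,
    noise_sigma=0.01, sample_interval=20.0,
)

OBS_BY_PROBE = {
    Probe.MAGFURA2: MAGFURA2_OBS,
    Probe.SBFI: SBFI_OBS,
    Probe.MAGNESIUM_GREEN: MAGGREEN_OBS,
}

#: default Na+ titration levels (mM): fractions of the two buffer Na+
#: concentrations (78.1 loading, 138.1 Mg2+-free)
TITRATION_LEVELS = (0.0, 9.8, 19.5, 39.0, 78.1, 138.1)

#: per-cell log-normal variability (coefficient of variation)
DEFAULT_JITTER_CV = 0.10   # on vmax_efflux
DEFAULT_GAIN_CV = 0.2      # on optical gain

#: charge-bookkeeping cell geometry
DEFAULT_CAPACITANCE_PF = 20.0
DEFAULT_VOLUME_PL = 2.0

#: seed of the frozen fixtures used by the test suite
FIXTURE_SEED = 20131205

#: analysis defaults
V0_WINDOW_S = 20.0
PLATEAU_K = 3


def condition_activity(condition: str) -> float:
    try:
        return CONDITION_ACTIVITY[condition]
    except KeyError:
        raise ConfigError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(CONDITION_ACTIVITY)}"
        ) from None
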