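"""Whole-cell model of Na+-coupled Mg2+ extrusion.

Two state variables: free intracellular Mg2+ and Na+ (mM).  The
exchanger extrudes Mg2+ with Hill-type activation by extracellular Na+
and Michaelis saturation in intracellular Mg2+:

    J_ex = a * Vmax * [Na+]o^n / (K_A^n + [Na+]o^n) * [Mg2+]i / (Km + [Mg2+]i)

(positive = Mg2+ efflux, mM/min; ``a`` is the condition activity scale).
Per transport cycle ``stoich`` Na+ move inward per Mg2+ extruded, so
d[Na+]i/dt carries a ``stoich * J_ex`` term.  The exchanger reverses
(Mg2+ influx, Na+ efflux) when the Na+ gradient is outward and the Mg2+
gradient inward, with the same Vmax/Km scaffold driven by intracellular
Na+ and extracellular Mg2+.

Around the exchanger: a CoHex-inhibitable, inward-only Mg2+ channel leak
proportional to the inward gradient, a gradient-driven background Na+
influx, and a first-order Na+ pump relaxing [Na+]i toward its baseline.
Mg2+ buffering is ignored (free Mg2+ is the state variable); cytosolic
buffering would only rescale Vmax.

Integration is fixed-step RK4 (default dt = 1 s) for bit-reproducible
trajectories; the dynamics are non-stiff at these rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, NumericError
from .protocols import BufferSegment, Ionophore, ProtocolSchedule

FARADAY_C_PER_MOL = 96485.332


@dataclass(frozen=True)
class ExchangerParams:
    """Kinetic parameters of the Na+/Mg2+ exchanger.

    vmax_efflux : Mg2+ efflux rate at saturating Na+ (mM/min)
    ka_na       : half-activating extracellular Na+ (mM)
    n_hill      : Hill exponent of the Na+ dependence
    km_mg       : intracellular Mg2+ half-saturation (mM)
    stoich      : Na+ moved inward per Mg2+ extruded (1, 2 or 3)
    activity_scale : condition multiplier in [0, 1] (WT=1, mock=0,
        Jalili-syndrome mutants ~0.05)
    """

    vmax_efflux: float
    ka_na: float
    n_hill: float
    km_mg: float
    stoich: int = 2
    activity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.vmax_efflux < 0:
            raise ConfigError("vmax_efflux must be >= 0")
        if self.ka_na <= 0:
            raise ConfigError("ka_na must be > 0")
        if not 0.5 <= self.n_hill <= 4.0:
            raise ConfigError("n_hill must lie in [0.5, 4]")
        if self.km_mg <= 0:
            raise ConfigError("km_mg must be > 0")
        if self.stoich not in (1, 2, 3):
            raise ConfigError("stoich must be 1, 2 or 3")
        if not 0.0 <= self.activity_scale <= 1.0:
            raise ConfigError("activity_scale must lie in [0, 1]")


@dataclass(frozen=True)
class LeakPumpParams:
    """Non-exchanger background fluxes.

    p_mg_channel : Mg2+ channel permeability (min^-1), CoHex-inhibitable,
        conducts only down an inward gradient
    cohex_inhibition : residual channel activity by CoHex dose (mM -> fraction)
    p_na_leak    : background Na+ influx coefficient (min^-1)
    na_pump_rate : first-order Na+ extrusion toward baseline (min^-1)
    na_baseline  : resting [Na+]i the pump relaxes toward (mM)
    """

    p_mg_channel: float = 0.0
    cohex_inhibition: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.4, 3.0: 0.15}
    )
    p_na_leak: float = 0.0
    na_pump_rate: float = 0.0
    na_baseline: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p_mg_channel", "p_na_leak", "na_pump_rate", "na_baseline"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        residuals = [self.cohex_inhibition[k] for k in sorted(self.cohex_inhibition)]
        if any(not 0.0 <= r <= 1.0 for r in residuals):
            raise ConfigError("cohex residual fractions must lie in [0, 1]")
        if any(b > a for a, b in zip(residuals, residuals[1:])):
            # residual activity may not increase with dose
            raise ConfigError("cohex residuals must be nonincreasing in dose")

    def cohex_residual(self, dose_mm: float) -> float:
        if dose_mm == 0:
            return 1.0
        for known, residual in self.cohex_inhibition.items():
            if abs(known - dose_mm) < 1e-9:
                return residual
        raise ConfigError(f"no CoHex residual tabulated for {dose_mm} mM")


@dataclass(frozen=True)
class CellState:
    """Free intracellular Mg2+ and Na+ (mM)."""

    mg_i: float
    na_i: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mg_i) and np.isfinite(self.na_i)):
            raise NumericError("cell state must be finite")
        if self.mg_i < 0 or self.na_i < 0:
            raise NumericError("cell state concentrations must be >= 0")


@dataclass(frozen=True)
class CellTrajectory:
    """Time-indexed solution of the cell model (uniform ``dt`` grid)."""

    times: np.ndarray   # s
    mg_i: np.ndarray    # mM
    na_i: np.ndarray    # mM
    j_ex: np.ndarray    # exchanger flux, mM/min (positive = Mg2+ efflux)
    dt: float

    def index_at(self, t: float) -> int:
        idx = int(round((t - self.times[0]) / self.dt))
        if idx < 0 or idx >= len(self.times) or abs(self.times[idx] - t) > 1e-6:
            raise NumericError(f"time {t} s not on trajectory grid")
        return idx

    def state_at(self, t: float) -> CellState:
        i = self.index_at(t)
        return CellState(float(self.mg_i[i]), float(self.na_i[i]))


def _hill(s: float, ka: float, n: float) -> float:
    if s <= 0.0:
        return 0.0
    sn = s**n
    return sn / (ka**n + sn)


def exchanger_flux(mg_i: float, na_i: float, seg: BufferSegment,
                   exch: ExchangerParams) -> float:
    """Exchanger Mg2+ flux (mM/min, positive = efflux) in a given buffer.

    Reverse mode engages when extracellular Na+ is below intracellular
    Na+ *and* the Mg2+ gradient is inward; the reverse rate uses the
    same saturation scaffold driven by the outward Na+ gradient and
    extracellular Mg2+.
    """
    a = exch.activity_scale * exch.vmax_efflux
    if a == 0.0:
        return 0.0
    if seg.na_out < na_i and seg.mg_out > mg_i:
        return -a * _hill(na_i, exch.ka_na, exch.n_hill) * (
            seg.mg_out / (exch.km_mg + seg.mg_out)
        )
    return a * _hill(seg.na_out, exch.ka_na, exch.n_hill) * (
        mg_i / (exch.km_mg + mg_i)
    )


def _rhs(mg_i: float, na_i: float, seg: BufferSegment,
         exch: ExchangerParams, leak: LeakPumpParams) -> tuple[float, float]:
    """Time derivatives in mM/s."""
    j_ex = exchanger_flux(mg_i, na_i, seg, exch)
    # inward-only channel leak, CoHex-inhibitable
    grad = seg.mg_out - mg_i
    j_ch = leak.p_mg_channel * leak.cohex_residual(seg.cohex_mm) * max(grad, 0.0)
    # background Na+ influx down its gradient, first-order pump toward baseline
    j_na_leak = leak.p_na_leak * max(seg.na_out - na_i, 0.0)
    j_na_pump = leak.na_pump_rate * (na_i - leak.na_baseline)
    dmg = (-j_ex + j_ch) / 60.0
    dna = (exch.stoich * j_ex + j_na_leak - j_na_pump) / 60.0
    return dmg, dna


def simulate_cell(
    exch: ExchangerParams,
    leak: LeakPumpParams,
    schedule: ProtocolSchedule,
    init: CellState,
    dt: float = 1.0,
) -> CellTrajectory:
    """Integrate the cell model over a protocol schedule.

    Fixed-step RK4 with buffer composition piecewise constant per
    segment; steps never straddle segment boundaries.  Raises
    :class:`NumericError` if a step drives a concentration negative
    (beyond roundoff).
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    times = [schedule.t_start]
    mg = [init.mg_i]
    na = [init.na_i]
    t = schedule.t_start
    for seg in schedule.segments:
        n_steps = max(int(round(seg.duration / dt)), 1)
        h = seg.duration / n_steps
        for _ in range(n_steps):
            m, s = mg[-1], na[-1]
            k1 = _rhs(m, s, seg, exch, leak)
            k2 = _rhs(m + 0.5 * h * k1[0], s + 0.5 * h * k1[1], seg, exch, leak)
            k3 = _rhs(m + 0.5 * h * k2[0], s + 0.5 * h * k2[1], seg, exch, leak)
            k4 = _rhs(m + h * k3[0], s + h * k3[1], seg, exch, leak)
            m_new = m + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            s_new = s + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            if m_new < 0.0 or s_new < 0.0:
                if m_new < -1e-9 or s_new < -1e-9:
                    raise NumericError(
                        f"integration step produced a negative concentration at "
                        f"t={t + h:.1f} s (mg={m_new:.3e}, na={s_new:.3e}); "
                        f"reduce dt or check parameters"
                    )
                m_new = max(m_new, 0.0)
                s_new = max(s_new, 0.0)
            t += h
            times.append(t)
            mg.append(m_new)
            na.append(s_new)
    times_arr = np.asarray(times)
    mg_arr = np.asarray(mg)
    na_arr = np.asarray(na)
    j_ex = np.array([
        exchanger_flux(m, s, schedule.segment_at(tt), exch)
        for m, s, tt in zip(mg_arr, na_arr, times_arr)
    ])
    return CellTrajectory(times_arr, mg_arr, na_arr, j_ex, dt=dt)


def predict_membrane_current(
    traj: CellTrajectory,
    exch: ExchangerParams,
    cell_capacitance_pf: float = 20.0,
    cell_volume_pl: float = 2.0,
) -> np.ndarray:
    """Charge-balance membrane current density (pA/pF) of the exchanger.

    Each cycle moves ``stoich`` Na+ in (+1 each) and one Mg2+ out (-2),
    a net inward charge of ``stoich - 2`` elementary charges; for the
    electroneutral 2:1 exchanger the predicted current is identically
    zero.  Pure bookkeeping: no membrane-potential dynamics or GHK flux.
    """
    if cell_capacitance_pf <= 0 or cell_volume_pl <= 0:
        raise ConfigError("capacitance and volume must be > 0")
    net_charge = exch.stoich - 2
    if net_charge == 0:
        return np.zeros_like(traj.j_ex)
    # J [mmol/(L*min)] * V [pL] -> mol/s -> A -> pA
    mol_per_s = traj.j_ex * 1e-3 / 60.0 * cell_volume_pl * 1e-12
    current_pa = net_charge * FARADAY_C_PER_MOL * mol_per_s * 1e12
    return current_pa / cell_capacitance_pf
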