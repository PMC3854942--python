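"""Ratiometric calibration: fluorescence -> intracellular concentration.

The in-situ calibration relation for dual-excitation probes is

    c = Kd * Q * (R - Rmin) / (Rmax - R),        R = F1 / F2,

with Rmin/Rmax and Q = F2min/F2max measured from ionophore plateau
episodes appended to each experiment (A23187/EDTA and A23187/50 mM Mg2+
for Mag-fura2; gramicidin in Na+-free and Na+-replete buffer for SBFI),
and Kd from the literature (1.5 mM Mag-fura2, 11.3 mM SBFI).

Single-wavelength traces (Magnesium Green) are reported as relative
fluorescence F/F0 over the pre-depletion baseline instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import CalibrationError, ConfigError, DataError
from .observe import PROBE_KD, Probe
from .protocols import ProtocolSchedule, Ionophore, ZERO_CLAMPS, SAT_CLAMPS
from .traces import (
    QC_CLAMPED_HIGH,
    QC_CLAMPED_LOW,
    QC_OK,
    ConcentrationTrace,
    FluorescenceTrace,
    MeanTrace,
    RelativeTrace,
)


@dataclass(frozen=True)
class CalibrationConstants:
    """Probe calibration: Kd (mM), Q, Rmin, Rmax."""

    probe: Probe
    kd: float
    q: float
    rmin: float
    rmax: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe", Probe(self.probe))
        if self.kd <= 0 or self.q <= 0:
            raise CalibrationError("kd and q must be > 0")
        if not self.rmax > self.rmin:
            raise CalibrationError(
                f"failed calibration: rmax ({self.rmax:.4g}) <= rmin ({self.rmin:.4g})"
            )


def compute_ratio(trace: FluorescenceTrace) -> np.ndarray:
    """Excitation ratio R(t) = F1(t)/F2(t) on the trace's grid."""
    if not trace.is_ratiometric:
        raise ConfigError("ratio requires a two-channel (ratiometric) trace")
    f2 = trace.channels["F2"]
    if np.any(f2 <= 0):
        raise DataError("F2 must be positive everywhere")
    return trace.channels["F1"] / f2


def _plateau_indices(trace: FluorescenceTrace, schedule: ProtocolSchedule,
                     iono: Ionophore, k: int) -> np.ndarray:
    seg = next((s for s in schedule.segments if s.ionophore is iono), None)
    if seg is None:
        raise CalibrationError(f"schedule has no {iono.value} plateau segment")
    # boundary samples belong to the *later* segment, except the final one
    mask = (trace.times >= seg.t_start - 1e-9) & (trace.times < seg.t_end - 1e-9)
    if seg is schedule.segments[-1]:
        mask |= np.isclose(trace.times, seg.t_end, atol=1e-9)
    idx = np.nonzero(mask)[0]
    if len(idx) < k:
        raise CalibrationError(
            f"{iono.value} plateau has {len(idx)} samples; need at least {k}"
        )
    return idx[-k:]


def estimate_calibration(
    trace: FluorescenceTrace,
    schedule: ProtocolSchedule,
    k: int = 3,
    kd: Optional[float] = None,
) -> CalibrationConstants:
    """Estimate (Rmin, Rmax, Q) from the trace's ionophore plateaus.

    Plateau values are the means of the final ``k`` samples of the
    zero-ion and saturating segments; Q is the ratio of mean F2 over the
    zero-ion plateau to mean F2 over the saturating plateau; Kd comes
    from the probe lookup unless overridden.
    """
    probe = trace.probe
    if not probe.is_ratiometric:
        raise ConfigError("in-situ calibration requires a ratiometric probe")
    zero_iono = next(i for i, ion in ZERO_CLAMPS.items() if ion == probe.ion)
    sat_iono = next(i for i, ion in SAT_CLAMPS.items() if ion == probe.ion)
    idx_zero = _plateau_indices(trace, schedule, zero_iono, k)
    idx_sat = _plateau_indices(trace, schedule, sat_iono, k)
    r = compute_ratio(trace)
    rmin = float(np.mean(r[idx_zero]))
    rmax = float(np.mean(r[idx_sat]))
    f2 = trace.channels["F2"]
    q = float(np.mean(f2[idx_zero]) / np.mean(f2[idx_sat]))
    if kd is None:
        kd = PROBE_KD[probe]
    return CalibrationConstants(probe=probe, kd=kd, q=q, rmin=rmin, rmax=rmax)


def invert_ratio(
    r: Union[float, np.ndarray],
    calib: CalibrationConstants,
    epsilon: Optional[float] = None,
    return_flags: bool = False,
):
    """Invert the calibration relation, c = Kd*Q*(R - Rmin)/(Rmax - R).

    R <= Rmin maps to 0 mM (flagged); R within ``epsilon`` of/above Rmax
    (default 2 % of the dynamic range) is clamped to the epsilon
    boundary below Rmax (flagged); R beyond Rmax + epsilon raises
    :class:`DataError`, signalling probe saturation or a misfit
    calibration.
    """
    if epsilon is None:
        epsilon = 0.02 * (calib.rmax - calib.rmin)
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr > calib.rmax + epsilon):
        raise DataError(
            f"ratio {float(np.max(r_arr)):.4g} far above rmax {calib.rmax:.4g}: "
            "probe saturated or calibration misfit"
        )
    flags = np.full(r_arr.shape, QC_OK, dtype=np.uint8)
    low = r_arr <= calib.rmin
    high = r_arr >= calib.rmax - epsilon
    flags[low] = QC_CLAMPED_LOW
    flags[high & ~low] = QC_CLAMPED_HIGH
    r_eff = np.clip(r_arr, calib.rmin, calib.rmax - epsilon)
    conc = calib.kd * calib.q * (r_eff - calib.rmin) / (calib.rmax - r_eff)
    if np.isscalar(r) or np.asarray(r).ndim == 0:
        c = float(conc[0])
        return (c, int(flags[0])) if return_flags else c
    return (conc, flags) if return_flags else conc


def calibrate_trace(
    trace: FluorescenceTrace,
    calib: CalibrationConstants,
    schedule: ProtocolSchedule,
    epsilon: Optional[float] = None,
) -> ConcentrationTrace:
    """Pointwise calibrated concentration over the experimental segments.

    Calibration-episode samples are excluded from the output; qc flags
    mark out-of-range samples that were clamped.
    """
    if trace.probe is not calib.probe:
        raise ConfigError("trace and calibration constants use different probes")
    r = compute_ratio(trace)
    t_exp = schedule.experimental_end()
    # the sample on the boundary belongs to the first ionophore segment
    if schedule.has_ionophore():
        mask = trace.times < t_exp - 1e-9
    else:
        mask = trace.times <= t_exp + 1e-9
    if mask.sum() < 2:
        raise DataError("no experimental samples to calibrate")
    conc, flags = invert_ratio(r[mask], calib, epsilon=epsilon, return_flags=True)
    return ConcentrationTrace(
        cell_id=trace.cell_id,
        ion=trace.probe.ion,
        times=trace.times[mask],
        conc=conc,
        qc_flags=flags,
        experiment_id=trace.experiment_id,
        condition=trace.condition,
    )


def normalize_single_wavelength(
    trace: FluorescenceTrace, schedule: ProtocolSchedule
) -> RelativeTrace:
    """Relative fluorescence F/F0 for single-wavelength probes.

    F0 is the mean over the baseline window, i.e. all samples before the
    schedule's depletion onset; gain-invariant by construction.
    """
    if trace.is_ratiometric:
        raise ConfigError("F/F0 normalization applies to single-channel traces")
    onset = schedule.depletion_onset()
    f = trace.channels["F"]
    baseline = trace.times < onset - 1e-9
    if not np.any(baseline):
        raise DataError("empty baseline window before depletion onset")
    return RelativeTrace(
        cell_id=trace.cell_id,
        times=trace.times,
        values=f / float(np.mean(f[baseline])),
        experiment_id=trace.experiment_id,
        condition=trace.condition,
    )


def average_cells(
    traces: Sequence[Union[ConcentrationTrace, RelativeTrace]],
) -> MeanTrace:
    """Pointwise mean trace with per-time s.e.m.

    When traces carry experiment labels, averaging is hierarchical:
    cells are first averaged within each experiment and the grand mean
    and s.e.m. are taken across experiment means (so experiments with
    unequal cell counts weigh equally).  Without labels all traces weigh
    equally.
    """
    if not traces:
        raise DataError("average_cells needs at least one trace")
    times = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise DataError("traces must share a common time grid")
    ion = getattr(traces[0], "ion", "Mg")
    labels = [getattr(tr, "experiment_id", None) for tr in traces]
    if all(lbl is not None for lbl in labels) and len(set(labels)) > 1:
        groups: dict[str, list[np.ndarray]] = {}
        for tr, lbl in zip(traces, labels):
            groups.setdefault(lbl, []).append(tr.conc)
        units = np.stack([np.mean(np.stack(g), axis=0) for g in groups.values()])
    else:
        units = np.stack([tr.conc for tr in traces])
    mean = units.mean(axis=0)
    n = units.shape[0]
    sem = units.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return MeanTrace(times=times, conc=mean, sem=sem, n=n, ion=ion)
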