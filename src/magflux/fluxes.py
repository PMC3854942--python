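"""Initial-velocity flux estimation, stoichiometry and Hill analysis.

The initial velocity V0 is the two-point difference quotient of the
calibrated concentration over the first sampling interval after Mg2+
depletion (0-20 s), signed so that Mg2+ efflux and Na+ influx are
positive, in mM/min.  The transporter-dependent Na+/Mg2+ flux ratio is
the control-subtracted ratio

    ratio = (V0(Na)_expressing - V0(Na)_control)
          / (V0(Mg)_expressing - V0(Mg)_control),

which equals the transport stoichiometry for an ideal exchanger; a
value of 2 corresponds to electroneutral 2 Na+ : 1 Mg2+ exchange.  The
Na+ dependence of V0(Mg) is summarized by a Hill fit

    V0 = Vmax * S^n / (K_A^n + S^n)

estimated by multi-start nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, DataError, NumericError
from .protocols import ProtocolSchedule
from .traces import ConcentrationTrace, MeanTrace, RelativeTrace

Trace = Union[ConcentrationTrace, MeanTrace, RelativeTrace]


@dataclass(frozen=True)
class FluxEstimate:
    """Initial velocity of one trace over a fixed window."""

    cell_or_group_id: str
    ion: str
    v0: float                      # mM/min; positive = Mg efflux / Na influx
    window: tuple[float, float]    # (t0, t0 + w), seconds
    condition: Optional[str] = None


@dataclass(frozen=True)
class NaTitrationCurve:
    """V0(Mg) versus extracellular Na+, with replicate scatter."""

    na_out: np.ndarray      # mM, sorted ascending, distinct
    v0_mg: np.ndarray       # mM/min, mean over replicates
    sem: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        for name in ("na_out", "v0_mg", "sem", "n_replicates"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.na_out < 0):
            raise DataError("na_out levels must be >= 0")
        if len(np.unique(self.na_out)) != len(self.na_out):
            raise DataError("na_out levels must be distinct")

    def __len__(self) -> int:
        return len(self.na_out)


@dataclass(frozen=True)
class HillFitResult:
    """Hill-equation fit of a Na+ titration curve."""

    vmax: float
    ka: float
    n: float
    rss: float
    converged: bool
    se_vmax: float = float("nan")
    se_ka: float = float("nan")
    se_n: float = float("nan")


@dataclass(frozen=True)
class StoichiometryResult:
    """Control-subtracted Na+/Mg2+ flux ratio and its components."""

    ratio: float
    v0_na_expressing: float
    v0_na_control: float
    v0_mg_expressing: float
    v0_mg_control: float
    n_experiments: int = 1


def initial_velocity(
    ctrace: Trace,
    t0: float,
    w: float = 20.0,
    schedule: Optional[ProtocolSchedule] = None,
    label: Optional[str] = None,
) -> FluxEstimate:
    """Two-point initial velocity over [t0, t0 + w].

    ``t0`` is normally the depletion onset from the schedule.  The
    velocity is sign*(c(t0+w) - c(t0)) / w in mM/min with sign -1 for
    Mg2+ (efflux positive) and +1 for Na+ (influx positive).  Raises if
    either sample is missing or the window crosses a buffer-segment
    boundary.
    """
    if w <= 0:
        raise ConfigError("window length must be > 0")
    times = ctrace.times
    hits0 = np.nonzero(np.isclose(times, t0, atol=1e-6))[0]
    hits1 = np.nonzero(np.isclose(times, t0 + w, atol=1e-6))[0]
    if len(hits0) != 1 or len(hits1) != 1:
        raise DataError(f"samples at t={t0} and t={t0 + w} s are required")
    if schedule is not None:
        seg = schedule.segment_at(t0)
        if not seg.contains(t0 + w):
            raise DataError("velocity window crosses a buffer-segment boundary")
    ion = getattr(ctrace, "ion", "Mg")
    sign = -1.0 if ion == "Mg" else 1.0
    c0 = float(ctrace.conc[hits0[0]])
    c1 = float(ctrace.conc[hits1[0]])
    v0 = sign * (c1 - c0) / w * 60.0
    return FluxEstimate(
        cell_or_group_id=label or getattr(ctrace, "cell_id", "mean"),
        ion=ion, v0=v0, window=(t0, t0 + w),
        condition=getattr(ctrace, "condition", None),
    )


def cnnm4_flux_ratio(
    v0_na_expressing: float,
    v0_na_control: float,
    v0_mg_expressing: float,
    v0_mg_control: float,
    n_experiments: int = 1,
) -> StoichiometryResult:
    """Transporter-dependent Na+ influx / Mg2+ efflux ratio.

    Both numerator and denominator are control-subtracted so that
    background leaks common to expressing and control cells cancel.
    Raises :class:`DataError` when the control-subtracted Mg2+ efflux is
    not positive (no transporter-dependent extrusion: ratio undefined).
    """
    denom = v0_mg_expressing - v0_mg_control
    if denom <= 0:
        raise DataError(
            "flux ratio undefined: no transporter-dependent Mg2+ efflux "
            f"(denominator {denom:.4g} mM/min)"
        )
    ratio = (v0_na_expressing - v0_na_control) / denom
    return StoichiometryResult(
        ratio=ratio,
        v0_na_expressing=v0_na_expressing,
        v0_na_control=v0_na_control,
        v0_mg_expressing=v0_mg_expressing,
        v0_mg_control=v0_mg_control,
        n_experiments=n_experiments,
    )


def electroneutrality_check(result: StoichiometryResult) -> float:
    """Net inward charge per Mg2+ extruded, in elementary charges.

    ratio*(+1) for the Na+ entering plus (-2) for the Mg2+ leaving; zero
    iff the measured ratio equals the electroneutral 2:1 stoichiometry.
    """
    return result.ratio * 1.0 - 2.0


def build_na_titration(
    v0_by_level: Mapping[float, Sequence[float]],
) -> NaTitrationCurve:
    """Assemble a titration curve from per-level replicate velocities.

    Keys are extracellular Na+ levels (mM), values the replicate
    (experiment-level) V0(Mg) estimates; levels are sorted ascending.
    """
    if not v0_by_level:
        raise DataError("titration needs at least one Na+ level")
    levels = sorted(v0_by_level)
    means, sems, ns = [], [], []
    for lv in levels:
        vals = np.asarray(list(v0_by_level[lv]), dtype=float)
        if vals.size == 0:
            raise DataError(f"no replicates at Na+ = {lv} mM")
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    return NaTitrationCurve(np.array(levels, dtype=float), np.array(means),
                            np.array(sems), np.array(ns))


def hill_model(s, vmax: float, ka: float, n: float):
    """V = Vmax * S^n / (K_A^n + S^n); V(0) = 0."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s > 0
    sn = s[pos] ** n
    out[pos] = vmax * sn / (ka**n + sn)
    return out


_KA_START_RANGE = (1.0, 300.0)
_N_BOUNDS = (0.5, 4.0)


def fit_hill(
    curve: NaTitrationCurve,
    starts: Optional[Sequence[tuple[float, float]]] = None,
) -> HillFitResult:
    """Multi-start least-squares Hill fit of a titration curve.

    Starting points cover a 5x5 log-grid over K_A in [1, 300] mM and n
    in [0.5, 4] with Vmax initialized at max(V0); the best converged
    solution by residual sum of squares wins (ties broken by lower n).
    Standard errors come from the Gauss-Newton curvature at the optimum.
    Raises on fewer than 4 distinct levels, on an all-zero curve (no
    activity to fit) or if no start converges.
    """
    s = curve.na_out
    y = curve.v0_mg
    if len(s) < 4:
        raise DataError("Hill fit needs at least 4 distinct Na+ levels")
    vscale = float(np.max(np.abs(y)))
    if vscale <= 0 or np.allclose(y, 0.0, atol=1e-12):
        raise DataError("all velocities are zero: no Na+-dependent activity to fit")
    if starts is None:
        kas = np.geomspace(*_KA_START_RANGE, 5)
        ns = np.geomspace(*_N_BOUNDS, 5)
        starts = [(ka, n) for ka in kas for n in ns]
    v0_init = float(np.max(y))

    def residuals(theta):
        vmax, log_ka, n = theta
        return hill_model(s, vmax, np.exp(log_ka), n) - y

    lb = [0.0, np.log(1e-3), _N_BOUNDS[0]]
    ub = [np.inf, np.log(1e5), _N_BOUNDS[1]]
    best = None
    for ka0, n0 in starts:
        theta0 = [max(v0_init, 1e-12), np.log(ka0), n0]
        try:
            res = least_squares(residuals, theta0, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(2.0 * res.cost)
        cand = (rss, float(res.x[2]), res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise NumericError("Hill fit did not converge from any start")
    rss, _, res = best
    vmax, log_ka, n = res.x
    ka = float(np.exp(log_ka))
    dof = max(len(s) - 3, 1)
    se = [float("nan")] * 3
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * rss / dof
        se_raw = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        # delta method for ka = exp(log_ka)
        se = [se_raw[0], se_raw[1] * ka, se_raw[2]]
    except np.linalg.LinAlgError:
        pass
    return HillFitResult(vmax=float(vmax), ka=ka, n=float(n), rss=rss,
                         converged=True, se_vmax=se[0], se_ka=se[1], se_n=se[2])
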