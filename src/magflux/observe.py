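"""Forward observation model: ion trajectories -> fluorescence traces.

For ratiometric probes (Mag-fura2 for Mg2+, SBFI for Na+) the noiseless
excitation ratio R = F1/F2 at free-ion concentration ``c`` is

    R(c) = (Rmin * Kd * Q + Rmax * c) / (Kd * Q + c),

the exact inverse of the in-situ calibration relation
c = Kd*Q*(R - Rmin)/(Rmax - R).  The two channels are emitted separately
with F2(c) interpolating between Q (ion-free) and 1 (saturation), so
that F2min/F2max = Q, and F1 = R * F2; multiplicative Gaussian noise is
applied independently per channel per frame.  Single-wavelength probes
(Magnesium Green) emit one monotone-saturating channel.

During ionophore calibration segments the observed ion is clamped to
zero or saturation, emulating A23187/EDTA, A23187/50 mM Mg2+ and
gramicidin episodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Union

import numpy as np

from .errors import ConfigError, DataError
from .model import CellTrajectory
from .protocols import Ionophore, ProtocolSchedule
from .traces import FluorescenceTrace


class Probe(str, Enum):
    MAGNESIUM_GREEN = "magnesium_green"
    MAGFURA2 = "mag_fura2"
    SBFI = "sbfi"

    @property
    def ion(self) -> str:
        return "Na" if self is Probe.SBFI else "Mg"

    @property
    def is_ratiometric(self) -> bool:
        return self is not Probe.MAGNESIUM_GREEN


#: literature dissociation constants (mM) used by the calibration stage
PROBE_KD = {Probe.MAGFURA2: 1.5, Probe.SBFI: 11.3}


@dataclass(frozen=True)
class ObservationModel:
    """Probe and acquisition parameters for one imaging channel set.

    ``rmin``/``rmax``/``q`` are the ground-truth calibration constants
    of the ratiometric relation (for Magnesium Green, ``rmin``/``rmax``
    are the ion-free and saturating fluorescence levels of the single
    channel and ``q`` is unused).  ``noise_sigma`` is the multiplicative
    Gaussian s.d. per channel per frame; ``sample_interval`` is the
    acquisition period in seconds; ``bleach_rate`` (min^-1) applies an
    exponential decay to every channel.
    """

    probe: Probe
    kd: float
    rmin: float
    rmax: float
    q: float = 1.0
    noise_sigma: float = 0.01
    sample_interval: float = 20.0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe", Probe(self.probe))
        if self.kd <= 0:
            raise ConfigError("kd must be > 0")
        if not self.rmax > self.rmin > 0:
            raise ConfigError("need rmax > rmin > 0")
        if not 0.0 < self.q <= 1.0:
            raise ConfigError("q must lie in (0, 1]")
        if self.sample_interval <= 0:
            raise ConfigError("sample_interval must be > 0")
        if self.noise_sigma < 0 or self.bleach_rate < 0:
            raise ConfigError("noise_sigma and bleach_rate must be >= 0")


def forward_ratio(c: Union[float, np.ndarray], obs: ObservationModel):
    """Noiseless excitation ratio R(c); R(0) = Rmin, R(inf) = Rmax."""
    a = obs.kd * obs.q
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.where(np.isinf(c), obs.rmax, (obs.rmin * a + obs.rmax * c) / (a + c))
    return float(r) if r.ndim == 0 else r


def forward_f2(c: Union[float, np.ndarray], obs: ObservationModel):
    """Noiseless F2 channel shape; F2(0)/F2(inf) = Q."""
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        f2 = np.where(np.isinf(c), 1.0, (obs.q * obs.kd + c) / (obs.kd + c))
    return float(f2) if f2.ndim == 0 else f2


def forward_single(c: Union[float, np.ndarray], obs: ObservationModel):
    """Noiseless single-wavelength intensity, monotone saturating in c."""
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        f = np.where(np.isinf(c), obs.rmax,
                     (obs.rmin * obs.kd + obs.rmax * c) / (obs.kd + c))
    return float(f) if f.ndim == 0 else f


def _clamped_concentration(traj: CellTrajectory, schedule: ProtocolSchedule,
                           probe: Probe, times: np.ndarray) -> np.ndarray:
    """Observed free-ion series: trajectory state, with ionophore clamps."""
    out = np.empty_like(times)
    for i, t in enumerate(times):
        seg = schedule.segment_at(t)
        iono = seg.ionophore
        if iono is Ionophore.NONE:
            idx = traj.index_at(t)
            out[i] = traj.mg_i[idx] if probe.ion == "Mg" else traj.na_i[idx]
        elif iono in (Ionophore.MG_FREE, Ionophore.NA_FREE):
            if (iono is Ionophore.MG_FREE) != (probe.ion == "Mg"):
                raise ConfigError(
                    f"ionophore episode {iono.value} does not match probe {probe.value}"
                )
            out[i] = 0.0
        else:  # saturating plateau
            if (iono is Ionophore.MG_SAT) != (probe.ion == "Mg"):
                raise ConfigError(
                    f"ionophore episode {iono.value} does not match probe {probe.value}"
                )
            out[i] = math.inf
    return out


def observe_fluorescence(
    traj: CellTrajectory,
    obs: ObservationModel,
    schedule: ProtocolSchedule,
    seed: Union[int, np.random.Generator],
    gain: float = 1.0,
    cell_id: str = "cell",
    experiment_id: Optional[str] = None,
    condition: Optional[str] = None,
) -> FluorescenceTrace:
    """Sample a trajectory through the probe's forward model.

    ``seed`` may be an integer or a ``numpy.random.Generator``; a fixed
    seed reproduces the trace exactly.  ``gain`` models the arbitrary
    per-cell illumination/collection factor shared by both channels.
    """
    if traj.dt > obs.sample_interval + 1e-9:
        raise ConfigError("simulation dt must not exceed the sample interval")
    if gain <= 0:
        raise ConfigError("gain must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t0, t1 = schedule.t_start, schedule.t_end
    n = int(math.floor((t1 - t0) / obs.sample_interval + 1e-9)) + 1
    times = t0 + obs.sample_interval * np.arange(n)
    c = _clamped_concentration(traj, schedule, obs.probe, times)
    bleach = np.exp(-obs.bleach_rate * (times - t0) / 60.0)

    def noisy(f: np.ndarray) -> np.ndarray:
        if obs.noise_sigma == 0:
            return np.maximum(f, 1e-12)
        return np.maximum(f * (1.0 + obs.noise_sigma * rng.standard_normal(f.shape)),
                          1e-12)

    if obs.probe.is_ratiometric:
        f2 = gain * forward_f2(c, obs) * bleach
        f1 = forward_ratio(c, obs) * f2
        channels = {"F1": noisy(f1), "F2": noisy(f2)}
    else:
        channels = {"F": noisy(gain * forward_single(c, obs) * bleach)}
    return FluorescenceTrace(cell_id=cell_id, probe=obs.probe, times=times,
                             channels=channels, experiment_id=experiment_id,
                             condition=condition)
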