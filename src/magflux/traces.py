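"""Per-cell trace containers shared by the generator and the analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError

#: qc flag values for calibrated samples
QC_OK = 0
QC_CLAMPED_LOW = 1   # R <= Rmin, concentration clamped to 0
QC_CLAMPED_HIGH = 2  # R near/above Rmax, clamped to the tolerance boundary


def _check_grid(times: np.ndarray) -> None:
    if times.ndim != 1 or len(times) < 2:
        raise DataError("trace needs at least two samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise DataError("trace times must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6):
        raise DataError("trace times must be uniformly spaced")


@dataclass
class FluorescenceTrace:
    """Raw per-cell fluorescence vs time.

    Ratiometric probes carry two channels, F1 (330-350 nm excitation)
    and F2 (370-390 nm excitation); single-wavelength probes carry one
    channel F.  Values are arbitrary units, strictly positive, on a
    uniform time grid (seconds).
    """

    cell_id: str
    probe: "Probe"  # noqa: F821 - magflux.observe.Probe
    times: np.ndarray
    channels: dict[str, np.ndarray]
    experiment_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        _check_grid(self.times)
        keys = set(self.channels)
        if keys not in ({"F1", "F2"}, {"F"}):
            raise DataError(f"channel set must be {{F1,F2}} or {{F}}, got {sorted(keys)}")
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            self.channels[name] = values
            if values.shape != self.times.shape:
                raise DataError(f"channel {name} length does not match time grid")
            if np.any(values <= 0):
                raise DataError(f"channel {name} has nonpositive values")

    @property
    def is_ratiometric(self) -> bool:
        return "F1" in self.channels


@dataclass
class ConcentrationTrace:
    """Calibrated intracellular ion concentration vs time (mM)."""

    cell_id: str
    ion: str  # "Mg" | "Na"
    times: np.ndarray
    conc: np.ndarray
    qc_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    experiment_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        _check_grid(self.times)
        if self.conc.shape != self.times.shape:
            raise DataError("concentration length does not match time grid")
        if self.qc_flags is None:
            self.qc_flags = np.zeros_like(self.times, dtype=np.uint8)
        else:
            self.qc_flags = np.asarray(self.qc_flags, dtype=np.uint8)
        if self.ion not in ("Mg", "Na"):
            raise DataError(f"ion must be 'Mg' or 'Na', got {self.ion!r}")
        ok = self.qc_flags == QC_OK
        if np.any(~np.isfinite(self.conc[ok])) or np.any(self.conc[ok] < 0):
            raise DataError("unflagged concentrations must be finite and >= 0")


@dataclass
class RelativeTrace:
    """Normalized single-wavelength fluorescence, F/F0 (dimensionless)."""

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    experiment_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.times)

    # duck-type the attribute initial_velocity and average_cells read
    @property
    def conc(self) -> np.ndarray:
        return self.values

    ion = "Mg"


@dataclass
class MeanTrace:
    """Pointwise mean trace with per-time s.e.m. across cells/experiments."""

    times: np.ndarray
    conc: np.ndarray
    sem: np.ndarray
    n: int
    ion: str = "Mg"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
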