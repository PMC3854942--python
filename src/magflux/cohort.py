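"""Cohort generation: simulated cells -> tidy fluorescence trace tables.

A cohort is a set of cells sharing a transfection condition and a
protocol, with per-cell log-normal variability on the exchanger Vmax
and on the optical gain.  Each cell's trajectory can be observed with
several probes simultaneously ("paired" observation of the same ground
truth), each probe getting its own appended ionophore calibration
episode.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import (
    CellState,
    CellTrajectory,
    ExchangerParams,
    LeakPumpParams,
    simulate_cell,
)
from .observe import ObservationModel, Probe, observe_fluorescence
from .presets import (
    DEFAULT_EXCHANGER,
    DEFAULT_GAIN_CV,
    DEFAULT_JITTER_CV,
    DEFAULT_LEAK,
    INIT_LOADED,
    condition_activity,
)
from .protocols import ProtocolSchedule, append_calibration_episode
from .traces import FluorescenceTrace

#: columns of the tidy trace table
TRACE_COLUMNS = ["experiment_id", "condition", "cell_id", "probe",
                 "time_s", "channel", "value"]


@dataclass
class CohortDataset:
    """Generated cohort: tidy traces, ground truth and provenance."""

    traces: pd.DataFrame
    truth: dict[str, CellTrajectory]            # cell_id -> trajectory
    schedules: dict[Probe, ProtocolSchedule]    # probe -> schedule incl. episode
    manifest: dict

    @property
    def condition(self) -> str:
        return self.manifest["condition"]

    @property
    def experiment_id(self) -> str:
        return self.manifest["experiment_id"]


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def generate_cohort(
    condition: str,
    n_cells: int,
    schedule: ProtocolSchedule,
    obs: Union[ObservationModel, Sequence[ObservationModel]],
    seed: Union[int, np.random.SeedSequence],
    exch: ExchangerParams = DEFAULT_EXCHANGER,
    leak: LeakPumpParams = DEFAULT_LEAK,
    init: CellState = INIT_LOADED,
    jitter_cv: float = DEFAULT_JITTER_CV,
    gain_cv: float = DEFAULT_GAIN_CV,
    experiment_id: str = "e1",
    noise_sigma: Optional[float] = None,
    with_calibration: bool = True,
    dt: float = 1.0,
) -> CohortDataset:
    """Simulate and observe one cohort of cells.

    ``obs`` may be one observation model or several (paired probes
    observing the same trajectory).  ``noise_sigma`` overrides the
    models' noise level when given.  The manifest records every piece
    of ground truth needed for downstream validation.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    activity = condition_activity(condition)
    obs_models = [obs] if isinstance(obs, ObservationModel) else list(obs)
    if noise_sigma is not None:
        obs_models = [replace(o, noise_sigma=noise_sigma) for o in obs_models]
    probes = [o.probe for o in obs_models]
    if len(set(probes)) != len(probes):
        raise ConfigError("each probe may appear only once per cohort")

    schedules: dict[Probe, ProtocolSchedule] = {}
    for o in obs_models:
        schedules[o.probe] = (
            append_calibration_episode(schedule, o.probe) if with_calibration
            else schedule
        )

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)

    rows: list[pd.DataFrame] = []
    truth: dict[str, CellTrajectory] = {}
    cells_manifest = []
    for i in range(n_cells):
        cell_id = f"{experiment_id}_{condition}_c{i:02d}"
        vmax_factor = _lognormal_factor(rng, jitter_cv)
        cell_exch = replace(exch, activity_scale=activity,
                            vmax_efflux=exch.vmax_efflux * vmax_factor)
        gains = {p: _lognormal_factor(rng, gain_cv) for p in probes}
        # one trajectory per probe-schedule; identical over the shared
        # experimental span (deterministic ODE), so the observation is paired
        per_probe_traj: dict[Probe, CellTrajectory] = {}
        for o in obs_models:
            traj = simulate_cell(cell_exch, leak, schedules[o.probe], init, dt=dt)
            per_probe_traj[o.probe] = traj
            trace = observe_fluorescence(
                traj, o, schedules[o.probe], rng, gain=gains[o.probe],
                cell_id=cell_id, experiment_id=experiment_id, condition=condition,
            )
            rows.append(_trace_rows(trace))
        truth[cell_id] = per_probe_traj[probes[0]]
        cells_manifest.append({
            "cell_id": cell_id,
            "vmax_efflux": cell_exch.vmax_efflux,
            "activity_scale": activity,
            "gains": {p.value: g for p, g in gains.items()},
        })

    traces = pd.concat(rows, ignore_index=True)
    manifest = {
        "schema_version": 1,
        "experiment_id": experiment_id,
        "condition": condition,
        "n_cells": n_cells,
        "seed_entropy": int(ss.entropy) if isinstance(ss.entropy, int) else None,
        "protocol": schedule.name,
        "depletion_onset_s": schedule.depletion_onset(),
        "exchanger": {
            "vmax_efflux": exch.vmax_efflux, "ka_na": exch.ka_na,
            "n_hill": exch.n_hill, "km_mg": exch.km_mg, "stoich": exch.stoich,
            "activity_scale": activity,
        },
        "leak": {
            "p_mg_channel": leak.p_mg_channel, "p_na_leak": leak.p_na_leak,
            "na_pump_rate": leak.na_pump_rate, "na_baseline": leak.na_baseline,
            "cohex_inhibition": dict(leak.cohex_inhibition),
        },
        "init": {"mg_i": init.mg_i, "na_i": init.na_i},
        "observation": [
            {"probe": o.probe.value, "kd": o.kd, "rmin": o.rmin, "rmax": o.rmax,
             "q": o.q, "noise_sigma": o.noise_sigma,
             "sample_interval": o.sample_interval, "bleach_rate": o.bleach_rate}
            for o in obs_models
        ],
        "jitter_cv": jitter_cv,
        "gain_cv": gain_cv,
        "cells": cells_manifest,
    }
    return CohortDataset(traces=traces, truth=truth, schedules=schedules,
                         manifest=manifest)


def _trace_rows(trace: FluorescenceTrace) -> pd.DataFrame:
    frames = []
    for channel, values in sorted(trace.channels.items()):
        frames.append(pd.DataFrame({
            "experiment_id": trace.experiment_id,
            "condition": trace.condition,
            "cell_id": trace.cell_id,
            "probe": trace.probe.value,
            "time_s": trace.times,
            "channel": channel,
            "value": values,
        }))
    return pd.concat(frames, ignore_index=True)


def traces_from_table(df: pd.DataFrame) -> list[FluorescenceTrace]:
    """Rebuild per-cell :class:`FluorescenceTrace` objects from a tidy table."""
    out = []
    for (exp, cond, cell, probe), grp in df.groupby(
        ["experiment_id", "condition", "cell_id", "probe"], sort=True
    ):
        channels = {}
        times = None
        for channel, sub in grp.groupby("channel", sort=True):
            sub = sub.sort_values("time_s")
            channels[channel] = sub["value"].to_numpy()
            times = sub["time_s"].to_numpy()
        out.append(FluorescenceTrace(
            cell_id=cell, probe=Probe(probe), times=times, channels=channels,
            experiment_id=exp, condition=cond,
        ))
    return out
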