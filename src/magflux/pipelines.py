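"""End-to-end wiring of the shipped experiment presets.

Three presets reproduce the quantitative assays one command each:

``stoichiometry``
    Mg2+ depletion with paired SBFI / Mag-fura2 observation of
    expressing and mock cohorts (6 experiments x 10 cells by default);
    yields the control-subtracted Na+/Mg2+ flux ratio.
``titration``
    Mg2+ depletion at a series of extracellular Na+ levels (Mag-fura2,
    3 experiments per level); yields the Na+ titration curve and its
    Hill fit.
``phases``
    Four-phase solution-exchange protocol observed with Magnesium
    Green; yields per-phase slopes of the relative fluorescence.

Two further presets (``extrusion``, ``loading``) expose the plain
extrusion assay and the reverse-mode loading assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    average_cells,
    calibrate_trace,
    estimate_calibration,
    normalize_single_wavelength,
)
from .cohort import CohortDataset, generate_cohort, traces_from_table
from .errors import ConfigError, DataError
from .fluxes import (
    HillFitResult,
    NaTitrationCurve,
    StoichiometryResult,
    build_na_titration,
    cnnm4_flux_ratio,
    electroneutrality_check,
    fit_hill,
    initial_velocity,
)
from .model import CellState, ExchangerParams, LeakPumpParams, predict_membrane_current
from .observe import ObservationModel, Probe
from .presets import (
    DEFAULT_CAPACITANCE_PF,
    DEFAULT_EXCHANGER,
    DEFAULT_GAIN_CV,
    DEFAULT_JITTER_CV,
    DEFAULT_LEAK,
    DEFAULT_VOLUME_PL,
    INIT_LOADED,
    INIT_UNLOADED,
    MAGFURA2_OBS,
    MAGGREEN_OBS,
    PLATEAU_K,
    SBFI_OBS,
    TITRATION_LEVELS,
    V0_WINDOW_S,
)
from .protocols import (
    ProtocolSchedule,
    extrusion_protocol,
    loading_protocol,
    phase_windows,
    phases_protocol,
    titration_protocol,
)
from .traces import ConcentrationTrace

_DEFAULT_N_EXPERIMENTS = {
    "stoichiometry": 6,
    "titration": 3,
    "phases": 1,
    "extrusion": 1,
    "loading": 1,
}


@dataclass
class PresetRun:
    """A simulated preset dataset plus everything needed to analyze it."""

    preset: str
    traces: pd.DataFrame
    schedules: dict[tuple[str, str], ProtocolSchedule]  # (exp_id, probe) -> schedule
    manifest: dict
    truth: dict = field(default_factory=dict)  # (exp_id, condition) -> cohort truth

    def schedule_for(self, experiment_id: str, probe: Probe) -> ProtocolSchedule:
        try:
            return self.schedules[(experiment_id, probe.value)]
        except KeyError:
            raise DataError(
                f"no schedule stored for experiment {experiment_id!r}, "
                f"probe {probe.value!r}"
            ) from None


def simulate_preset(
    preset: str,
    seed: int,
    n_experiments: Optional[int] = None,
    n_cells: int = 10,
    conditions: Optional[Sequence[str]] = None,
    noise_sigma: Optional[float] = None,
    jitter_cv: Optional[float] = None,
    gain_cv: Optional[float] = None,
    titration_levels: Sequence[float] = TITRATION_LEVELS,
    exch: ExchangerParams = DEFAULT_EXCHANGER,
    leak: LeakPumpParams = DEFAULT_LEAK,
    init: Optional[CellState] = None,
) -> PresetRun:
    """Simulate one of the packaged presets deterministically from a seed."""
    if n_experiments is None:
        n_experiments = _DEFAULT_N_EXPERIMENTS.get(preset)
    if n_experiments is None:
        raise ConfigError(f"unknown preset {preset!r}")
    jitter_cv = DEFAULT_JITTER_CV if jitter_cv is None else jitter_cv
    gain_cv = DEFAULT_GAIN_CV if gain_cv is None else gain_cv

    if preset == "stoichiometry":
        conditions = tuple(conditions or ("WT", "mock"))
        plan = [(f"e{j + 1:02d}", cond, extrusion_protocol(),
                 [SBFI_OBS, MAGFURA2_OBS], init or INIT_LOADED, True, None)
                for j in range(n_experiments) for cond in conditions]
    elif preset == "titration":
        conditions = tuple(conditions or ("WT",))
        plan = [(f"na{lv:g}_e{j + 1}", cond, titration_protocol(lv),
                 [MAGFURA2_OBS], init or INIT_LOADED, True, lv)
                for lv in titration_levels
                for j in range(n_experiments) for cond in conditions]
    elif preset == "phases":
        conditions = tuple(conditions or ("WT", "mock"))
        plan = [(f"e{j + 1:02d}", cond, phases_protocol(),
                 [MAGGREEN_OBS], init or INIT_LOADED, False, None)
                for j in range(n_experiments) for cond in conditions]
    elif preset == "extrusion":
        conditions = tuple(conditions or ("WT", "mock"))
        plan = [(f"e{j + 1:02d}", cond, extrusion_protocol(),
                 [MAGGREEN_OBS], init or INIT_LOADED, False, None)
                for j in range(n_experiments) for cond in conditions]
    elif preset == "loading":
        conditions = tuple(conditions or ("WT", "mock"))
        plan = [(f"e{j + 1:02d}", cond, loading_protocol(),
                 [MAGFURA2_OBS], init or INIT_UNLOADED, True, None)
                for j in range(n_experiments) for cond in conditions]
    else:
        raise ConfigError(f"unknown preset {preset!r}")

    children = np.random.SeedSequence(seed).spawn(len(plan))
    frames, schedules, truth = [], {}, {}
    experiments: dict[str, dict] = {}
    for (exp_id, cond, schedule, obs, init_state, with_cal, na_out), child in zip(
        plan, children
    ):
        ds = generate_cohort(
            condition=cond, n_cells=n_cells, schedule=schedule, obs=obs,
            seed=child, exch=exch, leak=leak, init=init_state,
            jitter_cv=jitter_cv, gain_cv=gain_cv, experiment_id=exp_id,
            noise_sigma=noise_sigma, with_calibration=with_cal,
        )
        frames.append(ds.traces)
        for probe, sched in ds.schedules.items():
            schedules[(exp_id, probe.value)] = sched
        truth[(exp_id, cond)] = ds
        meta = experiments.setdefault(
            exp_id, {"conditions": [], "protocol": schedule.name,
                     "depletion_onset_s": schedule.depletion_onset()}
        )
        meta["conditions"].append(cond)
        if na_out is not None:
            meta["na_out"] = float(na_out)

    manifest = {
        "schema_version": 1,
        "preset": preset,
        "seed": int(seed),
        "n_experiments": n_experiments,
        "n_cells": n_cells,
        "conditions": list(conditions),
        "noise_sigma": noise_sigma,
        "jitter_cv": jitter_cv,
        "gain_cv": gain_cv,
        "experiments": experiments,
        "exchanger": truth[next(iter(truth))].manifest["exchanger"] | {
            "activity_scale": 1.0
        },
        "leak": truth[next(iter(truth))].manifest["leak"],
        "observation": truth[next(iter(truth))].manifest["observation"],
    }
    return PresetRun(
        preset=preset,
        traces=pd.concat(frames, ignore_index=True),
        schedules=schedules,
        manifest=manifest,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# analysis helpers

def _conc_traces(
    run: PresetRun, exp_id: str, condition: str, probe: Probe, k: int = PLATEAU_K
) -> list[ConcentrationTrace]:
    """Calibrate every cell of one experiment/condition/probe group."""
    df = run.traces
    sel = df[(df["experiment_id"] == exp_id) & (df["condition"] == condition)
             & (df["probe"] == probe.value)]
    if sel.empty:
        raise DataError(f"no traces for {exp_id}/{condition}/{probe.value}")
    schedule = run.schedule_for(exp_id, probe)
    out = []
    for trace in traces_from_table(sel):
        calib = estimate_calibration(trace, schedule, k=k)
        out.append(calibrate_trace(trace, calib, schedule))
    return out


def _mean_v0(
    run: PresetRun, exp_id: str, condition: str, probe: Probe,
    w: float = V0_WINDOW_S, k: int = PLATEAU_K,
) -> float:
    """Initial velocity of the cell-averaged concentration trace."""
    traces = _conc_traces(run, exp_id, condition, probe, k=k)
    mean = average_cells(traces)
    schedule = run.schedule_for(exp_id, probe)
    t0 = schedule.depletion_onset()
    return initial_velocity(mean, t0, w=w, schedule=schedule,
                            label=f"{exp_id}/{condition}").v0


def analyze_stoichiometry(
    run: PresetRun,
    w: float = V0_WINDOW_S,
    k: int = PLATEAU_K,
    aggregation: str = "ratio_of_means",
    expressing: str = "WT",
    control: str = "mock",
) -> dict:
    """Control-subtracted Na+/Mg2+ flux ratio from a stoichiometry run.

    Velocities are computed per experiment from 10-cell mean traces;
    the default aggregation is the ratio of experiment-mean velocities.
    When the run has no control cohort the control velocities are taken
    as zero (exact for noiseless, leak-free simulations).
    """
    exps = sorted(run.manifest["experiments"])
    has_control = control in run.manifest["conditions"]
    rows = []
    for exp_id in exps:
        row = {"experiment_id": exp_id}
        row["v0_na_exp"] = _mean_v0(run, exp_id, expressing, Probe.SBFI, w, k)
        row["v0_mg_exp"] = _mean_v0(run, exp_id, expressing, Probe.MAGFURA2, w, k)
        row["v0_na_ctl"] = (_mean_v0(run, exp_id, control, Probe.SBFI, w, k)
                            if has_control else 0.0)
        row["v0_mg_ctl"] = (_mean_v0(run, exp_id, control, Probe.MAGFURA2, w, k)
                            if has_control else 0.0)
        rows.append(row)
    table = pd.DataFrame(rows)
    n = len(exps)
    if aggregation == "ratio_of_means":
        result = cnnm4_flux_ratio(
            table["v0_na_exp"].mean(), table["v0_na_ctl"].mean(),
            table["v0_mg_exp"].mean(), table["v0_mg_ctl"].mean(),
            n_experiments=n,
        )
    elif aggregation == "mean_of_ratios":
        ratios = [
            cnnm4_flux_ratio(r["v0_na_exp"], r["v0_na_ctl"],
                             r["v0_mg_exp"], r["v0_mg_ctl"]).ratio
            for _, r in table.iterrows()
        ]
        result = StoichiometryResult(
            ratio=float(np.mean(ratios)),
            v0_na_expressing=table["v0_na_exp"].mean(),
            v0_na_control=table["v0_na_ctl"].mean(),
            v0_mg_expressing=table["v0_mg_exp"].mean(),
            v0_mg_control=table["v0_mg_ctl"].mean(),
            n_experiments=n,
        )
    else:
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    return {
        "result": result,
        "net_charge_per_mg": electroneutrality_check(result),
        "v0_table": table,
    }


def analyze_titration(
    run: PresetRun,
    w: float = V0_WINDOW_S,
    k: int = PLATEAU_K,
    expressing: str = "WT",
) -> dict:
    """Na+ titration curve of V0(Mg) and its Hill fit."""
    by_level: dict[float, list[float]] = {}
    for exp_id, meta in run.manifest["experiments"].items():
        lv = meta.get("na_out")
        if lv is None:
            raise DataError(f"experiment {exp_id} has no na_out level")
        v0 = _mean_v0(run, exp_id, expressing, Probe.MAGFURA2, w, k)
        by_level.setdefault(float(lv), []).append(v0)
    curve = build_na_titration(by_level)
    fit = fit_hill(curve)
    return {"curve": curve, "fit": fit}


def analyze_phases(run: PresetRun, w: float = V0_WINDOW_S) -> dict:
    """Per-condition phase slopes and post-depletion velocities (F/F0 units).

    Slopes are (last - first)/duration of the condition-mean relative
    trace over each protocol phase, in fraction of baseline per minute;
    ``v0_cells`` holds per-cell two-point velocities over the first
    window after depletion, whose scatter serves as the noise floor for
    flatness checks.
    """
    df = run.traces
    out: dict[str, dict] = {}
    for cond in run.manifest["conditions"]:
        rel_traces = []
        v0_cells = []
        for exp_id in sorted(run.manifest["experiments"]):
            schedule = run.schedule_for(exp_id, Probe.MAGNESIUM_GREEN)
            sel = df[(df["experiment_id"] == exp_id) & (df["condition"] == cond)]
            t0 = schedule.depletion_onset()
            for trace in traces_from_table(sel):
                rel = normalize_single_wavelength(trace, schedule)
                rel_traces.append(rel)
                v0_cells.append(initial_velocity(rel, t0, w=w,
                                                 schedule=schedule).v0)
        mean = average_cells(rel_traces)
        schedule = run.schedule_for(sorted(run.manifest["experiments"])[0],
                                    Probe.MAGNESIUM_GREEN)
        slopes = {}
        for phase, (a, b) in phase_windows(schedule).items():
            # first sample at/after the phase start, last sample strictly
            # before its end (the boundary sample belongs to the next phase)
            ia = int(mean.times.searchsorted(a - 1e-9))
            ib = int(mean.times.searchsorted(b - 1e-9)) - 1
            ib = min(ib, len(mean.times) - 1)
            slopes[phase] = float(
                (mean.conc[ib] - mean.conc[ia]) / (mean.times[ib] - mean.times[ia])
                * 60.0
            )
        out[cond] = {
            "slopes_per_min": slopes,
            "v0_cells": np.asarray(v0_cells),
            "mean_trace": mean,
        }
    return out


# ---------------------------------------------------------------------------
# one-shot drivers

def run_stoichiometry(seed: int, aggregation: str = "ratio_of_means",
                      **overrides) -> dict:
    """Simulate the stoichiometry preset and compute the flux ratio."""
    run = simulate_preset("stoichiometry", seed, **overrides)
    out = analyze_stoichiometry(run, aggregation=aggregation)
    out["run"] = run
    return out


def run_titration(seed: int, **overrides) -> dict:
    """Simulate the titration preset and fit the Hill curve."""
    run = simulate_preset("titration", seed, **overrides)
    out = analyze_titration(run)
    out["run"] = run
    return out


def run_phases(seed: int, **overrides) -> dict:
    """Simulate the four-phase protocol and summarize per-phase slopes."""
    run = simulate_preset("phases", seed, **overrides)
    out = analyze_phases(run)
    return {"phases": out, "run": run}


def electroneutral_limit(stoich: int = 2) -> dict:
    """Noiseless, leak-free single-cell limit of the stoichiometry pipeline.

    With all background fluxes off and a perfect 2:1 exchanger the
    measured Na+/Mg2+ flux ratio equals the stoichiometry exactly and
    the charge-balance membrane current is identically zero.
    """
    exch = replace(DEFAULT_EXCHANGER, stoich=stoich)
    leak = LeakPumpParams(p_mg_channel=0.0, p_na_leak=0.0, na_pump_rate=0.0)
    run = simulate_preset(
        "stoichiometry", seed=0, n_experiments=1, n_cells=1,
        conditions=("WT",), noise_sigma=0.0, jitter_cv=0.0, gain_cv=0.0,
        exch=exch, leak=leak,
    )
    out = analyze_stoichiometry(run)
    ds = run.truth[("e01", "WT")]
    traj = next(iter(ds.truth.values()))
    current = predict_membrane_current(
        traj, replace(exch, activity_scale=1.0),
        cell_capacitance_pf=DEFAULT_CAPACITANCE_PF,
        cell_volume_pl=DEFAULT_VOLUME_PL,
    )
    out["current_pa_per_pf"] = current
    out["max_abs_current"] = float(np.max(np.abs(current)))
    out["run"] = run
    return out


def analyze_extrusion(run: PresetRun, w: float = V0_WINDOW_S) -> dict:
    """Per-condition post-depletion velocities of F/F0 traces."""
    df = run.traces
    out: dict[str, dict] = {}
    for cond in run.manifest["conditions"]:
        v0_cells = []
        rel_traces = []
        for exp_id in sorted(run.manifest["experiments"]):
            schedule = run.schedule_for(exp_id, Probe.MAGNESIUM_GREEN)
            sel = df[(df["experiment_id"] == exp_id) & (df["condition"] == cond)]
            t0 = schedule.depletion_onset()
            for trace in traces_from_table(sel):
                rel = normalize_single_wavelength(trace, schedule)
                rel_traces.append(rel)
                v0_cells.append(initial_velocity(rel, t0, w=w,
                                                 schedule=schedule).v0)
        mean = average_cells(rel_traces)
        v0 = np.asarray(v0_cells)
        out[cond] = {
            "v0_mean": float(v0.mean()),
            "v0_sem": float(v0.std(ddof=1) / np.sqrt(len(v0))) if len(v0) > 1 else 0.0,
            "n_cells": len(v0),
            "mean_trace": mean,
        }
    return out


def analyze_loading(run: PresetRun, k: int = PLATEAU_K) -> dict:
    """Condition-mean calibrated Mg2+ traces of the reverse-mode assay."""
    out: dict[str, dict] = {}
    for cond in run.manifest["conditions"]:
        traces = []
        for exp_id in sorted(run.manifest["experiments"]):
            traces.extend(_conc_traces(run, exp_id, cond, Probe.MAGFURA2, k=k))
        mean = average_cells(traces)
        out[cond] = {
            "mean_trace": mean,
            "mg_start": float(mean.conc[0]),
            "mg_peak": float(mean.conc.max()),
            "mg_end": float(mean.conc[-1]),
        }
    return out


# ---------------------------------------------------------------------------
# persistence (dataset directories written/read by the command line)

def save_run(run: PresetRun, outdir) -> None:
    """Write a preset run as a dataset directory of text artifacts."""
    from pathlib import Path

    from .io import write_schedule, write_traces, write_yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "schedules").mkdir(exist_ok=True)
    write_traces(run.traces, outdir / "traces.csv")
    schedule_files = {}
    written = {}
    for (exp_id, probe), sched in run.schedules.items():
        fname = f"schedules/{sched.name}_{probe}.yaml"
        if fname not in written:
            write_schedule(sched, outdir / fname)
            written[fname] = True
        schedule_files[f"{exp_id}|{probe}"] = fname
    manifest = dict(run.manifest)
    manifest["schedule_files"] = schedule_files
    write_yaml(manifest, outdir / "manifest.yaml")


def load_run(path) -> PresetRun:
    """Read a dataset directory back into a :class:`PresetRun`.

    Ground-truth trajectories are not persisted; the loaded run carries
    traces, schedules and the manifest, which is all analysis needs.
    """
    from pathlib import Path

    from .io import read_schedule, read_traces, read_yaml

    path = Path(path)
    manifest = read_yaml(path / "manifest.yaml")
    traces = read_traces(path / "traces.csv")
    schedules = {}
    for key, fname in manifest.get("schedule_files", {}).items():
        exp_id, probe = key.split("|")
        schedules[(exp_id, probe)] = read_schedule(path / fname)
    return PresetRun(preset=manifest["preset"], traces=traces,
                     schedules=schedules, manifest=manifest)
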