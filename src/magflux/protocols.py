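"""Experiment protocols: timed extracellular buffer schedules.

A protocol is an ordered, contiguous sequence of :class:`BufferSegment`
objects, each holding the extracellular composition during a time window
(seconds).  Schedules drive both the whole-cell simulation and the
analysis windowing (depletion onset, calibration plateaus).

Buffer conventions follow the standard HEK293 imaging recipes: the
Mg2+-loading buffer contains 78.1 mM NaCl and 40 mM MgCl2; the Mg2+-free
buffer replaces MgCl2 with 60 mM NaCl (138.1 mM Na+ total); Na+-free
buffers substitute NaCl with equimolar NMDG-Cl.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .errors import ConfigError, ScheduleError

# canonical buffer concentrations (mM)
LOADING_NA = 78.1
LOADING_MG = 40.0
MG_FREE_NA = 138.1  # NaCl 78.1 + 60 mM replacing MgCl2
SAT_MG = 50.0       # ionophore saturation episode for Mg probes

_TOL = 1e-9


class Ionophore(str, Enum):
    """Ionophore state of a buffer segment.

    ``MG_FREE``/``MG_SAT`` model 4-Bromo-A23187 with EDTA or 50 mM Mg2+
    (divalent clamp); ``NA_FREE``/``NA_SAT`` model gramicidin in Na+-free
    or Na+-replete buffer (monovalent clamp).  During an ionophore
    segment the observed ion is clamped to zero or saturation.
    """

    NONE = "none"
    MG_FREE = "mg_free"
    MG_SAT = "mg_sat"
    NA_SAT = "gramicidin_na"
    NA_FREE = "gramicidin_na_free"


#: ionophore states that clamp the probe's ion to zero / saturation
ZERO_CLAMPS = {Ionophore.MG_FREE: "Mg", Ionophore.NA_FREE: "Na"}
SAT_CLAMPS = {Ionophore.MG_SAT: "Mg", Ionophore.NA_SAT: "Na"}


@dataclass(frozen=True)
class BufferSegment:
    """One timed extracellular condition.

    Times are seconds; concentrations are mM.  ``nmdg_out`` records the
    impermeant cation substituting for Na+ (book-keeping only; NMDG
    carries no flux).
    """

    t_start: float
    t_end: float
    mg_out: float = 0.0
    na_out: float = 0.0
    nmdg_out: float = 0.0
    cohex_mm: float = 0.0
    ionophore: Ionophore = Ionophore.NONE

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ScheduleError(
                f"segment t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        for name in ("mg_out", "na_out", "nmdg_out", "cohex_mm"):
            if getattr(self, name) < 0:
                raise ScheduleError(f"segment {name} must be >= 0")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start - _TOL <= t <= self.t_end + _TOL


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered, contiguous, non-overlapping buffer segments."""

    segments: tuple[BufferSegment, ...]
    name: str = ""

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ScheduleError("schedule has no segments")
        for prev, cur in zip(segs, segs[1:]):
            if cur.t_start < prev.t_end - _TOL:
                raise ScheduleError(
                    f"overlapping segments at t={cur.t_start} (previous ends {prev.t_end})"
                )
            if cur.t_start > prev.t_end + _TOL:
                raise ScheduleError(
                    f"gap between segments at t={prev.t_end}..{cur.t_start}"
                )

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    def segment_at(self, t: float) -> BufferSegment:
        """Segment active at time ``t`` (boundaries belong to the later segment)."""
        for seg in self.segments[:-1]:
            if seg.t_start - _TOL <= t < seg.t_end - _TOL:
                return seg
        last = self.segments[-1]
        if last.contains(t):
            return last
        raise ScheduleError(f"time {t} s outside schedule [{self.t_start}, {self.t_end}]")

    def depletion_onset(self) -> float:
        """Time of the first switch into an Mg2+-free experimental buffer.

        Defined as the start of the first ionophore-free segment with
        ``mg_out == 0`` whose predecessor had ``mg_out > 0``; if the
        schedule begins Mg2+-free and never re-depletes, the schedule
        start is returned.
        """
        segs = [s for s in self.segments if s.ionophore is Ionophore.NONE]
        for prev, cur in zip(segs, segs[1:]):
            if prev.mg_out > 0 and cur.mg_out == 0:
                return cur.t_start
        if segs and segs[0].mg_out == 0:
            return segs[0].t_start
        raise ScheduleError(f"schedule {self.name!r} has no Mg2+ depletion step")

    def experimental_end(self) -> float:
        """End of the experimental span (start of the first ionophore segment)."""
        for seg in self.segments:
            if seg.ionophore is not Ionophore.NONE:
                return seg.t_start
        return self.t_end

    def has_ionophore(self) -> bool:
        return any(s.ionophore is not Ionophore.NONE for s in self.segments)

    def ionophore_segments(self) -> list[BufferSegment]:
        return [s for s in self.segments if s.ionophore is not Ionophore.NONE]


def _nmdg(na_out: float) -> float:
    """NMDG-Cl substituting for NaCl in an Mg2+-free buffer."""
    return max(MG_FREE_NA - na_out, 0.0)


def extrusion_protocol(
    na_out: float = MG_FREE_NA,
    baseline_s: float = 40.0,
    depletion_s: float = 120.0,
    cohex_mm: float = 0.0,
    name: str = "extrusion",
) -> ProtocolSchedule:
    """Mg2+-extrusion assay: loading-buffer baseline, then Mg2+ depletion.

    ``na_out`` sets the Na+ concentration of the depletion buffer (NMDG
    makes up the balance), which is how Na+-titration schedules are built.
    """
    segs = (
        BufferSegment(0.0, baseline_s, mg_out=LOADING_MG, na_out=LOADING_NA,
                      cohex_mm=cohex_mm),
        BufferSegment(baseline_s, baseline_s + depletion_s, mg_out=0.0,
                      na_out=na_out, nmdg_out=_nmdg(na_out), cohex_mm=cohex_mm),
    )
    return ProtocolSchedule(segs, name=name)


def titration_protocol(na_out: float, **kw) -> ProtocolSchedule:
    """Extrusion assay at a given depletion-buffer Na+ level (mM)."""
    return extrusion_protocol(na_out=na_out, name=f"na_titration_{na_out:g}", **kw)


def phases_protocol(baseline_s: float = 60.0, phase_s: float = 160.0) -> ProtocolSchedule:
    """Four-phase solution-exchange protocol.

    Phase 1: Mg2+ depletion with Na+ present (extrusion); phase 2: 40 mM
    Mg2+ re-addition (channel-mediated refill); phase 3: Mg2+- and
    Na+-free (NMDG; exchange silenced); phase 4: Na+ restoration
    (extrusion resumes).
    """
    t = baseline_s
    segs = [BufferSegment(0.0, t, mg_out=LOADING_MG, na_out=LOADING_NA)]
    # phase 1: -Mg +Na
    segs.append(BufferSegment(t, t + phase_s, mg_out=0.0, na_out=MG_FREE_NA))
    t += phase_s
    # phase 2: +40 Mg +Na
    segs.append(BufferSegment(t, t + phase_s, mg_out=LOADING_MG, na_out=LOADING_NA))
    t += phase_s
    # phase 3: -Mg -Na (NMDG)
    segs.append(BufferSegment(t, t + phase_s, mg_out=0.0, na_out=0.0,
                              nmdg_out=MG_FREE_NA))
    t += phase_s
    # phase 4: -Mg +Na
    segs.append(BufferSegment(t, t + phase_s, mg_out=0.0, na_out=MG_FREE_NA))
    return ProtocolSchedule(tuple(segs), name="phases_1_4")


def phase_windows(schedule: ProtocolSchedule) -> dict[str, tuple[float, float]]:
    """Named (t_start, t_end) windows for the four-phase protocol."""
    if schedule.name != "phases_1_4":
        raise ConfigError("phase windows are defined for the phases_1_4 preset only")
    segs = schedule.segments
    return {
        "baseline": (segs[0].t_start, segs[0].t_end),
        "phase1": (segs[1].t_start, segs[1].t_end),
        "phase2": (segs[2].t_start, segs[2].t_end),
        "phase3": (segs[3].t_start, segs[3].t_end),
        "phase4": (segs[4].t_start, segs[4].t_end),
    }


def loading_protocol(
    mg_load: float = 10.0,
    na_load: float = 0.0,
    baseline_s: float = 40.0,
    load_s: float = 240.0,
    efflux_s: float = 240.0,
) -> ProtocolSchedule:
    """Reverse-mode Mg2+-loading assay.

    Unloaded cells are bathed Mg2+-free, exposed to ``mg_load`` mM Mg2+
    with ``na_load`` mM Na+ (NMDG balance) to drive reverse exchange,
    then returned to Mg2+-free, Na+-replete buffer.
    """
    t1 = baseline_s
    t2 = t1 + load_s
    t3 = t2 + efflux_s
    segs = (
        BufferSegment(0.0, t1, mg_out=0.0, na_out=MG_FREE_NA),
        BufferSegment(t1, t2, mg_out=mg_load, na_out=na_load,
                      nmdg_out=_nmdg(na_load)),
        BufferSegment(t2, t3, mg_out=0.0, na_out=MG_FREE_NA),
    )
    return ProtocolSchedule(segs, name="loading")


def append_calibration_episode(
    schedule: ProtocolSchedule, probe, plateau_s: float = 120.0
) -> ProtocolSchedule:
    """Append in-situ ionophore calibration plateaus for ``probe``.

    Adds a zero-ion plateau followed by a saturating plateau after the
    experimental segments (each long enough for at least 5 samples on
    the 20 s grid).  Mg2+ probes get the A23187/EDTA then A23187/50 mM
    Mg2+ episodes; SBFI gets gramicidin in Na+-free then Na+-replete
    buffer.
    """
    from .observe import Probe  # local import to avoid a cycle

    if schedule.has_ionophore():
        raise ConfigError("schedule already contains a calibration episode")
    probe = Probe(probe)
    t0 = schedule.t_end
    t1 = t0 + plateau_s
    t2 = t1 + plateau_s
    if probe.ion == "Mg":
        extra = (
            BufferSegment(t0, t1, mg_out=0.0, na_out=MG_FREE_NA,
                          ionophore=Ionophore.MG_FREE),
            BufferSegment(t1, t2, mg_out=SAT_MG, na_out=MG_FREE_NA,
                          ionophore=Ionophore.MG_SAT),
        )
    elif probe.ion == "Na":
        extra = (
            BufferSegment(t0, t1, mg_out=0.0, na_out=0.0, nmdg_out=MG_FREE_NA,
                          ionophore=Ionophore.NA_FREE),
            BufferSegment(t1, t2, mg_out=0.0, na_out=MG_FREE_NA,
                          ionophore=Ionophore.NA_SAT),
        )
    else:  # pragma: no cover - Probe restricts ions
        raise ConfigError(f"unknown probe {probe!r}")
    return ProtocolSchedule(schedule.segments + extra,
                            name=schedule.name or "with_calibration")
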