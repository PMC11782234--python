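"""Ladder diagrams, AVNRT classification and fixed-point sustainability.

A Lewis ladder diagram organises the activation events of a simulation
into wavefronts per anatomical pathway (atrial approach, fast pathway,
slow pathway, His bundle), with a conduction direction inferred from the
slope of activation time along the cell order.  Reentry shows up as a
retrograde front in one AV-nodal pathway paired with an anterograde
front in the other; the pathway conducting anterogradely names the AVNRT
form (slow pathway => typical slow-fast, fast pathway => atypical
fast-slow).

Sustainability is analysed as a fixed-point problem: a reentrant rhythm
of cycle length CL is self-consistent when the anterograde conduction
time of one limb plus the retrograde conduction time of the other, both
measured at pacing interval CL with the S1S1 protocol, equal CL.  The
crossing of the summation curve with the identity line y = x gives the
predicted AVNRT cycle length; absence of a crossing predicts that the
rhythm cannot persist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import ANSSchedule, SolverOptions, integrate
from .protocols import run_s1s1
from .topology import NodeTopology

__all__ = [
    "LadderDiagram",
    "Wavefront",
    "EpisodeClassification",
    "SustainabilitySummary",
    "build_ladder",
    "classify_episode",
    "sustainability_analysis",
    "sinus_interval",
    "sinus_rate",
    "ECHO_THRESHOLD",
    "RateUndefinedError",
]

#: Reentry lasting at most this many cycles is an echo; more cycles that
#: persist to the end of the window (or the next gamma change) are
#: sustained tachycardia.
ECHO_THRESHOLD = 5

#: Maximum per-link activation-time gap (ms) for two events to belong to
#: the same wavefront.
WAVEFRONT_GAP = 40.0


class RateUndefinedError(RuntimeError):
    pass


#: Pathways of the ladder: ordered cell chains in the anterograde sense.
def _pathways(topo: NodeTopology) -> dict[str, list[str]]:
    return {
        "atrial": topo.cells_in("SN") + topo.cells_in("PS") + topo.cells_in("AM"),
        "FP": topo.cells_in("FP"),
        "SP": topo.cells_in("SP"),
        "his": topo.cells_in("PB") + topo.cells_in("HB"),
    }


@dataclass
class Wavefront:
    """One propagating front within a single pathway."""

    pathway: str
    cells: list[str]
    times: list[float]
    direction: str          # "anterograde" | "retrograde" | "collision" | "focal"

    @property
    def t_start(self) -> float:
        return min(self.times)

    @property
    def t_end(self) -> float:
        return max(self.times)

    def time_of(self, cell: str) -> float | None:
        try:
            return self.times[self.cells.index(cell)]
        except ValueError:
            return None


@dataclass
class LadderDiagram:
    """Wavefronts per pathway plus annihilation (collision) points."""

    wavefronts: list[Wavefront]
    annihilations: list[tuple[float, str, str]]   # (time, pathway, cell)
    ambiguous: int = 0
    t_span: tuple[float, float] = (0.0, 0.0)

    def fronts(self, pathway: str) -> list[Wavefront]:
        return sorted((w for w in self.wavefronts if w.pathway == pathway),
                      key=lambda w: w.t_start)


@dataclass
class EpisodeClassification:
    """Form and persistence of reentrant activity in one window."""

    form: str               # "slow-fast" | "fast-slow" | "none"
    persistence: str        # "sustained" | "echo" | "none"
    n_cycles: int = 0
    cycle_lengths: list[float] = field(default_factory=list)

    @property
    def label(self) -> str:
        if self.form == "none":
            return "-"
        tag = {"slow-fast": "S-F", "fast-slow": "F-S"}[self.form]
        return tag + ("*" if self.persistence == "echo" else "")


@dataclass
class SustainabilitySummary:
    """Fixed-point analysis of one AVNRT form at one gamma."""

    gamma: float
    form: str
    summation: pd.DataFrame          # columns interval, total, unstable
    fixed_point_exists: bool
    fixed_point_interval: float | None
    stable: bool | None              # None when no fixed point
    note: str = ""


def build_ladder(events: pd.DataFrame, topology: NodeTopology) -> LadderDiagram:
    """Group activation events into per-pathway wavefronts.

    Events of adjacent cells closer than 40 ms are chained into one
    front; the front direction is the sign of the activation-time slope
    along the anterograde cell order.  A front whose internal times rise
    then fall contains a collision of two opposing fronts: it is split at
    the latest cell and the meeting point recorded as an annihilation.
    """
    paths = _pathways(topology)
    fronts: list[Wavefront] = []
    annihilations: list[tuple[float, str, str]] = []
    ambiguous = 0
    tmin, tmax = np.inf, -np.inf

    for pname, cells in paths.items():
        if not cells:
            continue
        evs = []
        for ci, cell in enumerate(cells):
            for t in events.loc[events["cell"] == cell, "time"]:
                evs.append((float(t), ci))
                tmin, tmax = min(tmin, t), max(tmax, t)
        evs.sort()
        # union-find over events: link events on adjacent cells within gap
        parent = list(range(len(evs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

        by_cell: dict[int, list[int]] = {}
        for i, (t, ci) in enumerate(evs):
            by_cell.setdefault(ci, []).append(i)
        for ci in by_cell:
            for i in by_cell[ci]:
                for j in by_cell.get(ci + 1, ()):
                    if abs(evs[i][0] - evs[j][0]) <= WAVEFRONT_GAP:
                        union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(len(evs)):
            groups.setdefault(find(i), []).append(i)

        for g in groups.values():
            sub = sorted(((evs[i][1], evs[i][0]) for i in g))  # by cell index
            cidx = [c for c, _ in sub]
            times = [t for _, t in sub]
            if len(set(cidx)) != len(cidx):
                # same cell twice in one component: over-merged fronts
                ambiguous += 1
                continue
            if len(cidx) == 1:
                direction = "focal"
            else:
                diffs = np.diff(times)
                if np.all(diffs > 0):
                    direction = "anterograde"
                elif np.all(diffs < 0):
                    direction = "retrograde"
                else:
                    # rise-then-fall (or v-shape): opposing fronts met
                    peak = int(np.argmax(times))
                    if 0 < peak < len(times) - 1:
                        direction = "collision"
                        annihilations.append(
                            (times[peak], pname, cells[cidx[peak]])
                        )
                    else:
                        ambiguous += 1
                        direction = "collision"
            fronts.append(Wavefront(
                pathway=pname,
                cells=[cells[c] for c in cidx],
                times=times,
                direction=direction,
            ))
    if not np.isfinite(tmin):
        tmin = tmax = 0.0
    fronts.sort(key=lambda w: w.t_start)
    return LadderDiagram(wavefronts=fronts, annihilations=annihilations,
                         ambiguous=ambiguous, t_span=(float(tmin), float(tmax)))


def _reentrant_cycles(ladder: LadderDiagram, topology: NodeTopology):
    """Pair retrograde fronts in one AV pathway with anterograde fronts in
    the other; returns (form, times at the penetrating-bundle end)."""
    retro_fp = [w for w in ladder.fronts("FP") if w.direction == "retrograde"
                and len(w.cells) >= 3]
    retro_sp = [w for w in ladder.fronts("SP") if w.direction == "retrograde"
                and len(w.cells) >= 3]
    ante_sp = [w for w in ladder.fronts("SP")
               if w.direction in ("anterograde", "collision") and len(w.cells) >= 3]
    ante_fp = [w for w in ladder.fronts("FP")
               if w.direction in ("anterograde", "collision") and len(w.cells) >= 3]

    def cycles(retro, ante):
        """Retrograde front followed within one cycle by an anterograde
        front of the other pathway (or vice versa)."""
        out = []
        for w in retro:
            # the reentrant beat re-enters the other pathway near w.t_end
            partner = [a for a in ante if -150.0 <= a.t_start - w.t_start <= 250.0]
            if partner:
                out.append(w)
        return out

    sf = cycles(retro_fp, ante_sp)   # slow-fast: anterograde SP + retrograde FP
    fs = cycles(retro_sp, ante_fp)   # fast-slow: anterograde FP + retrograde SP
    if len(sf) >= len(fs) and sf:
        return "slow-fast", sorted(w.t_start for w in sf)
    if fs:
        return "fast-slow", sorted(w.t_start for w in fs)
    return "none", []


def classify_episode(
    ladder: LadderDiagram,
    schedule: ANSSchedule | None = None,
    window: tuple[float, float] | None = None,
    echo_threshold: int = ECHO_THRESHOLD,
) -> EpisodeClassification:
    """Classify reentrant activity in a ladder window.

    ``form`` is named after the anterograde limb of the reentrant cycles
    (slow pathway => slow-fast, fast pathway => fast-slow).  Reentry with
    more than ``echo_threshold`` cycles that is still running at the end
    of the window (i.e. up to the next gamma change) is sustained;
    shorter runs are echo beats.
    """
    form, starts = _reentrant_cycles(ladder, None)
    if window is None:
        window = ladder.t_span
    if form == "none" or not starts:
        return EpisodeClassification(form="none", persistence="none")
    starts = [t for t in starts if window[0] - 50.0 <= t <= window[1] + 1.0]
    if not starts:
        return EpisodeClassification(form="none", persistence="none")
    n = len(starts)
    cls = np.diff(starts).tolist()
    mean_cl = float(np.mean(cls)) if cls else 250.0
    running = (window[1] - starts[-1]) < 2.0 * mean_cl
    if n > echo_threshold and running:
        persistence = "sustained"
    else:
        persistence = "echo"
    return EpisodeClassification(form=form, persistence=persistence,
                                 n_cycles=n, cycle_lengths=cls)


def sustainability_analysis(
    topology: NodeTopology,
    gamma: float,
    form: str,
    solver: SolverOptions = SolverOptions(),
    curves: tuple | None = None,
    min_interval: float = 60.0,
) -> SustainabilitySummary:
    """Fixed-point (summation-curve) analysis of one AVNRT form.

    The anterograde limb (SP for slow-fast, FP for fast-slow) and the
    retrograde limb are measured with the S1S1 protocol on the
    single-pathway (post-ablation) preparations; their summed conduction
    time on the common pacing-interval grid is intersected with the
    identity line.  ``curves`` may supply precomputed (anterograde,
    retrograde) :class:`~avnode.protocols.ConductionCurve` objects.
    """
    if form not in ("slow-fast", "fast-slow"):
        raise ValueError(f"form must be 'slow-fast' or 'fast-slow', got {form!r}")
    a_limb = "SP" if form == "slow-fast" else "FP"
    r_limb = "FP" if form == "slow-fast" else "SP"
    if curves is None:
        a_curve = run_s1s1(topology, gamma, site="atrial",
                           ablation="FP" if a_limb == "SP" else "SP",
                           solver=solver, min_interval=min_interval)
        r_curve = run_s1s1(topology, gamma, site="his",
                           ablation="FP" if r_limb == "SP" else "SP",
                           solver=solver, min_interval=min_interval)
    else:
        a_curve, r_curve = curves

    a = a_curve.points[a_curve.points["conducted"]][["interval", "conduction_time", "unstable"]]
    r = r_curve.points[r_curve.points["conducted"]][["interval", "conduction_time", "unstable"]]
    merged = a.merge(r, on="interval", suffixes=("_a", "_r")).sort_values("interval")
    if len(merged) == 0:
        return SustainabilitySummary(
            gamma=gamma, form=form,
            summation=pd.DataFrame(columns=["interval", "total", "unstable"]),
            fixed_point_exists=False, fixed_point_interval=None, stable=None,
            note="fixed-point-undefined: conducted ranges do not overlap",
        )
    summation = pd.DataFrame({
        "interval": merged["interval"].to_numpy(),
        "total": (merged["conduction_time_a"] + merged["conduction_time_r"]).to_numpy(),
        "unstable": (merged["unstable_a"] | merged["unstable_r"]).to_numpy(),
    })
    x = summation["interval"].to_numpy(dtype=float)
    y = summation["total"].to_numpy(dtype=float)
    f = y - x
    fp_interval = None
    unstable_fp = False
    for i in range(len(x) - 1):
        if f[i] == 0.0 or f[i] * f[i + 1] < 0:
            if f[i] == 0.0:
                xi = x[i]
            else:
                xi = x[i] + (x[i + 1] - x[i]) * f[i] / (f[i] - f[i + 1])
            fp_interval = float(xi)
            unstable_fp = bool(summation["unstable"].iloc[i] or summation["unstable"].iloc[i + 1])
            break
    if fp_interval is None and len(x) and f[-1] == 0.0:
        fp_interval = float(x[-1])
        unstable_fp = bool(summation["unstable"].iloc[-1])
    exists = fp_interval is not None
    return SustainabilitySummary(
        gamma=gamma, form=form, summation=summation,
        fixed_point_exists=exists,
        fixed_point_interval=fp_interval,
        stable=(not unstable_fp) if exists else None,
        note="" if exists else "summation curve does not cross the identity line",
    )


_sinus_cache: dict[tuple, float] = {}


def sinus_interval(
    topology: NodeTopology,
    gamma: float,
    solver: SolverOptions = SolverOptions(),
    settle_ms: float = 2000.0,
    n_beats: int = 5,
) -> float:
    """Mean of the last ``n_beats`` spontaneous sinus inter-beat intervals
    (ms) after a settling pre-roll."""
    key = (id(topology), round(gamma, 12), solver, settle_ms, n_beats)
    if key in _sinus_cache:
        return _sinus_cache[key]
    sn = topology.cells_in("SN")[0]
    span = settle_ms
    chunk = max(3000.0, 500.0 * (n_beats + 2) * gamma)
    res = integrate(topology, gamma, t_span=span + chunk, solver=solver)
    times = res.events_of(sn)
    times = times[times > settle_ms * 0.5]
    while len(times) < n_beats + 1 and span + chunk < 60000.0:
        chunk *= 2
        res = integrate(topology, gamma, t_span=span + chunk, solver=solver)
        times = res.events_of(sn)
        times = times[times > settle_ms * 0.5]
    if len(times) < n_beats + 1:
        raise RateUndefinedError(f"no spontaneous sinus activity at gamma={gamma}")
    iv = float(np.mean(np.diff(times[-(n_beats + 1):])))
    _sinus_cache[key] = iv
    return iv


def sinus_rate(topology: NodeTopology, gamma: float,
               solver: SolverOptions = SolverOptions()) -> float:
    """Spontaneous sinus rate in beats per minute at the given gamma."""
    return 60000.0 / sinus_interval(topology, gamma, solver=solver)
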