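"""S1S2 / S1S1 extrastimulus protocols and refractory-period measurement.

The S1S2 protocol delivers nine basic stimuli (S1) at the spontaneous
sinus interval of the current autonomic state followed by one premature
test stimulus (S2) whose coupling interval is decremented in 1 ms steps
until conduction through the node blocks.  Conduction time is measured
between atrial cell AM2 and His cell HB1 (anterograde, atrial pacing) or
the reverse (retrograde, His-bundle pacing).  The effective refractory
period (ERP) is the longest coupling interval at which the locally
captured S2 fails to traverse the node; the shortest conducted interval
is therefore ERP + 1 ms.

The S1S1 protocol paces ten beats at a fixed interval, decremented from
the sinus interval, and measures the conduction delay of the last beat
between AM3 and the penetrating bundle.  Because conduction at short
pacing intervals can depend on the phase at which the train starts, each
point is re-run with several initial-delay offsets and flagged unstable
when the last-beat delay spreads by more than 2 ms.

Atrial stimuli are 1 ms long, His-bundle stimuli 2 ms, both delivered at
1.3 times the site threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cells import InvalidParameterError
from .engine import (
    ANSSchedule,
    SolverOptions,
    StimulusSpec,
    find_threshold,
    integrate,
    settled_state,
)
from .topology import NodeTopology, ablate

__all__ = [
    "ProtocolSpec",
    "ConductionCurve",
    "ERPTable",
    "run_s1s2",
    "run_s1s1",
    "erp_sweep",
    "ProtocolError",
    "SITES",
]

#: Stimulation and measurement sites per pacing side.
SITES = {
    "atrial": dict(stim="AM1", duration=1.0, proximal="AM2", distal="HB1",
                   ring_proximal="AM3", ring_distal="PB1"),
    "his": dict(stim="HB6", duration=2.0, proximal="HB1", distal="AM2",
                ring_proximal="PB1", ring_distal="AM3"),
}

AMPLITUDE_FACTOR = 1.3
CONDUCTION_WINDOW = 400.0   # ms after the test beat within which the
                            # transnodal response must appear
ATTRIBUTION_TOL = 3.0       # ms tolerance when matching against the
                            # stimulus-free twin run
#: Overdrive margin subtracted from the spontaneous interval for the
#: basic drive train.  The sinus node is not reset-suppressed in this
#: model, and its post-excitation cycle is slightly shorter than its
#: unperturbed period, so pacing at exactly the spontaneous interval
#: loses the phase race and the train slides into refractory tissue;
#: a small overdrive keeps every basic stimulus capturing.
OVERDRIVE_MS = 8.0
OVERDRIVE_FRAC = 0.025


def basic_interval(S: float) -> float:
    """Basic-train interval for a spontaneous sinus interval ``S``."""
    return S - max(OVERDRIVE_MS, OVERDRIVE_FRAC * S)
UNSTABLE_SPREAD = 2.0       # ms spread across initial offsets => unstable
S1S1_OFFSETS = (0.0, 37.0, 81.0)
TRAIN_LEAD = 200.0          # ms between end of settling and first S1


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one extrastimulus protocol run."""

    kind: str                     # "S1S2" | "S1S1"
    site: str                     # "atrial" | "his"
    gamma: float
    n_basic: int = 9              # 9 for S1S2 trains; 10 pulses for S1S1
    decrement: float = 1.0
    start_interval: float | None = None   # default: spontaneous sinus interval

    def __post_init__(self):
        if self.kind not in ("S1S2", "S1S1"):
            raise InvalidParameterError(f"unknown protocol kind {self.kind!r}")
        if self.site not in SITES:
            raise InvalidParameterError(f"site must be 'atrial' or 'his', got {self.site!r}")


@dataclass
class ConductionCurve:
    """Points of one conduction curve.

    ``points`` has columns interval (ms), conduction_time (ms), conducted,
    captured, unstable.
    """

    points: pd.DataFrame
    direction: str                # "anterograde" | "retrograde"
    pathway: str                  # "control" | "SP-only" | "FP-only"
    gamma: float
    kind: str = "S1S2"
    erp: float | None = None

    def conducted_points(self) -> pd.DataFrame:
        return self.points[self.points["conducted"]]

    @property
    def min_conducted_interval(self) -> float | None:
        sub = self.conducted_points()
        return float(sub["interval"].min()) if len(sub) else None


@dataclass
class ERPTable:
    """Tidy table of ERPs: columns gamma, direction, pathway, erp."""

    table: pd.DataFrame

    def _row(self, gamma: float, direction: str, pathway: str) -> pd.Series:
        sub = self.table[
            (np.isclose(self.table["gamma"], gamma))
            & (self.table["direction"] == direction)
            & (self.table["pathway"] == pathway)
        ]
        if len(sub) != 1:
            raise KeyError((gamma, direction, pathway))
        return sub.iloc[0]

    def erp(self, gamma: float, direction: str, pathway: str) -> float:
        """ERP in ms; NaN when the pathway conducted all the way down to
        the paced chain's capture floor (ERP below the measurable range)."""
        return float(self._row(gamma, direction, pathway)["erp"])

    def erp_upper_bound(self, gamma: float, direction: str, pathway: str) -> float:
        """The ERP itself, or the shortest conducted interval when the ERP
        was below the capture floor (an upper bound on the true ERP)."""
        row = self._row(gamma, direction, pathway)
        if np.isfinite(row["erp"]):
            return float(row["erp"])
        return float(row.get("floor", np.nan))

    def induction_window(self, gamma: float, direction: str = "anterograde") -> float:
        """ERP_FP - ERP_SP: the coupling-interval range where a premature
        beat blocks in one pathway but conducts in the other."""
        return self.erp(gamma, direction, "FP") - self.erp(gamma, direction, "SP")


def _pathway_label(ablation: str | None) -> str:
    return {None: "control", "FP": "SP-only", "SP": "FP-only"}[ablation]


_ablate_cache: dict[tuple[int, str], NodeTopology] = {}


def _prepared(topology: NodeTopology, ablation: str | None) -> NodeTopology:
    if ablation is None:
        return topology
    key = (id(topology), ablation)
    if key not in _ablate_cache:
        _ablate_cache[key] = ablate(topology, ablation)
    return _ablate_cache[key]


def _sinus_interval(topo: NodeTopology, gamma: float, solver: SolverOptions) -> float:
    # local import to avoid a cycle (analysis imports protocols)
    from .analysis import sinus_interval

    return sinus_interval(topo, gamma, solver=solver)


#: First-S1 phase within the spontaneous cycle, per pacing site.  The
#: sinus node keeps running during pacing (no reset line), so the train
#: must be launched at a phase that lets its first wavefront reach and
#: reset the sinus node instead of colliding mid-pathway with the next
#: spontaneous beat; His-bundle pacing needs the earlier phase because of
#: the retrograde travel time up to the atria.
TRAIN_PHASE = {"atrial": 0.8, "his": 0.5}


def _train_start(topo, gamma, cfg, S, state0, t0, solver, site, amp=None) -> float:
    """First-S1 time: phase-locked within the site's spontaneous cycle.

    Because the sinus node keeps firing during pacing, an unluckily
    phased train can lock into a permanent mid-pathway collision with
    the spontaneous rhythm and never conduct across the node.  If an
    amplitude is supplied, candidate phases are screened by simulating a
    basic train and requiring the last basic beat to traverse the node;
    the first phase that conducts is used.
    """
    probe = integrate(topo, gamma, t_span=(t0, t0 + TRAIN_LEAD + 2.2 * S),
                      initial_state=state0, solver=solver)
    evts = probe.events_of(cfg["stim"])
    evts = evts[evts > t0 + 20.0]
    if not len(evts):
        return t0 + TRAIN_LEAD
    anchor = float(evts[-1])
    phases = [TRAIN_PHASE[site], 0.35, 0.65, 0.2, 0.9]
    if amp is None:
        return anchor + phases[0] * S

    def train_conducts(t_first: float) -> bool:
        onsets = [t_first + i * S for i in range(9)]
        stims = [StimulusSpec(cfg["stim"], t, cfg["duration"], amp) for t in onsets]
        horizon = onsets[-1] + 0.9 * S
        res = integrate(topo, gamma, stimuli=stims, t_span=(t0, horizon),
                        initial_state=state0, solver=solver)
        twin = integrate(topo, gamma, t_span=(t0, horizon),
                         initial_state=state0, solver=solver)
        t_on = onsets[-1]
        cap = _new_events(res.events_of(cfg["proximal"]), twin.events_of(cfg["proximal"]),
                          t_on, t_on + 60.0)
        dist = _new_events(res.events_of(cfg["distal"]), twin.events_of(cfg["distal"]),
                           t_on, t_on + 0.9 * S)
        return len(cap) > 0 and len(dist) > 0

    for ph in phases:
        if train_conducts(anchor + ph * S):
            return anchor + ph * S
    return anchor + phases[0] * S


def _new_events(times: np.ndarray, twin: np.ndarray, lo: float, hi: float,
                tol: float = ATTRIBUTION_TOL) -> np.ndarray:
    """Events in [lo, hi] not present (within tol) in the twin run."""
    sel = times[(times >= lo) & (times <= hi)]
    if len(twin) == 0:
        return sel
    keep = [t for t in sel if not np.any(np.abs(twin - t) <= tol)]
    return np.asarray(keep)


def run_s1s2(
    topology: NodeTopology,
    gamma: float,
    site: str = "atrial",
    ablation: str | None = None,
    solver: SolverOptions = SolverOptions(),
    start_interval: float | None = None,
    min_interval: float = 40.0,
    extra_after_block: int = 12,
) -> ConductionCurve:
    """S1S2 conduction curve and ERP for one site / preparation / gamma.

    Returns a :class:`ConductionCurve` whose ``erp`` attribute is the
    longest coupling interval at which the captured S2 blocks.  Points
    where S2 fails to capture the paced site locally are flagged and the
    scan stops there.
    """
    cfg = SITES[site]
    topo = _prepared(topology, ablation)
    S = start_interval if start_interval is not None else _sinus_interval(topo, gamma, solver)
    if not np.isfinite(S):
        raise ProtocolError(f"no sinus rhythm at gamma={gamma}")
    amp = AMPLITUDE_FACTOR * find_threshold(topo, cfg["stim"], gamma, cfg["duration"],
                                            solver=solver)
    Sb = basic_interval(S)
    state0, t0 = settled_state(topo, gamma, solver=solver)
    t_first = _train_start(topo, gamma, cfg, Sb, state0, t0, solver, site, amp=amp)
    s1_onsets = [t_first + i * Sb for i in range(9)]
    s1_stims = [StimulusSpec(cfg["stim"], t, cfg["duration"], amp) for t in s1_onsets]
    t_last = s1_onsets[-1]
    t_hold = t_last + cfg["duration"] + 3.0
    train = integrate(topo, gamma, stimuli=s1_stims, t_span=(t0, t_hold),
                      initial_state=state0, solver=solver)
    state_train = train.final_state

    horizon = t_last + S + CONDUCTION_WINDOW + 50.0  # covers the longest S2
    twin = integrate(topo, gamma, t_span=(t_hold, horizon),
                     initial_state=state_train, solver=solver)
    twin_stim = twin.events_of(cfg["stim"])
    twin_prox = twin.events_of(cfg["proximal"])
    twin_dist = twin.events_of(cfg["distal"])

    rows = []
    consec_blocked = 0
    consec_nocap = 0
    ci = float(np.floor(Sb))
    while ci >= min_interval:
        s2_on = t_last + ci
        res = integrate(
            topo, gamma,
            stimuli=[StimulusSpec(cfg["stim"], s2_on, cfg["duration"], amp)],
            t_span=(t_hold, s2_on + CONDUCTION_WINDOW), initial_state=state_train,
            solver=solver,
        )
        # capture requires a propagated response at the proximal
        # measurement cell: the stimulus current alone can deflect the
        # paced cell's potential past the detection threshold without
        # starting an action potential
        prox = _new_events(res.events_of(cfg["proximal"]), twin_prox,
                           s2_on - 1e-6, s2_on + 60.0)
        captured = len(prox) > 0
        dist = _new_events(res.events_of(cfg["distal"]), twin_dist,
                           s2_on - 1e-6, s2_on + CONDUCTION_WINDOW)
        conducted = captured and len(dist) > 0
        ct = float(dist[0] - prox[0]) if conducted else np.nan
        rows.append(dict(interval=ci, conduction_time=ct, conducted=conducted,
                         captured=captured, unstable=False))
        if not captured:
            # near the sinus interval a test pulse can merge with the
            # spontaneous beat and look uncaptured; only a run of capture
            # failures marks the true local refractory floor
            consec_nocap += 1
            if consec_nocap >= 4:
                break
        else:
            consec_nocap = 0
        if not conducted:
            consec_blocked += 1
            if consec_blocked > extra_after_block:
                break
        else:
            consec_blocked = 0
        ci -= 1.0

    # ERP: longest blocked interval of the contiguous blocked run at the
    # short-interval end of the scan.  Isolated blocked points at long
    # intervals (interference with the running sinus) are not the ERP.
    erp = None
    for row in rows[::-1]:
        if not row["captured"]:
            continue
        if row["conducted"]:
            break
        erp = row["interval"]

    curve = ConductionCurve(
        points=pd.DataFrame(rows),
        direction="anterograde" if site == "atrial" else "retrograde",
        pathway=_pathway_label(ablation),
        gamma=gamma,
        kind="S1S2",
        erp=erp,
    )
    return curve


def run_s1s1(
    topology: NodeTopology,
    gamma: float,
    site: str = "atrial",
    ablation: str | None = None,
    solver: SolverOptions = SolverOptions(),
    start_interval: float | None = None,
    min_interval: float = 40.0,
    offsets: Sequence[float] = S1S1_OFFSETS,
    n_pulses: int = 10,
    decrement: float = 1.0,
) -> ConductionCurve:
    """S1S1 conduction curve (with instability flags) for one preparation.

    For each pacing interval, ``n_pulses`` stimuli are delivered and the
    conduction delay of the last beat is measured between AM3 and the
    penetrating bundle.  A point is 1:1-conducted only if every one of
    the last five beats traverses the node; 2:1 responses are excluded
    from the curve.  The point is re-run with each initial-delay offset
    and flagged unstable when the spread exceeds 2 ms.
    """
    cfg = SITES[site]
    topo = _prepared(topology, ablation)
    S = start_interval if start_interval is not None else _sinus_interval(topo, gamma, solver)
    if not np.isfinite(S):
        raise ProtocolError(f"no sinus rhythm at gamma={gamma}")
    amp = AMPLITUDE_FACTOR * find_threshold(topo, cfg["stim"], gamma, cfg["duration"],
                                            solver=solver)
    Sb = basic_interval(S)
    state0, t0 = settled_state(topo, gamma, solver=solver)

    t_first = _train_start(topo, gamma, cfg, Sb, state0, t0, solver, site, amp=amp)

    # stimulus-free twin for beat attribution, shared by all points
    max_horizon = t_first + max(offsets) + n_pulses * Sb + CONDUCTION_WINDOW
    twin = integrate(topo, gamma, t_span=(t0, max_horizon),
                     initial_state=state0, solver=solver)
    tw_p = twin.events_of(cfg["ring_proximal"])
    tw_d = twin.events_of(cfg["ring_distal"])

    def one_run(pi: float, offset: float):
        onsets = [t_first + offset + i * pi for i in range(n_pulses)]
        stims = [StimulusSpec(cfg["stim"], t, cfg["duration"], amp) for t in onsets]
        horizon = onsets[-1] + CONDUCTION_WINDOW
        res = integrate(topo, gamma, stimuli=stims, t_span=(t0, horizon),
                        initial_state=state0, solver=solver)
        prox_all = res.events_of(cfg["ring_proximal"])
        dist_all = res.events_of(cfg["ring_distal"])
        # per-beat conduction for the last five beats
        delays = []
        ok = True
        for t_on in onsets[-5:]:
            prox = _new_events(prox_all, tw_p, t_on, t_on + 60.0)
            dist = _new_events(dist_all, tw_d, t_on, t_on + min(pi, CONDUCTION_WINDOW))
            if len(prox) == 0 or len(dist) == 0 or dist[0] <= prox[0]:
                ok = False
                delays.append(np.nan)
            else:
                delays.append(float(dist[0] - prox[0]))
        return ok, delays[-1]

    rows = []
    blocked_run = 0
    pi = float(np.floor(Sb))
    while pi >= min_interval:
        oks, cts = [], []
        for off in offsets:
            ok, ct = one_run(pi, off)
            oks.append(ok)
            cts.append(ct)
        conducted = oks[0]
        ct = cts[0]
        finite = [x for x in cts if np.isfinite(x)]
        unstable = (
            (len(finite) >= 2 and (max(finite) - min(finite)) > UNSTABLE_SPREAD)
            or (any(oks) and not all(oks))
        )
        rows.append(dict(interval=pi, conduction_time=ct, conducted=conducted,
                         captured=True, unstable=unstable))
        if not any(oks):
            blocked_run += 1
            if blocked_run >= 3:
                break
        else:
            blocked_run = 0
        pi -= decrement

    return ConductionCurve(
        points=pd.DataFrame(rows),
        direction="anterograde" if site == "atrial" else "retrograde",
        pathway=_pathway_label(ablation),
        gamma=gamma,
        kind="S1S1",
    )


def erp_sweep(
    topology: NodeTopology,
    gammas: Sequence[float] = (0.8, 1.0, 1.2, 1.5, 1.7),
    directions: Sequence[str] = ("anterograde", "retrograde"),
    ablations: Sequence[str] = ("FP", "SP"),
    solver: SolverOptions = SolverOptions(),
) -> ERPTable:
    """ERPs of each isolated pathway for every (gamma, direction).

    ``ablations=("FP", "SP")`` measures the SP-only and FP-only
    preparations; pathway labels in the output name the surviving
    pathway.  The anterograde induction window aERP_FP - aERP_SP is
    available from :meth:`ERPTable.induction_window`.
    """
    site_of = {"anterograde": "atrial", "retrograde": "his"}
    rows = []
    for g in gammas:
        for direction in directions:
            for ab in ablations:
                surviving = "SP" if ab == "FP" else "FP"
                curve = run_s1s2(topology, g, site=site_of[direction], ablation=ab,
                                 solver=solver)
                floor = curve.min_conducted_interval
                rows.append(dict(gamma=g, direction=direction, pathway=surviving,
                                 erp=curve.erp if curve.erp is not None else np.nan,
                                 floor=floor if floor is not None else np.nan))
    return ERPTable(table=pd.DataFrame(rows))
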