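"""Scripted premature-complex scenarios and the variant/gamma outcome grid.

Three induction mechanisms are modelled, classified by the origin of the
premature complex:

* PAC -- a premature atrial stimulus delivered into the induction window
  (between the anterograde ERPs of the two AV-nodal pathways);
* PVC -- a premature His-bundle stimulus (the model has no ventricles;
  His-bundle origin stands in for ventricular ectopy);
* PJC -- no external stimulus: a brief burst of very strong sympathetic
  tone (gamma dropped to 0.57) drives the sinus rate so high that the
  slow pathway blocks, which can start fast-slow reentry from within the
  junction.

A scenario executes a stepwise gamma schedule, applies the premature
stimulus (or burst), classifies the reentrant activity in every gamma
epoch, and reports when and how a tachycardia terminates.  The outcome
grid over all variants, mechanisms and gamma values is compared against
the packaged expectation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import (
    EpisodeClassification,
    build_ladder,
    classify_episode,
    sinus_interval,
)
from .engine import (
    ANSSchedule,
    SolverOptions,
    StimulusSpec,
    find_threshold,
    integrate,
    settled_state,
)
from .protocols import AMPLITUDE_FACTOR, SITES
from .topology import NodeTopology, build_variant

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "run_scenario",
    "table1_matrix",
    "expected_table1",
    "PJC_BURST_GAMMA",
    "PJC_BURST_MS",
    "EPOCH_DWELL_MS",
]

PJC_BURST_GAMMA = 0.57
PJC_BURST_MS = 1500.0
EPOCH_DWELL_MS = 3000.0


@dataclass(frozen=True)
class ScenarioSpec:
    """One scripted experiment.

    ``premature_timing`` is the coupling interval (ms) between the last
    spontaneous activation at the stimulation site and the premature
    stimulus; None triggers a scan of the induction window.  PJC
    scenarios carry burst parameters instead of a stimulus.
    """

    variant_id: int
    induction: str                        # "PAC" | "PVC" | "PJC"
    gamma_schedule: ANSSchedule
    premature_timing: float | None = None
    burst_gamma: float = PJC_BURST_GAMMA
    burst_ms: float = PJC_BURST_MS

    def __post_init__(self):
        if self.induction not in ("PAC", "PVC", "PJC"):
            raise ValueError(f"induction must be PAC/PVC/PJC, got {self.induction!r}")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    epochs: list[tuple[float, float, float, EpisodeClassification]]
    events: pd.DataFrame
    chosen_timing: float | None
    termination: tuple[float, str] | None   # (gamma of terminating epoch, mechanism)

    @property
    def timeline(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(t0=a, t1=b, gamma=g, form=c.form, persistence=c.persistence,
                  n_cycles=c.n_cycles, label=c.label)
             for a, b, g, c in self.epochs]
        )


def _stim_site(induction: str) -> dict:
    return SITES["atrial"] if induction == "PAC" else SITES["his"]


def _classify_window(events: pd.DataFrame, topo: NodeTopology,
                     window: tuple[float, float]) -> EpisodeClassification:
    sub = events[(events["time"] >= window[0] - 100.0) & (events["time"] <= window[1])]
    ladder = build_ladder(sub, topo)
    return classify_episode(ladder, window=window)


def _induces(events: pd.DataFrame, topo: NodeTopology,
             window: tuple[float, float]) -> EpisodeClassification:
    return _classify_window(events, topo, window)


def induction_attempt(
    topo: NodeTopology,
    gamma: float,
    induction: str,
    timing: float | None,
    solver: SolverOptions = SolverOptions(),
    observe_ms: float = EPOCH_DWELL_MS,
    timing_step: float = 1.0,
    timing_range: tuple[float, float] | None = None,
) -> tuple[EpisodeClassification, float | None, np.ndarray | None, float, pd.DataFrame]:
    """Deliver one premature stimulus (scanning the coupling interval if
    ``timing`` is None) and classify the following window.

    Returns (classification, timing_used, final_state, t_end, events).
    """
    cfg = _stim_site(induction)
    S = sinus_interval(topo, gamma, solver=solver)
    amp = AMPLITUDE_FACTOR * find_threshold(topo, cfg["stim"], gamma, cfg["duration"],
                                            solver=solver)
    state0, t0 = settled_state(topo, gamma, solver=solver)
    # reference activation of the site: last spontaneous beat before stimulus
    probe = integrate(topo, gamma, t_span=(t0, t0 + 3.0 * S + 200.0),
                      initial_state=state0, solver=solver)
    site_evts = probe.events_of(cfg["stim"])
    site_evts = site_evts[site_evts > t0 + 50.0]
    if len(site_evts) == 0:
        raise RuntimeError(f"site {cfg['stim']} never activates at gamma={gamma}")
    t_ref = float(site_evts[min(1, len(site_evts) - 1)])

    if timing_range is None:
        timing_range = (0.25 * S, 0.95 * S)

    def attempt(ci: float):
        onset = t_ref + ci
        res = integrate(
            topo, gamma,
            stimuli=[StimulusSpec(cfg["stim"], onset, cfg["duration"], amp)],
            t_span=(t0, onset + observe_ms), initial_state=state0, solver=solver,
        )
        cls = _classify_window(res.events, topo, (onset, onset + observe_ms))
        return cls, res

    if timing is not None:
        cls, res = attempt(timing)
        return cls, timing, res.final_state, t_ref + timing + observe_ms, res.events

    best = (EpisodeClassification(form="none", persistence="none"), None, None, 0.0, None)
    ci = timing_range[0]
    while ci <= timing_range[1]:
        cls, res = attempt(ci)
        if cls.form != "none":
            return cls, ci, res.final_state, t_ref + ci + observe_ms, res.events
        ci += timing_step
    # no induction anywhere in the window
    cls, res = attempt(timing_range[1])
    return (EpisodeClassification(form="none", persistence="none"),
            None, res.final_state, t_ref + timing_range[1] + observe_ms, res.events)


def _termination_mechanism(events: pd.DataFrame, topo: NodeTopology,
                           around: float) -> str:
    """Mechanism of spontaneous termination: which pathway blocked.

    Looks at partial (incomplete) fronts near the last reentrant cycle;
    an incomplete fast-pathway traversal means the reentrant impulse died
    in the FP."""
    sub = events[(events["time"] >= around - 400.0) & (events["time"] <= around + 400.0)]
    ladder = build_ladder(sub, topo)
    n_fp = len(topo.cells_in("FP"))
    n_sp = len(topo.cells_in("SP"))
    fp_partial = any(1 <= len(w.cells) < max(2, n_fp - 1) for w in ladder.fronts("FP"))
    sp_partial = any(1 <= len(w.cells) < max(2, n_sp - 1) for w in ladder.fronts("SP"))
    if fp_partial and not sp_partial:
        return "FP block"
    if sp_partial and not fp_partial:
        return "SP block"
    if fp_partial and sp_partial:
        return "FP block"
    return "fixed-point loss"


def run_scenario(
    spec: ScenarioSpec,
    topology: NodeTopology | None = None,
    solver: SolverOptions = SolverOptions(),
    timing_step: float = 1.0,
) -> ScenarioResult:
    """Execute a scenario: settle, induce (stimulus or gamma burst), then
    walk the gamma schedule classifying each epoch."""
    topo = topology if topology is not None else build_variant(spec.variant_id)
    sched = spec.gamma_schedule
    bps = list(sched.breakpoints)
    gamma0 = bps[0][1]

    if spec.induction == "PJC":
        # burst is expressed in the schedule itself: ensure it is present
        has_burst = any(abs(g - spec.burst_gamma) < 1e-9 for _, g in bps)
        if not has_burst:
            raise ValueError("PJC scenario schedule must contain the burst epoch")
        state0, t0 = settled_state(topo, gamma0, solver=solver)
        sched_run = sched.shifted(t0) if bps[0][0] == 0.0 else sched
        t_end = sched_run.breakpoints[-1][0] + EPOCH_DWELL_MS
        res = integrate(topo, sched_run, t_span=(t0, t_end),
                        initial_state=state0, solver=solver)
        events = res.events
        chosen = None
        epochs_bounds = [(tb, g) for tb, g in sched_run.breakpoints]
    else:
        cls0, chosen, state_after, t_after, ev0 = induction_attempt(
            topo, gamma0, spec.induction, spec.premature_timing, solver=solver,
            observe_ms=EPOCH_DWELL_MS, timing_step=timing_step,
        )
        # continue through the remaining schedule from the post-induction state
        rest = [(t_after + (tb - bps[0][0]), g) for tb, g in bps[1:]]
        if rest:
            sched_run = ANSSchedule([(0.0, gamma0)] + rest)
            t_end = rest[-1][0] + EPOCH_DWELL_MS
            res = integrate(topo, sched_run, t_span=(t_after, t_end),
                            initial_state=state_after, solver=solver)
            events = pd.concat([ev0, res.events], ignore_index=True)
            epochs_bounds = [(float(ev0["time"].min() if len(ev0) else 0.0), gamma0)] + rest
        else:
            events = ev0
            epochs_bounds = [(float(ev0["time"].min() if len(ev0) else 0.0), gamma0)]
            t_end = t_after

    epochs = []
    for i, (tb, g) in enumerate(epochs_bounds):
        te = epochs_bounds[i + 1][0] if i + 1 < len(epochs_bounds) else t_end
        cls = _classify_window(events, topo, (tb, te))
        epochs.append((tb, te, g, cls))

    termination = None
    for (a, b, g, c), (a2, b2, g2, c2) in zip(epochs, epochs[1:]):
        if c.persistence == "sustained" and c2.persistence != "sustained":
            mech = _termination_mechanism(events, topo, around=a2 + 100.0)
            termination = (g2, mech)
            break

    return ScenarioResult(spec=spec, epochs=epochs, events=events,
                          chosen_timing=chosen, termination=termination)


# --------------------------------------------------------------------------
# outcome grid (variants x mechanisms x gamma)

GRID_GAMMAS = (0.8, 1.0, 1.2, None, 1.7, 2.0)   # None => 1.4 or 1.5 by variant


def _grid_gammas(variant_id: int) -> list[float]:
    mid = 1.4 if variant_id == 2 else 1.5
    return [g if g is not None else mid for g in GRID_GAMMAS]


def expected_table1() -> pd.DataFrame:
    """Packaged expected outcome grid (long form: variant, induction,
    row_type, gamma_col, label)."""
    with resources.files("avnode.data").joinpath("table1_expected.csv").open("r") as fh:
        return pd.read_csv(fh)


def table1_matrix(
    variant_id: int,
    topology: NodeTopology | None = None,
    solver: SolverOptions = SolverOptions(),
    timing_step: float = 2.0,
    dwell_ms: float = EPOCH_DWELL_MS,
    compare: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, float | None]:
    """Outcome grid of one variant over gamma x {PAC, PVC, PJC}.

    Two row types per mechanism mirror the summary table: "Pulse" is
    direct induction at the column's gamma; "ANS tone change" induces at
    a favourable gamma (or with the sympathetic burst for PJC) and then
    steps gamma to the column value, probing sustainability.  Returns
    (grid, per-cell comparison against the expectation, match fraction).
    """
    topo = topology if topology is not None else build_variant(variant_id)
    gammas = _grid_gammas(variant_id)
    rows = []

    pulse_results: dict[tuple[str, float], EpisodeClassification] = {}
    pulse_states: dict[tuple[str, float], tuple[np.ndarray, float, float]] = {}
    for mech in ("PAC", "PVC"):
        for g in gammas:
            try:
                cls, timing, state, t_end, _ = induction_attempt(
                    topo, g, mech, None, solver=solver, observe_ms=dwell_ms,
                    timing_step=timing_step,
                )
            except Exception:
                cls, timing, state, t_end = (
                    EpisodeClassification(form="none", persistence="none"), None, None, 0.0)
            pulse_results[(mech, g)] = cls
            if cls.persistence == "sustained" and state is not None:
                pulse_states[(mech, g)] = (state, t_end, g)
            rows.append(dict(induction=mech, row_type="Pulse", gamma=g, label=cls.label))

    def sustain_from(state, t_end, g_from, g_to) -> EpisodeClassification:
        sched = ANSSchedule([(0.0, g_from), (t_end + 10.0, g_to)])
        res = integrate(topo, sched, t_span=(t_end, t_end + 10.0 + dwell_ms),
                        initial_state=state, solver=solver)
        return _classify_window(res.events, topo, (t_end + 10.0, t_end + 10.0 + dwell_ms))

    for mech in ("PAC", "PVC"):
        seed = None
        for g in gammas:
            cls = pulse_results[(mech, g)]
            if cls.persistence == "sustained":
                seed = pulse_states[(mech, g)]
                break
        for g in gammas:
            if seed is None:
                label = "-"
            else:
                state, t_end, g_from = seed
                label = sustain_from(state, t_end, g_from, g).label
            rows.append(dict(induction=mech, row_type="ANS tone change",
                             gamma=g, label=label))

    # PJC: sympathetic burst at gamma0 = 1.0, then step to each target
    state0, t0 = settled_state(topo, 1.0, solver=solver)
    burst_sched = ANSSchedule([(0.0, 1.0), (t0 + 500.0, PJC_BURST_GAMMA),
                               (t0 + 500.0 + PJC_BURST_MS, 1.0)])
    t_end = t0 + 500.0 + PJC_BURST_MS + dwell_ms
    burst = integrate(topo, burst_sched, t_span=(t0, t_end),
                      initial_state=state0, solver=solver)
    burst_cls = _classify_window(burst.events, topo,
                                 (t0 + 500.0 + PJC_BURST_MS, t_end))
    for g in gammas:
        if burst_cls.persistence != "sustained":
            label = "-"
        else:
            label = sustain_from(burst.final_state, t_end, 1.0, g).label
        rows.append(dict(induction="PJC", row_type="ANS tone change",
                         gamma=g, label=label))

    grid = pd.DataFrame(rows)
    grid.insert(0, "variant", variant_id)
    grid["gamma_col"] = [
        "1.4/1.5" if gc is None else f"{gc:g}"
        for gc in list(GRID_GAMMAS) * (len(grid) // 6)
    ]
    if not compare:
        return grid, None, None
    exp = expected_table1()
    exp = exp[exp["variant"] == variant_id]
    merged = grid.merge(exp, on=["variant", "induction", "row_type", "gamma_col"],
                        suffixes=("", "_expected"))
    merged["match"] = merged["label"] == merged["label_expected"]
    frac = float(merged["match"].mean()) if len(merged) else None
    return grid, merged, frac
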