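"""Ladder construction, episode classification, fixed-point analysis."""

import numpy as np
import pandas as pd
import pytest

from avnode.analysis import (
    ECHO_THRESHOLD,
    EpisodeClassification,
    build_ladder,
    classify_episode,
    sinus_interval,
    sinus_rate,
    sustainability_analysis,
)
from avnode.engine import SolverOptions, integrate
from avnode.protocols import ConductionCurve


def _events(rows):
    return pd.DataFrame(rows, columns=["cell", "time"])


def test_single_wavefront_ladder(variant1):
    fp = variant1.cells_in("FP")
    ev = _events([(c, 100.0 + 3.0 * i) for i, c in enumerate(fp)])
    ladder = build_ladder(ev, variant1)
    fronts = ladder.fronts("FP")
    assert len(fronts) == 1
    assert fronts[0].direction == "anterograde"
    assert ladder.annihilations == []
    assert ladder.ambiguous == 0


def test_retrograde_front_direction(variant1):
    fp = variant1.cells_in("FP")
    ev = _events([(c, 100.0 + 3.0 * (len(fp) - i)) for i, c in enumerate(fp)])
    ladder = build_ladder(ev, variant1)
    assert ladder.fronts("FP")[0].direction == "retrograde"


def test_collision_marks_annihilation(variant1):
    """Opposing fronts meeting mid-pathway: activation times rise toward
    the meeting cell from both ends."""
    sp = variant1.cells_in("SP")
    times = [100.0 + 4.0 * min(i, len(sp) - 1 - i) for i in range(len(sp))]
    ladder = build_ladder(_events(list(zip(sp, times))), variant1)
    assert len(ladder.annihilations) == 1
    t, pathway, cell = ladder.annihilations[0]
    assert pathway == "SP"
    assert cell in (sp[len(sp) // 2 - 1], sp[len(sp) // 2], sp[len(sp) // 2 + 1])


def test_quiescent_classification(variant1):
    ladder = build_ladder(_events([]), variant1)
    cls = classify_episode(ladder)
    assert (cls.form, cls.persistence) == ("none", "none")


def _reentry_events(topo, n_cycles, cl=150.0, t0=100.0):
    """Synthetic slow-fast reentry: anterograde SP fronts paired with
    retrograde FP fronts, n_cycles times."""
    sp = topo.cells_in("SP")
    fp = topo.cells_in("FP")
    rows = []
    for k in range(n_cycles):
        base = t0 + k * cl
        rows += [(c, base + 8.0 * i) for i, c in enumerate(sp)]            # antero SP
        rows += [(c, base + 90.0 + 3.0 * (len(fp) - i)) for i, c in enumerate(fp)]  # retro FP
    return _events(rows)


def test_echo_vs_sustained_threshold(variant1):
    few = _reentry_events(variant1, 3)
    cls = classify_episode(build_ladder(few, variant1),
                           window=(0.0, 3 * 150.0 + 2000.0))
    assert cls.form == "slow-fast"
    assert cls.persistence == "echo"
    assert cls.n_cycles == 3

    many = _reentry_events(variant1, ECHO_THRESHOLD + 4)
    end = 100.0 + (ECHO_THRESHOLD + 4) * 150.0
    cls2 = classify_episode(build_ladder(many, variant1), window=(0.0, end))
    assert cls2.form == "slow-fast"
    assert cls2.persistence == "sustained"
    assert cls2.label == "S-F"


def test_fast_slow_labelling(variant1):
    """Anterograde FP + retrograde SP is the atypical form."""
    sp = variant1.cells_in("SP")
    fp = variant1.cells_in("FP")
    rows = []
    for k in range(2):
        base = 100.0 + k * 160.0
        rows += [(c, base + 3.0 * i) for i, c in enumerate(fp)]
        rows += [(c, base + 60.0 + 8.0 * (len(sp) - i)) for i, c in enumerate(sp)]
    cls = classify_episode(build_ladder(_events(rows), variant1),
                           window=(0.0, 2000.0))
    assert cls.form == "fast-slow"
    assert cls.label == "F-S*"


def _fake_curve(intervals, cts, direction, pathway, unstable=None):
    n = len(intervals)
    pts = pd.DataFrame({
        "interval": intervals,
        "conduction_time": cts,
        "conducted": [True] * n,
        "captured": [True] * n,
        "unstable": unstable if unstable is not None else [False] * n,
    })
    return ConductionCurve(points=pts, direction=direction, pathway=pathway,
                           gamma=1.0, kind="S1S1")


def test_fixed_point_from_constructed_curves(variant1):
    """Hand-built limb curves whose summation crosses y = x.  Totals are
    145 at interval 140 and 134 at 141, so the residuals are +5 and -7
    and linear interpolation puts the crossing at 140 + 5/12 ms."""
    iv = np.arange(120.0, 180.0)
    a = _fake_curve(iv, np.where(iv <= 140, 100.0, 89.0), "anterograde", "SP-only")
    r = _fake_curve(iv, np.full(len(iv), 45.0), "retrograde", "FP-only")
    s = sustainability_analysis(variant1, 1.0, "slow-fast", curves=(a, r))
    assert s.fixed_point_exists
    assert s.stable is True
    assert s.fixed_point_interval == pytest.approx(140.0 + 5.0 / 12.0, abs=1e-9)


def test_no_fixed_point_when_curve_above_identity(variant1):
    iv = np.arange(120.0, 160.0)
    a = _fake_curve(iv, np.full(len(iv), 150.0), "anterograde", "SP-only")
    r = _fake_curve(iv, np.full(len(iv), 60.0), "retrograde", "FP-only")
    s = sustainability_analysis(variant1, 1.0, "slow-fast", curves=(a, r))
    assert not s.fixed_point_exists
    assert s.fixed_point_interval is None


def test_fixed_point_in_unstable_region_flagged(variant1):
    iv = np.arange(120.0, 180.0)
    a = _fake_curve(iv, np.where(iv <= 140, 100.0, 89.0), "anterograde", "SP-only",
                    unstable=(iv <= 145))
    r = _fake_curve(iv, np.full(len(iv), 45.0), "retrograde", "FP-only")
    s = sustainability_analysis(variant1, 1.0, "slow-fast", curves=(a, r))
    assert s.fixed_point_exists
    assert s.stable is False


def test_disjoint_limb_ranges_reported(variant1):
    a = _fake_curve(np.arange(120.0, 140.0), np.full(20, 90.0), "anterograde", "SP-only")
    r = _fake_curve(np.arange(200.0, 220.0), np.full(20, 40.0), "retrograde", "FP-only")
    s = sustainability_analysis(variant1, 1.0, "slow-fast", curves=(a, r))
    assert not s.fixed_point_exists
    assert "undefined" in s.note


def test_sinus_rate_orders_with_gamma(variant1):
    assert sinus_rate(variant1, 0.8) > sinus_rate(variant1, 1.7) > sinus_rate(variant1, 2.0)


def test_sinus_interval_solver_robustness(variant1):
    """The measured rate is a property of the model, not of the solver
    discretisation: changing the maximum step leaves it within 0.5 bpm."""
    a = 60000.0 / sinus_interval(variant1, 1.2)
    b = 60000.0 / sinus_interval(variant1, 1.2, solver=SolverOptions(max_step=0.5))
    assert abs(a - b) < 0.5
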