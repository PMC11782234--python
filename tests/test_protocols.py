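"""Extrastimulus protocols: S1S2 curves, ERPs, S1S1 instability flags."""

import numpy as np
import pandas as pd
import pytest

from avnode.cells import InvalidParameterError
from avnode.protocols import (
    ConductionCurve,
    ERPTable,
    ProtocolSpec,
    basic_interval,
    erp_sweep,
    run_s1s1,
    run_s1s2,
)


@pytest.fixture(scope="module")
def sp_curve(variant1):
    """Anterograde slow-pathway curve (FP ablated) at gamma = 1.2."""
    return run_s1s2(variant1, 1.2, site="atrial", ablation="FP")


@pytest.fixture(scope="module")
def fp_curve(variant1):
    return run_s1s2(variant1, 1.2, site="atrial", ablation="SP")


def test_protocol_spec_validation():
    ProtocolSpec(kind="S1S2", site="atrial", gamma=1.0)
    with pytest.raises(InvalidParameterError):
        ProtocolSpec(kind="S3", site="atrial", gamma=1.0)
    with pytest.raises(InvalidParameterError):
        ProtocolSpec(kind="S1S1", site="ventricular", gamma=1.0)


def test_basic_interval_overdrives():
    assert basic_interval(200.0) == pytest.approx(192.0)
    assert basic_interval(400.0) == pytest.approx(390.0)


def test_s1s2_curve_shape(sp_curve):
    pts = sp_curve.points
    # intervals strictly decreasing by 1 ms
    assert np.allclose(np.diff(pts["interval"]), -1.0)
    conducted = pts[pts["conducted"]]
    assert len(conducted) > 20
    assert (conducted["conduction_time"] > 0).all()
    assert sp_curve.direction == "anterograde"
    assert sp_curve.pathway == "SP-only"


def test_s1s2_erp_bracketing(sp_curve):
    """The interval at the ERP blocks; one millisecond longer conducts."""
    erp = sp_curve.erp
    assert erp is not None
    pts = sp_curve.points.set_index("interval")
    assert not pts.loc[erp, "conducted"]
    assert pts.loc[erp + 1.0, "conducted"]


def test_conduction_slows_toward_erp(sp_curve):
    """Decremental conduction: delay near the ERP well above the delay at
    long coupling intervals."""
    conducted = sp_curve.points[sp_curve.points["conducted"]]
    long_ct = conducted["conduction_time"].iloc[:10].mean()
    short_ct = conducted["conduction_time"].iloc[-3:].mean()
    assert short_ct > long_ct + 10.0


def test_fast_pathway_longer_erp_shorter_delay(sp_curve, fp_curve):
    """The defining dual-pathway asymmetry at one autonomic state: the
    fast pathway conducts faster but blocks earlier (longer ERP)."""
    assert fp_curve.erp > sp_curve.erp
    fp_ct = fp_curve.points[fp_curve.points["conducted"]]["conduction_time"].iloc[:10].mean()
    sp_ct = sp_curve.points[sp_curve.points["conducted"]]["conduction_time"].iloc[:10].mean()
    assert fp_ct < sp_ct


def test_s1s1_curve_and_instability(variant1):
    curve = run_s1s1(variant1, 1.2, site="atrial", ablation="FP",
                     min_interval=140.0)
    pts = curve.points
    assert curve.kind == "S1S1"
    conducted = pts[pts["conducted"]]
    assert len(conducted) > 10
    # near the spontaneous interval no point is unstable
    top = pts.iloc[:8]
    assert not top["unstable"].any()
    # conduction time non-increasing as the pacing interval grows, up to
    # small alternans bumps
    c = conducted.sort_values("interval")
    assert c["conduction_time"].iloc[-1] <= c["conduction_time"].iloc[0] + 5.0


def test_erp_sweep_table(variant1):
    table = erp_sweep(variant1, gammas=(1.0, 1.7))
    df = table.table
    assert len(df) == 2 * 2 * 2                      # gamma x direction x pathway
    assert set(df["pathway"]) == {"SP", "FP"}
    # anterograde ordering and its gamma trend at these states
    assert table.erp(1.0, "anterograde", "SP") < table.erp(1.0, "anterograde", "FP")
    assert table.erp(1.7, "anterograde", "SP") < table.erp(1.7, "anterograde", "FP")
    assert table.induction_window(1.0) > 0
    # upper-bound accessor falls back to the conducted floor
    for g in (1.0, 1.7):
        for d in ("anterograde", "retrograde"):
            for p in ("SP", "FP"):
                assert np.isfinite(table.erp_upper_bound(g, d, p))
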