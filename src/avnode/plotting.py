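"""Figure rendering: Lewis ladder diagrams and conduction-curve panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import LadderDiagram
from .protocols import ConductionCurve
from .topology import NodeTopology

__all__ = ["plot_ladder", "plot_conduction_curves"]

_PATH_COLOR = {"atrial": "0.3", "FP": "tab:red", "SP": "tab:blue", "his": "0.3"}


def _levels(topo: NodeTopology) -> dict[str, float]:
    """Vertical coordinate of each cell: atrium at the top, His at the
    bottom, FP and SP sharing the nodal span."""
    lv: dict[str, float] = {}
    atr = topo.cells_in("SN") + topo.cells_in("PS") + topo.cells_in("AM")
    fp = topo.cells_in("FP")
    sp = topo.cells_in("SP")
    his = topo.cells_in("PB") + topo.cells_in("HB")
    y = 0.0
    for c in atr:
        lv[c] = y
        y += 1.0
    top, bottom = y, y + 9.0
    for i, c in enumerate(fp):
        lv[c] = top + (bottom - top) * (i + 1) / (len(fp) + 1)
    for i, c in enumerate(sp):
        lv[c] = top + (bottom - top) * (i + 1) / (len(sp) + 1)
    y = bottom
    for c in his:
        lv[c] = y
        y += 1.0
    return lv


def plot_ladder(
    ladder: LadderDiagram,
    topology: NodeTopology,
    trajectory: pd.DataFrame | None = None,
    path: str | None = None,
    title: str = "",
):
    """Three-panel ladder figure: fronts (FP red, SP blue) over time, and
    optionally the FP / SP action-potential traces below."""
    lv = _levels(topology)
    n_panels = 3 if trajectory is not None else 1
    fig, axes = plt.subplots(n_panels, 1, figsize=(11, 3 * n_panels),
                             sharex=True, squeeze=False)
    ax = axes[0][0]
    for w in ladder.wavefronts:
        ys = [lv[c] for c in w.cells]
        ax.plot(w.times, ys, "-", color=_PATH_COLOR.get(w.pathway, "k"), lw=1.2)
    for t, pathway, cell in ladder.annihilations:
        ax.plot([t], [lv[cell]], "kx", ms=6)
    ax.invert_yaxis()
    ax.set_ylabel("SN -> HB level")
    ax.set_title(title)
    if trajectory is not None:
        for axi, seg, color in ((axes[1][0], "FP", "tab:red"), (axes[2][0], "SP", "tab:blue")):
            cells = topology.cells_in(seg)
            for j, c in enumerate(cells):
                sub = trajectory[trajectory["cell"] == c]
                axi.plot(sub["time"], sub["V"] + 1.3 * j, color=color, lw=0.6)
            axi.set_ylabel(seg)
        axes[-1][0].set_xlabel("time (ms)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=130)
        plt.close(fig)
        return None
    return fig


def plot_conduction_curves(curves: list[ConductionCurve], path: str | None = None,
                           identity_line: bool = False, title: str = ""):
    """Conduction time vs coupling/pacing interval for a set of curves;
    unstable stretches drawn dotted and thick."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for cv in curves:
        pts = cv.points[cv.points["conducted"]]
        lab = f"{cv.pathway} {cv.direction} g={cv.gamma:g}"
        (line,) = ax.plot(pts["interval"], pts["conduction_time"], "-o", ms=2.5, label=lab)
        uns = pts[pts["unstable"]]
        if len(uns):
            ax.plot(uns["interval"], uns["conduction_time"], ":", lw=3,
                    color=line.get_color())
        if cv.erp is not None:
            ax.axvline(cv.erp, color=line.get_color(), ls="--", lw=0.7)
    if identity_line:
        lims = ax.get_xlim()
        xs = np.linspace(*lims, 10)
        ax.plot(xs, xs, "k-", lw=1)
    ax.set_xlabel("interval (ms)")
    ax.set_ylabel("conduction time (ms)")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=130)
        plt.close(fig)
        return None
    return fig
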