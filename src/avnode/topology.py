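"""Branched topology of the compact rabbit AV-node conduction model.

The default network has 32 cells arranged as

    SN1-SN2 - PS1-PS2 - AM1-AM2-AM3 -+- FP1..FP8 -+- PB - HB1..HB6
                                     +- SP1..SP10 -+

i.e. a linear atrial approach (sinus node SN, peripheral sinus cells PS,
atrial muscle AM) that splits at the distal atrial cell into the fast
pathway (FP) and slow pathway (SP), which rejoin at the penetrating
bundle (PB) and continue into the His bundle (HB).  The FP/SP ring is the
substrate for AV-nodal reentry.

Cells SN..PB are under autonomic (gamma) control; HB cells are not.  The
sinus node cells are the primary pacemaker; the distal slow-pathway cell
carries a slower latent (AV-junctional) pacemaker.

Three model variants differing in retrograde pathway properties are
provided by :func:`build_variant`.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import CellParams, LinkSpec, InvalidParameterError

__all__ = [
    "NodeTopology",
    "VariantSpec",
    "SEGMENTS",
    "DEFAULT_COUNTS",
    "build_variant",
    "ablate",
    "TopologyError",
]

SEGMENTS = ("SN", "PS", "AM", "FP", "SP", "PB", "HB")

#: Default number of cells per segment (total 32).
DEFAULT_COUNTS: Mapping[str, int] = {
    "SN": 2, "PS": 2, "AM": 3, "FP": 8, "SP": 10, "PB": 1, "HB": 6,
}


class TopologyError(ValueError):
    """The topology violates a structural constraint."""


@dataclass
class NodeTopology:
    """Cells, links and measurement sites of the conduction network.

    ``cells`` maps cell id (e.g. ``"FP3"``) to its :class:`CellParams` in
    anatomical (anterograde) order.  ``links`` are directed anterograde.
    ``time_scale`` converts model time units to milliseconds.
    """

    cells: dict[str, CellParams]
    links: list[LinkSpec]
    time_scale: float = 1.0
    variant_id: int | None = None
    ablated: str | None = None

    # ---- structural queries -------------------------------------------------

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def segment_of(self, cell_id: str) -> str:
        seg = "".join(ch for ch in cell_id if not ch.isdigit())
        if seg not in SEGMENTS:
            raise TopologyError(f"unknown segment for cell {cell_id!r}")
        return seg

    def cells_in(self, segment: str) -> list[str]:
        return [c for c in self.cells if self.segment_of(c) == segment]

    def link(self, from_cell: str, to_cell: str) -> LinkSpec:
        for l in self.links:
            if l.from_cell == from_cell and l.to_cell == to_cell:
                return l
        raise TopologyError(f"no link {from_cell}->{to_cell}")

    def index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise TopologyError(f"unknown cell {cell_id!r}") from None

    @property
    def named_cells(self) -> dict[str, str]:
        """Measurement / stimulation sites referenced by the protocols."""
        out = {}
        for name in ("SN1", "AM1", "AM2", "AM3", "SP10", "PB1", "HB1", "HB6"):
            if name in self.cells:
                out[name] = name
        return out

    # ---- editing ------------------------------------------------------------

    def copy(self) -> "NodeTopology":
        return NodeTopology(
            cells=dict(self.cells),
            links=list(self.links),
            time_scale=self.time_scale,
            variant_id=self.variant_id,
            ablated=self.ablated,
        )

    def set_cell(self, cell_id: str, **fields) -> None:
        if cell_id not in self.cells:
            raise TopologyError(f"unknown cell {cell_id!r}")
        self.cells[cell_id] = self.cells[cell_id].with_(**fields)

    def set_link(self, from_cell: str, to_cell: str, **fields) -> None:
        for i, l in enumerate(self.links):
            if l.from_cell == from_cell and l.to_cell == to_cell:
                self.links[i] = l.with_(**fields)
                return
        raise TopologyError(f"no link {from_cell}->{to_cell}")

    # ---- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check connectivity, ring structure, pacemakers and flags."""
        ids = set(self.cells)
        for l in self.links:
            if l.from_cell not in ids or l.to_cell not in ids:
                raise TopologyError(f"dangling link {l.from_cell}->{l.to_cell}")
        # connectivity (undirected)
        adj: dict[str, set[str]] = {c: set() for c in ids}
        for l in self.links:
            adj[l.from_cell].add(l.to_cell)
            adj[l.to_cell].add(l.from_cell)
        seen: set[str] = set()
        stack = [next(iter(ids))]
        while stack:
            c = stack.pop()
            if c in seen:
                continue
            seen.add(c)
            stack.extend(adj[c] - seen)
        if seen != ids:
            raise TopologyError(f"disconnected cells: {sorted(ids - seen)}")
        # cycle count: a single FP/SP ring means E = N (one independent cycle)
        # unless a pathway has been ablated, in which case the graph is a tree.
        n_edges = len(self.links)
        if self.ablated is None and n_edges != self.n_cells:
            raise TopologyError(
                f"expected one ring (edges == cells), got {n_edges} edges / {self.n_cells} cells"
            )
        if self.ablated is not None and n_edges != self.n_cells - 1:
            raise TopologyError("ablated topology must be a tree")
        # gamma flags: SN..PB controlled, HB not
        for c, p in self.cells.items():
            seg = self.segment_of(c)
            if (seg != "HB") != p.gamma_controlled:
                raise TopologyError(f"gamma_controlled flag wrong on {c}")
        # pacemakers
        if not any(self.cells[c].is_pacemaker for c in self.cells_in("SN")):
            raise TopologyError("no sinus-node pacemaker")
        if self.ablated != "SP" and not any(
            self.cells[c].is_pacemaker for c in self.cells_in("SP")
        ):
            raise TopologyError("no latent slow-pathway pacemaker")

    # ---- CSV round trip -----------------------------------------------------

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for cid, p in self.cells.items():
            rows.append(
                dict(id=cid, segment=self.segment_of(cid), a1=p.a1, a2=p.a2, k=p.k,
                     c=p.c, eps0=p.eps0, mu1=p.mu1, mu2=p.mu2,
                     is_pacemaker=int(p.is_pacemaker),
                     gamma_controlled=int(p.gamma_controlled))
            )
        return pd.DataFrame(rows)

    def links_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(from_cell=l.from_cell, to_cell=l.to_cell, d=l.d, beta=l.beta)
             for l in self.links]
        )

    def to_csv(self, cells_path: str | Path, links_path: str | Path) -> None:
        self.cells_frame().to_csv(cells_path, index=False)
        self.links_frame().to_csv(links_path, index=False)

    @classmethod
    def from_frames(
        cls, cells: pd.DataFrame, links: pd.DataFrame, time_scale: float = 1.0
    ) -> "NodeTopology":
        cell_map: dict[str, CellParams] = {}
        for row in cells.itertuples(index=False):
            cell_map[row.id] = CellParams(
                a1=row.a1, a2=row.a2, k=row.k, c=row.c, eps0=row.eps0,
                mu1=row.mu1, mu2=row.mu2,
                is_pacemaker=bool(row.is_pacemaker),
                gamma_controlled=bool(row.gamma_controlled),
            )
        link_list = [
            LinkSpec(row.from_cell, row.to_cell, d=row.d, beta=row.beta)
            for row in links.itertuples(index=False)
        ]
        return cls(cells=cell_map, links=link_list, time_scale=time_scale)

    @classmethod
    def from_csv(
        cls, cells_path: str | Path, links_path: str | Path, time_scale: float = 1.0
    ) -> "NodeTopology":
        return cls.from_frames(
            pd.read_csv(cells_path), pd.read_csv(links_path), time_scale=time_scale
        )


@dataclass(frozen=True)
class VariantSpec:
    """Declarative description of the edits a variant applies to the base."""

    variant_id: int
    link_d_scale: tuple[tuple[str, str, float], ...] = ()
    link_beta_scale: tuple[tuple[str, str, float], ...] = ()
    cell_mu1_scale: tuple[tuple[str, float], ...] = ()


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("avnode.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def _load_calibration() -> dict:
    with resources.files("avnode.data").joinpath("calibration.json").open("r") as fh:
        return json.load(fh)


def variant_spec(variant_id: int) -> VariantSpec:
    """The declarative edit list of each model variant.

    Variant 1 is the base (no edits).  Variant 2 slightly reduces the
    diffusion coefficient on the last three fast-pathway links and
    increases it on the last four slow-pathway links, lengthening the
    retrograde FP refractory period throughout the gamma range.  Variant 3
    divides the coupling-asymmetry coefficient beta of the SP10->PB link
    by five, making the retrograde SP refractory period exceed the FP one
    at sympathetic tone with an inversion at vagal tone.  Variants 2 and 3
    additionally shorten refractoriness of the proximal His bundle
    (HB1-HB3) to ease His-bundle premature stimulation.
    """
    if variant_id == 1:
        return VariantSpec(1)
    hb_fast = (("HB1", 1.1), ("HB2", 1.1), ("HB3", 1.1))
    if variant_id == 2:
        return VariantSpec(
            2,
            link_d_scale=(
                ("FP6", "FP7", 0.8), ("FP7", "FP8", 0.8), ("FP8", "PB1", 0.8),
                ("SP7", "SP8", 1.6), ("SP8", "SP9", 1.6),
                ("SP9", "SP10", 1.6), ("SP10", "PB1", 1.6),
            ),
            cell_mu1_scale=hb_fast,
        )
    if variant_id == 3:
        return VariantSpec(
            3,
            link_beta_scale=(("SP10", "PB1", 1.0 / 5.0),),
            cell_mu1_scale=hb_fast,
        )
    raise InvalidParameterError(f"variant_id must be 1, 2 or 3 (got {variant_id})")


def build_variant(
    variant_id: int = 1,
    overrides: str | Path | None = None,
    counts: Mapping[str, int] | None = None,
) -> NodeTopology:
    """Build a validated topology for one of the three model variants.

    Parameters
    ----------
    variant_id : int
        1 (base), 2 or 3; see :func:`variant_spec`.
    overrides : path, optional
        CSV file with the cells schema of :meth:`NodeTopology.cells_frame`;
        rows replace the packaged per-cell parameters by cell id.
    counts : mapping, optional
        Per-segment cell counts; only the packaged default (32 cells) is
        shipped with fixture parameters, other counts reuse per-segment
        values.
    """
    spec = variant_spec(variant_id)
    calib = _load_calibration()
    cells_df = _load_packaged("cells_base.csv")
    links_df = _load_packaged("links_base.csv")
    topo = NodeTopology.from_frames(cells_df, links_df, time_scale=calib["time_scale_ms"])
    topo.variant_id = variant_id

    if counts is not None and dict(counts) != dict(DEFAULT_COUNTS):
        topo = _rebuild_with_counts(topo, counts)
        topo.variant_id = variant_id

    if overrides is not None:
        odf = pd.read_csv(overrides)
        unknown = set(odf["id"]) - set(topo.cells)
        if unknown:
            raise InvalidParameterError(f"override file names unknown cells: {sorted(unknown)}")
        for row in odf.itertuples(index=False):
            topo.cells[row.id] = CellParams(
                a1=row.a1, a2=row.a2, k=row.k, c=row.c, eps0=row.eps0,
                mu1=row.mu1, mu2=row.mu2,
                is_pacemaker=bool(row.is_pacemaker),
                gamma_controlled=bool(row.gamma_controlled),
            )

    for frm, to, s in spec.link_d_scale:
        topo.set_link(frm, to, d=topo.link(frm, to).d * s)
    for frm, to, s in spec.link_beta_scale:
        topo.set_link(frm, to, beta=topo.link(frm, to).beta * s)
    for cid, s in spec.cell_mu1_scale:
        topo.set_cell(cid, mu1=topo.cells[cid].mu1 * s)

    topo.validate()
    return topo


def _rebuild_with_counts(base: NodeTopology, counts: Mapping[str, int]) -> NodeTopology:
    """Re-lay the chain with different per-segment counts, reusing the
    per-segment parameter of the first cell of each segment in ``base``."""
    cells: dict[str, CellParams] = {}
    order: list[str] = []
    for seg in SEGMENTS:
        n = counts.get(seg, DEFAULT_COUNTS[seg])
        proto = base.cells[base.cells_in(seg)[0]]
        pace_proto = next((base.cells[c] for c in base.cells_in(seg)
                           if base.cells[c].is_pacemaker), None)
        # keep the latent pacemaker one cell proximal to the distal end of
        # the slow pathway, as in the default layout
        pace_at = max(n - 1, 1) if seg == "SP" else None
        for i in range(1, n + 1):
            cid = f"{seg}{i}"
            cells[cid] = pace_proto if (pace_at == i and pace_proto) else proto
            order.append(cid)
    topo = NodeTopology(cells={c: cells[c] for c in order}, links=[],
                        time_scale=base.time_scale)
    # rebuild links with per-segment d/beta taken from base
    def seg_link(seg_from, seg_to):
        a = base.cells_in(seg_from)[-1]
        b = base.cells_in(seg_to)[0]
        return base.link(a, b)

    def intra(seg):
        ids = topo.cells_in(seg)
        ref = None
        base_ids = base.cells_in(seg)
        if len(base_ids) > 1:
            ref = base.link(base_ids[0], base_ids[1])
        for a, b in zip(ids[:-1], ids[1:]):
            topo.links.append(LinkSpec(a, b, d=ref.d if ref else 0.0,
                                       beta=ref.beta if ref else 1.0))

    for seg in SEGMENTS:
        intra(seg)
    chain = [("SN", "PS"), ("PS", "AM")]
    for a, b in chain:
        ref = seg_link(a, b)
        topo.links.append(LinkSpec(topo.cells_in(a)[-1], topo.cells_in(b)[0],
                                   d=ref.d, beta=ref.beta))
    am_tail = topo.cells_in("AM")[-1]
    for seg in ("FP", "SP"):
        ref = base.link(base.cells_in("AM")[-1], base.cells_in(seg)[0])
        topo.links.append(LinkSpec(am_tail, topo.cells_in(seg)[0], d=ref.d, beta=ref.beta))
        ref2 = base.link(base.cells_in(seg)[-1], base.cells_in("PB")[0])
        topo.links.append(LinkSpec(topo.cells_in(seg)[-1], topo.cells_in("PB")[0],
                                   d=ref2.d, beta=ref2.beta))
    ref = seg_link("PB", "HB")
    topo.links.append(LinkSpec(topo.cells_in("PB")[-1], topo.cells_in("HB")[0],
                               d=ref.d, beta=ref.beta))
    return topo


def ablate(topology: NodeTopology, pathway: str) -> NodeTopology:
    """Remove one pathway (``"SP"`` or ``"FP"``), leaving a single route.

    Mirrors the post-ablation preparations used to measure the conduction
    curve of each pathway in isolation.
    """
    if pathway not in ("SP", "FP"):
        raise InvalidParameterError(f"pathway must be 'SP' or 'FP', got {pathway!r}")
    if topology.ablated is not None:
        raise TopologyError("topology already has an ablated pathway")
    out = topology.copy()
    doomed = set(out.cells_in(pathway))
    if not doomed:
        raise TopologyError(f"pathway {pathway} not present")
    out.cells = {c: p for c, p in out.cells.items() if c not in doomed}
    out.links = [l for l in out.links if l.from_cell not in doomed and l.to_cell not in doomed]
    out.ablated = pathway
    out.validate()
    return out
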