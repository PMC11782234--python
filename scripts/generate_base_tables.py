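#!/usr/bin/env python
"""Regenerate the packaged base parameter tables.

Writes ``cells_base.csv`` and ``links_base.csv`` (the per-segment
Aliev--Panfilov parameters and the branched coupling layout described in
docs/methods.md) into ``src/avnode/data/``, then resets the calibration
marker.  Run ``avnode calibrate --write`` afterwards to re-fit the sinus
pacemaker and the time base to the rate anchors.
"""

import json
from pathlib import Path

import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "avnode" / "data"

#: segment -> (n, a1, a2, k, c, eps0, mu1, mu2, is_pacemaker, gamma_controlled)
SEGMENTS = {
    "SN": (2, -0.09, 0.2, 8.0, 1.0, 0.0075, 0.01, 0.2, 1, 1),
    "PS": (2, 0.06, 0.1, 8.0, 0.5, 0.007, 0.3, 0.3, 0, 1),
    "AM": (3, 0.08, 0.1, 8.0, 0.55, 0.007, 0.3, 0.3, 0, 1),
    "FP": (8, 0.10, 0.1, 8.0, 0.5, 0.006, 0.075, 0.3, 0, 1),
    "SP": (10, 0.07, 0.1, 8.0, 0.6, 0.008, 0.15, 0.3, 0, 1),
    "PB": (1, 0.13, 0.1, 8.0, 0.5, 0.006, 0.2, 0.3, 0, 1),
    "HB": (6, 0.13, 0.1, 8.0, 0.55, 0.006, 0.35, 0.3, 0, 0),
}


def cells_table() -> pd.DataFrame:
    rows = []
    for seg, (n, a1, a2, k, c, e0, m1, m2, pace, g) in SEGMENTS.items():
        for i in range(1, n + 1):
            rows.append(dict(id=f"{seg}{i}", segment=seg, a1=a1, a2=a2, k=k,
                             c=c, eps0=e0, mu1=m1, mu2=m2,
                             is_pacemaker=pace, gamma_controlled=g))
    df = pd.DataFrame(rows)
    # latent AV-junctional pacemaker in the distal slow pathway (one cell
    # proximal to the nodal insertion): barely sub-threshold oscillator
    # with the conduction properties of an SP cell
    df.loc[df.id == "SP9", ["a1", "is_pacemaker"]] = [-0.004, 1]
    return df


def links_table() -> pd.DataFrame:
    links = []

    def add(a, b, d, beta=1.0):
        links.append(dict(from_cell=a, to_cell=b, d=d, beta=beta))

    add("SN1", "SN2", 0.4)
    add("SN2", "PS1", 0.25)
    add("PS1", "PS2", 0.5)
    add("PS2", "AM1", 0.5)
    add("AM1", "AM2", 0.5)
    add("AM2", "AM3", 0.5)
    fp = ["AM3"] + [f"FP{i}" for i in range(1, 9)] + ["PB1"]
    for a, b in zip(fp[:-1], fp[1:]):
        add(a, b, 0.25, 0.75)
    sp = ["AM3"] + [f"SP{i}" for i in range(1, 11)] + ["PB1"]
    for a, b in zip(sp[:-1], sp[1:]):
        add(a, b, 0.10, 0.9)
    # weak atrionodal entry into the slow pathway: slows SP engagement and
    # keeps the refractory slow pathway from loading the atrial branch point
    links[-11]["d"] = 0.08
    # strong distal junction into the penetrating bundle so the decremental
    # slow-pathway wavefront can still source the compact node
    links[-1]["d"] = 0.25
    hb = ["PB1"] + [f"HB{i}" for i in range(1, 7)]
    for a, b in zip(hb[:-1], hb[1:]):
        add(a, b, 0.5)
    return pd.DataFrame(links)


def main() -> None:
    cells_table().to_csv(DATA / "cells_base.csv", index=False)
    links_table().to_csv(DATA / "links_base.csv", index=False)
    with open(DATA / "calibration.json", "w") as fh:
        json.dump({"time_scale_ms": 1.22, "calibrated": False}, fh, indent=1)
        fh.write("\n")
    print(f"base tables written to {DATA}; run `avnode calibrate --write` next")


if __name__ == "__main__":
    main()
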