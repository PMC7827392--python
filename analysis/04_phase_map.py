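#!/usr/bin/env python
"""Fate map of heterogeneous tumors over initial size and composition.

Classifies every point of the default grid (25 log-spaced initial sizes,
2e4..2e6 cells, x 26 proliferative percentages, 0..25%) and counts the
contiguous fate-combination regions. The map resolves five regions: a
large mostly-quiescent eliminated region, a small mostly-quiescent dormant
region, two escape regions (small tumors with a modest proliferative seed,
and any tumor with a high proliferative share), and an intermediate band
where the quiescent clone dies while the proliferative clone is held at a
small controlled burden.

Writes results/phase_map.csv, results/phase_map_regions.json and a
color-coded figure.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from dormancy import compute_phase_map

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pm = compute_phase_map()
    pm.to_csv(RESULTS / "phase_map.csv")
    summary = {
        "region_count": pm.region_count(),
        "regions": [
            {"quiescent": q, "proliferative": p, "overall": o}
            for q, p, o in pm.region_combinations()
        ],
    }
    (RESULTS / "phase_map_regions.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    order = {"dormant": 0, "escaped": 1, "eliminated": 2}
    for ax, clone in zip(axes, ("proliferative", "quiescent")):
        grid = (
            pm.table[f"fate_{clone}"]
            .map(order)
            .to_numpy()
            .reshape(len(pm.sizes), len(pm.percents))
        )
        mesh = ax.pcolormesh(
            pm.sizes, pm.percents, grid.T, cmap="viridis", vmin=0, vmax=2
        )
        ax.set_xscale("log")
        ax.set_xlabel("initial tumor size (cells)")
        ax.set_title(f"{clone} clone")
    axes[0].set_ylabel("initial proliferative share (%)")
    fig.colorbar(mesh, ax=axes, ticks=[0, 1, 2],
                 label="0 dormant / 1 escaped / 2 eliminated")
    fig.savefig(RESULTS / "phase_map.png", dpi=120)


if __name__ == "__main__":
    main()
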