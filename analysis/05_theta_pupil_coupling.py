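#!/usr/bin/env python
"""Cross-modal coupling: theta-bin × pupil-bin correlation clusters.

Correlates every ROI theta time bin (0–1 s) with every phasic pupil time bin
(0–2 s) across subjects, masks at p ≤ 0.05, extracts 4-connected negative
clusters whose centroid falls in the theta 0–1 s × pupil 1–2 s window, and
normalises cluster sizes to the largest across the compared sessions.
Writes the correlation matrices, the cluster table and a figure to
results/coupling/.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from thetapupil.pipeline import coupling_cluster_sizes, run_cohort

HERE = Path(__file__).resolve().parent
OUT = HERE.parent / "results" / "coupling"


def _load_step01():
    spec = importlib.util.spec_from_file_location("step01", HERE / "01_simulate_cohort.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = _load_step01().build_cohort(seed)
    res = run_cohort(cohort.cfg, leadfield=cohort.leadfield)
    cc = coupling_cluster_sizes(res, decim=8)

    rows = []
    for c in cc["clusters"]:
        rows.append(
            dict(
                session=c.label[1],
                size_raw=c.size_raw,
                size_norm=c.size_norm,
                mean_r=c.mean_r,
                peak_r=c.peak_r,
                centroid_theta_s=c.centroid_theta_s,
                centroid_pupil_s=c.centroid_pupil_s,
                area_s2=c.area_s2,
            )
        )
    pd.DataFrame(rows).to_csv(OUT / "clusters.tsv", sep="\t", index=False, float_format="%.4f")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, s in zip(axes, res.sessions):
        cm = cc["matrices"][s]
        np.savetxt(OUT / f"r_matrix_s{s}.tsv", cm.r, delimiter="\t", fmt="%.4f")
        shown = np.where(cm.p <= 0.05, cm.r, np.nan)
        im = ax.imshow(
            shown,
            aspect="auto",
            origin="lower",
            extent=[cm.pupil_times[0], cm.pupil_times[-1], cm.theta_times[0], cm.theta_times[-1]],
            cmap="RdBu_r",
            vmin=-1,
            vmax=1,
        )
        ax.set_title(f"session {s}")
        ax.set_xlabel("pupil time (s)")
    axes[0].set_ylabel("theta time (s)")
    fig.colorbar(im, ax=axes, label="Pearson r (p ≤ .05)")
    fig.savefig(OUT / "coupling_matrices.png", dpi=120)

    print("normalised in-window negative cluster sizes:",
          {f"S{s}": round(v, 3) for s, v in cc["size_norm"].items()})
    for r in rows:
        print(f"  session {r['session']}: size_norm={r['size_norm']:.3f} "
              f"mean_r={r['mean_r']:.2f} centroid=({r['centroid_theta_s']:.2f} s, "
              f"{r['centroid_pupil_s']:.2f} s)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
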