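#!/usr/bin/env python
"""Pupillometry: phasic peak metrics per condition and tonic baselines.

Conditions each subject's pupil trace (blink interpolation + 20 Hz low-pass),
epochs it like the EEG, extracts phasic peak amplitude/latency per
condition × session, runs the angle × session RM-ANOVA on Go-trial peaks
(Greenhouse–Geisser corrected), and summarises the tonic resting diameter
over the fixation periods.  Writes tables to results/pupil/.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from thetapupil.pupillometry import (
    epoch_pupil,
    metrics_table,
    preprocess_pupil,
    tonic_baseline,
)
from thetapupil.stats_report import format_effect, rm_anova_2x4

HERE = Path(__file__).resolve().parent
OUT = HERE.parent / "results" / "pupil"


def _load_step01():
    spec = importlib.util.spec_from_file_location("step01", HERE / "01_simulate_cohort.py")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = _load_step01().build_cohort(seed)
    cfg = cohort.cfg

    tables = []
    tonic_rows = []
    n_sess = cfg.n_sessions
    peaks = np.full((cfg.n_subjects, 2, n_sess), np.nan)
    for i in range(cfg.n_subjects):
        trace = preprocess_pupil(cohort.subject_pupil(i))
        pep = epoch_pupil(trace, cohort.events)
        tab = metrics_table(pep)
        tab.insert(0, "subject", i)
        tables.append(tab)
        go = tab[tab.trial_type == "go"]
        for ai, ang in enumerate((30, 150)):
            for s in range(1, n_sess + 1):
                row = go[(go.angle == ang) & (go.session == s)]
                if len(row):
                    peaks[i, ai, s - 1] = row["peak_amp_mm"].iloc[0]
        tb = tonic_baseline(trace, cohort.fixations)
        tb.insert(0, "subject", i)
        tonic_rows.append(tb)

    metrics = pd.concat(tables, ignore_index=True)
    metrics.to_csv(OUT / "phasic_metrics.tsv", sep="\t", index=False, float_format="%.5f")
    tonic = pd.concat(tonic_rows, ignore_index=True)
    tonic.to_csv(OUT / "tonic_baseline.tsv", sep="\t", index=False, float_format="%.4f")

    go_means = metrics[metrics.trial_type == "go"].groupby("session")["peak_amp_mm"].mean()
    print("Go phasic peak by session (mm):",
          ", ".join(f"S{s}={v:.4f}" for s, v in go_means.items()))
    if np.isfinite(peaks).all():
        res = rm_anova_2x4(peaks)
        report = "\n".join(format_effect(e) for e in res.effects.values())
        (OUT / "rm_anova_go_peaks.txt").write_text(report + "\n")
        print("RM-ANOVA on Go peaks (angle x session):")
        print("  " + report.replace("\n", "\n  "))
    start = tonic[tonic.kind == "start"]["mean_diameter_mm"].mean()
    end = tonic[tonic.kind == "end"]["mean_diameter_mm"].mean()
    print(f"tonic resting diameter: start {start:.3f} mm -> end {end:.3f} mm")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
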