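#!/usr/bin/env python
"""Simulate a demonstration cohort and write it in standard formats.

Generates a scaled-down cohort (27 subjects, 16 channels, 2 analysed
sessions of 40 trials each; the full study design is 60 channels × 4
sessions × 1200 trials, far too large for a demonstration run).  The two
sessions play the roles of the first (S1) and last (S4) session of the
experiment.  Subject 0 is exported as BrainVision EEG plus TSV event/pupil
tables and the ground-truth JSON under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from thetapupil.forward import HeadModel, compute_leadfield
from thetapupil.io import (
    write_brainvision,
    write_events_tsv,
    write_ground_truth_json,
    write_pupil_tsv,
)
from thetapupil.montage import equidistant_montage
from thetapupil.synthetic_data import Cohort, SimConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def demo_config(seed: int = 1) -> SimConfig:
    return SimConfig(
        n_subjects=27,
        n_sessions=2,
        trials_per_session=40,
        n_channels=16,
        theta_amp_by_session=(60.0, 48.0),
        coupling_by_session=(-0.65, 0.0),
        pupil_amp_by_session=(0.070, 0.052),
        long_fixation_s=30.0,
        n_short_fixations=5,
        short_fixation_s=5.0,
        seed=seed,
    )


def build_cohort(seed: int = 1) -> Cohort:
    cfg = demo_config(seed)
    names, pos = equidistant_montage(cfg.n_channels)
    lf = compute_leadfield(HeadModel(), pos, spacing=0.012, ch_names=names)
    return Cohort(cfg, leadfield=lf)


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(seed)
    cfg = cohort.cfg

    write_events_tsv(cohort.events, OUT / "events.tsv")
    write_ground_truth_json(cohort.truth, OUT / "ground_truth.json")
    cfg.to_json(OUT / "sim_config.json")

    rec = cohort.subject_eeg(0)
    write_brainvision(rec, OUT / "sub-00_eeg", events=cohort.events)
    trace = cohort.subject_pupil(0)
    write_pupil_tsv(trace.times, trace.diameter, OUT / "sub-00_pupil.tsv")

    ev = cohort.events
    print(f"cohort: {cfg.n_subjects} subjects x {cfg.n_sessions} sessions "
          f"x {cfg.trials_per_session} trials, {cfg.n_channels} channels @ {cfg.sfreq:g} Hz")
    print(f"  Go:Nogo per session = {cfg.n_go}:{cfg.n_nogo}; "
          f"timeline {cohort.fixations['t_end'].iloc[-1]:.0f} s")
    print(f"  subject 0 EEG rms {rec.data.std():.2f} uV; "
          f"pupil range {trace.diameter.min():.2f}-{trace.diameter.max():.2f} mm")
    tp = cohort.truth.per_subject_theta_power
    pa = cohort.truth.per_subject_pupil_amp
    r1 = np.corrcoef(np.log(tp[:, 0]), pa[:, 0])[0, 1]
    print(f"  programmed S1 theta-pupil coupling realised as r = {r1:.2f} "
          f"(target {cfg.coupling_by_session[0]:.2f}, n = {cfg.n_subjects})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
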