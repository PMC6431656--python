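#!/usr/bin/env python
"""Simulate the calibration study cohort and a small serialised dataset.

Draws the default 30-child cohort (even sex split, ages 8-11) and prints its
summary statistics, then serialises a 2-participant demonstration dataset
(raw 80 Hz triaxial CSV, breath-by-breath VO2, bout annotations) under
results/data/ so the file-based pipeline can be inspected.  The full-size
30-child analysis runs in memory in 02_build_labeled_epochs.py — the raw
signal for a full study is tens of millions of samples and is never
materialised on disk for the main analysis.
"""

import numpy as np

from accelcal.cohort import generate_cohort
from accelcal.config import RunConfig
from accelcal.io import generate_study
from accelcal.protocol import default_protocol

cfg = RunConfig()
profiles = generate_cohort(cfg.n_participants, cfg.master_seed, cfg)

ages = np.array([p.age for p in profiles])
mass = np.array([p.mass for p in profiles])
height = np.array([p.height for p in profiles])
sexes = [p.sex for p in profiles]
print(f"cohort: {len(profiles)} children ({sexes.count('F')} girls, {sexes.count('M')} boys)")
print(f"  age    {ages.mean():.1f} +/- {ages.std(ddof=1):.1f} y")
print(f"  mass   {mass.mean():.1f} +/- {mass.std(ddof=1):.1f} kg")
print(f"  height {height.mean():.2f} +/- {height.std(ddof=1):.2f} m")

demo_cfg = cfg.replace(n_participants=2)
manifest = generate_study(
    default_protocol(demo_cfg), 2, cfg.master_seed, "results/data", demo_cfg
)
print(
    f"demonstration dataset: {manifest['n_recordings']} recordings, "
    f"{manifest['n_annotations']} bout annotations -> results/data/"
)
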