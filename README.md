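# tbslice

Quantification pipeline for repetitive magnetic stimulation experiments in
organotypic entorhino-hippocampal slice cultures.  After a single session of
intermittent theta-burst stimulation (iTBS600: 600 pulses as 3-pulse 50 Hz
bursts at 5 Hz, 20 duty cycles of 2 s on / 8 s off), such experiments
quantify plasticity through four data modalities, each with its own analysis
chain:

* **c-Fos immunostaining** — count activity-marked cells per region
  (DG, CA3, CA1) from confocal z-stacks and normalize by batch control
  means;
* **miniature EPSC recordings** — detect quantal synaptic events in
  voltage-clamp current traces and compare amplitude/area distributions,
  frequencies, and the 2-minute-scaled summated area;
* **time-lapse spine imaging** — track spine sizes over 11 scans spanning
  five baseline days, five post-stimulation hours and a 24-h follow-up;
  normalize to the day-4 baseline, bin size changes by initial size,
  classify enlarged/shrunk transitions, and summarize heterosynaptic
  coordination with spine-pair correlation matrices reduced to a fixed-size
  **15 × 15 unit matrix** (the elementwise mean of all 15 × 15 principal
  submatrices sliding along the diagonal of a segment's correlation
  matrix);
* **calcium imaging** — extract per-neuron GCaMP6f traces through label
  masks, detrend with a rolling median, form ΔF/F0, detect calcium spikes
  at mean + 3 SD, and compute trace AUC, pairwise synchrony and Welch power
  spectra.

Group decisions use Mann-Whitney U tests (exact by enumeration for small
samples), chi-square tests on 2 × 2 transition tables, and linear mixed
models with random intercepts per neuron or culture, read out by whether
the effect's confidence interval (95-99.99%) crosses zero.

No raw recordings are publicly deposited for this kind of experiment, so
the package ships ground-truthed synthetic generators for all four
modalities (`tbslice.synthetic_data`); every analysis stage is verified by
parameter recovery against generator truth.  See `docs/methods.md` for the
models, defaults, and design decisions.

## Worked example

Generate the default stimulation train and verify its structure:

```python
>>> from tbslice.protocol import generate_pulse_train, segment_train
>>> train = generate_pulse_train()
>>> len(train), float(train.timestamps[-1])
(600, 191.84)
>>> cycles = segment_train(train, burst_gap=0.1, cycle_gap=1.0)
>>> len(cycles), len(cycles[0]), len(cycles[0][0])
(20, 10, 3)
```

600 pulses end 191.84 s after the first one, and gap-based segmentation
recovers the 20 cycles × 10 bursts × 3 pulses structure exactly.

Simulate spine trajectories and compute the unit-matrix contrast:

```python
>>> from tbslice.synthetic_data import SpineSimParams, simulate_spine_trajectory_set
>>> from tbslice.spine_dynamics import (unit_matrices_for_set,
...                                     mean_unit_matrix, near_far_summary)
>>> p = SpineSimParams(n_segments=100, seed=77)
>>> ctrl, _ = simulate_spine_trajectory_set(p, "control")
>>> stim, _ = simulate_spine_trajectory_set(p, "stimulated")
>>> near, far = near_far_summary(mean_unit_matrix(unit_matrices_for_set(ctrl)))
>>> round(near, 3), round(far, 3)
(0.385, -0.148)
>>> _, far_s = near_far_summary(mean_unit_matrix(unit_matrices_for_set(stim)))
>>> round(far_s - far, 3)
0.033
```

Under baseline dynamics, neighboring spines change size together (mean
near-diagonal correlation +0.39) while distant spines change in opposition
(far corners −0.15).  Adding the post-stimulation enlargement of small
spines to the same trajectories pulls the far corners up by ~0.03 — the
qualitative signature of stimulation overriding the spatial correlation
structure.

## Analysis drivers

`analysis/` holds numbered narrative scripts that run each stage end to end
on synthetic data and write tables under `results/`:

```
01_protocol_timing.py    pulse train generation and segmentation
02_simulate_datasets.py  one ground-truthed dataset per modality
03_cfos_counts.py        counting, batch normalization, Mann-Whitney tests
04_mepsc_events.py       detection, distributions, summated areas, LMM
05_spine_dynamics.py     delta bins, transitions, unit matrices, variance
06_calcium_metrics.py    movie extraction, spikes/AUC/PSD, synchrony, LMM
```

## Command line

A thin CLI mirrors the pipeline stages:

```bash
tbslice protocol emit --out pulses.csv
tbslice simulate calcium --seed 1 --out sim/ --movie
tbslice cfos count --cfos stack.tif --rois masks.tif --out counts.csv
tbslice mepsc analyze --traces traces/ --out out/
tbslice spines analyze --sizes sizes.csv --out out/
tbslice calcium analyze --movie mov.tif --mask mask.tif --rate 10 --out out/
tbslice report --metrics metrics.csv --out report.json
```

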