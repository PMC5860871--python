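# boldadapt

Analysis of the **decay of fMRI adaptation** in block-design auditory
experiments, built around a fully testable synthetic pipeline.

Repeated stimuli suppress the neural — and hence BOLD — response
("adaptation"); the suppression wanes as the interval between trials
grows. In a design where each block keeps a constant trial onset
asynchrony (TOA ∈ {3, 6, 9, 15} s, 16 trials per block, 3 runs of 4
blocks, TR = 1 s), the per-block GLM amplitude β follows an
exponential recovery law

```
β(TOA) = a + b · exp(−TOA / τ)
```

where *a* is the asymptotic BOLD level, *b* the magnitude of
adaptation, and **τ the time constant of its decay**. Comparing τ
between groups (e.g. 19 control readers vs 20 readers with dyslexia)
tests whether one group's implicit memory of recent stimuli decays
faster. This package implements the full chain:

1. **Synthetic cohorts** (`boldadapt.synth`) — seeded two-group BOLD
   simulations whose voxel amplitudes follow the decay law, with
   Gaussian noise, low-frequency drift, and optional spatial
   smoothness; ground truth is returned for recovery tests.
2. **Preprocessing** (`boldadapt.preprocess`) — regression-based
   removal of low frequencies up to 3 cycles/scan (mean, linear trend,
   slow sinusoids), voxelwise z-scoring, 3-D Gaussian smoothing
   (FWHM 4 mm default).
3. **Block GLM** (`boldadapt.glm`, `boldadapt.hrf`) — two-gamma HRF
   convolved with each TOA block's event train; OLS gives one β per
   TOA per voxel; task-responsive voxels selected by a pooled omnibus
   F test with Benjamini–Hochberg FDR (q = 0.001).
4. **Decay fitting** (`boldadapt.decay`) — least-squares fit of
   (a, b, τ) by variable projection: a log-spaced τ grid plus
   golden-section refinement; vectorized over voxels.
5. **Group inference** (`boldadapt.stats`, `boldadapt.clusters`) —
   voxelwise Mann-Whitney U tests on per-subject τ (z, two-sided p,
   effect size r = z/√N), with Monte-Carlo cluster-extent correction:
   the extent threshold k is the smallest cluster size reached by at
   most 5% of simulated null fields.
6. **ROI analysis** (`boldadapt.roi`) — β averaging over a mask
   (e.g. a 99-voxel auditory-cortex-sized region), per-subject decay
   fits, Mann-Whitney group comparison.
7. **Pipeline** (`boldadapt.pipeline`, CLI `boldadapt`) — one seeded
   config running every stage with provenance; re-running a config
   reproduces all maps and tables byte-identically.

## Worked example

```bash
python examples/03_roi_group_comparison.py
```

simulates 19 controls (τ = 10 s) and 20 dyslexic readers (τ = 5 s) on
a 99-voxel ROI grid, runs preprocessing + GLM, fits the decay model to
each subject's ROI-averaged βs, and prints:

```
ROI 'roi99' (99 voxels), n = 19 controls vs 20 dyslexic
median tau: control 11.04 s, dyslexic 4.73 s (truth 10 / 5)
Mann-Whitney U=380, z=5.32, p=1.01e-07, effect size r=0.85
```

The group medians recover the generating time constants; z > 0 means
controls hold adaptation longer, and r = z/√39 is the rank-test effect
size. With the empirical effect reported for such cohorts (z = 2.6,
N = 39) the same identity gives r = 0.42.

Other examples: `01_simulate_cohort.py` (forward model),
`02_fit_decay.py` (exact recovery and τ maps), `04_cluster_correction.py`
(Monte-Carlo extent threshold), `05_full_pipeline.py` (end-to-end run
with written artifacts). The `boldadapt` console script exposes the
same stages as subcommands (`simulate`, `preprocess`, `glm`,
`fit-decay`, `group-test`, `cluster-correct`, `roi`, `run-all`).

## Module layout

```
src/boldadapt/
  types.py       EventSchedule, BOLDRun, ROIMask (+ NIfTI I/O)
  hrf.py         two-gamma hemodynamic response function
  synth.py       NoiseSpec, GroundTruth, CohortDesign, Cohort, simulate_run
  preprocess.py  high-pass detrend, z-score, Gaussian smoothing
  glm.py         design matrices, OLS βs, BH-FDR, task selection
  decay.py       fit_decay / fit_decay_map (variable projection)
  stats.py       Mann-Whitney U/z/p, effect size r, voxelwise maps
  clusters.py    labeling, Monte-Carlo extent threshold, corrected tables
  roi.py         ROI averaging, per-subject fits, group comparison
  pipeline.py    PipelineConfig, run_pipeline, provenance
  cli.py         thin click front end
```

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and what the synthetic validation does and does not show.
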