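# glassdev

A tested, reusable pipeline for developmental block-design fMRI analyses
built around Glass-pattern stimuli: stimulus and schedule generation, a
synthetic longitudinal BOLD generator with known ground truth, minimal
preprocessing, GLM mapping with multiple-comparison control, a spectral
signal-to-noise metric, rank-ordered multivoxel pattern classification
with a binomial chance model, and constrained saturation fits of the
sensitivity index d' against age with a d' = 2 criterion age.

## Modules

| module | what it does |
| --- | --- |
| `glassdev.stimgen` | Glass-pattern dipole fields (concentric / radial / random), static (1 s) and dynamic (33 ms) frame sequences, palindromic block/blank schedules, 48 s pinwheel on/off schedules; BIDS-style events TSV I/O |
| `glassdev.synthbold` | double-gamma HRF, longitudinal synthetic sessions (TR = 6 s, V1/V4/MT-V5 masks) whose decodability follows per-area saturating developmental curves |
| `glassdev.preprocess` | per-voxel linear detrending with percent-intensity-adjustment QC |
| `glassdev.glmmap` | two-predictor GLM (convolved stimulus + baseline), t-tests, Benjamini-Hochberg FDR and within-VOI Bonferroni thresholds, percent-significant summaries, onset-age regression (>= 4 consecutive significant sessions, abscissa intercept) |
| `glassdev.snrspec` | DFT amplitude at the 0.625 cycles/min alternation frequency over the mean of the two flanks at 0.5x and 1.5x |
| `glassdev.mvpa` | voxel ranking by pinwheel responsiveness (positives only, truncated at 70), pattern assembly with a one-volume delay, 8-fold cross-validated linear SVM over held-out condition pairs, binomial 95% chance bounds |
| `glassdev.devtraj` | sensitivity index d', fold-accuracy bootstrap, constrained Naka-Rushton fit of d' vs age, criterion-age inversion, paired bootstrap comparisons of crossing ages |
| `glassdev.pipeline` / `glassdev.cli` | end-to-end orchestration with deterministic seeding, CSV/JSON outputs and a reproducibility manifest |

## Command line

```sh
# write a synthetic longitudinal study (NIfTI runs + masks + events TSV)
glassdev simulate --ages 3.4,9,18,30,47 --n-voxels 100 --seed 1 --out scratch/study

# stage by stage
glassdev preprocess scratch/study      # detrended runs + qc.csv
glassdev snr scratch/study             # snr.csv
glassdev glm scratch/study             # glm_percent.csv + onset_regression.csv
glassdev mvpa scratch/study            # mvpa_sessions.csv
glassdev trajectory scratch/study      # trajectory.json + comparisons.csv

# or everything in memory from a YAML config
glassdev run-all --config config.yaml --seed 1 --out scratch/out
```

`run-all` accepts any `StudyConfig` field in the YAML (ages, VOI sizes,
noise level, ground-truth half-saturation ages, contrasts, thresholds,
bootstrap size, seed). Identical config and seed reproduce identical
outputs.

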