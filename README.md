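# naturalscan

Annotation-informed analysis of brain responses to naturalistic audiovisual
stimulation (free viewing of a film during fMRI).  The package implements,
as a tested and reusable pipeline, the two complementary routes such studies
take:

- **model-free**: temporal-concatenation group spatial ICA with repeated
  randomized/bootstrapped runs and ICASSO-style stability clustering,
  followed by inter-subject-correlation (ISC) screening of component time
  courses; and
- **model-driven**: GLM fitting of stimulus-annotation regressors
  (HRF-convolved audio descriptors, manual sound-category boxcars, DCT
  edge-density, ordinal motion scores) to component and voxel time courses,
  with significance thresholds from circular-shift permutation testing.

It is aimed at researchers analysing naturalistic fMRI who want each stage —
feature annotation, design construction, group ICA, permutation inference,
network comparison — as an inspectable, seedable library function rather
than a GUI toolbox, plus a synthetic-data generator that plants known
networks so the whole chain can be validated end to end.

## The model

Each subject's masked BOLD data `Y_s` (time × voxels) is high-pass filtered
by Gaussian-weighted running-line fitting (σ = 100 s).  Group spatial ICA
factors the temporally concatenated data

    [Y_1; …; Y_S] ≈ A · C,

where rows of `C` are spatial component maps and `A` holds their time
courses; stability of each component is the mean pairwise |spatial ρ| of
its cluster across `n` repeated bootstrapped runs, and subject time courses
are recovered by projecting each `Y_s` onto the pseudo-inverse of the maps
(a spatial-map-weighted average of voxel time courses).

Stimulus models are collections of annotation tracks `x_f(t)` sampled at
1 Hz, convolved with a canonical double-gamma HRF (6-s peak) and resampled
to the TR grid.  For a component or voxel time course `y`,

    y = β₀ + Σ_f β_f x_f + ε,

and the model fit is summarised by r = corr(Σ_f β̂_f x_f, y), with weights
reported as β̂_f / max|β̂| so the main explanatory feature receives 1.
Significance thresholds for r come from refitting the GLM at every circular
shift of the time courses (autocorrelation preserved, stimulus alignment
destroyed), pooling the r values into a 100-bin lookup table with linear
interpolation.  ISC of a component is the Fisher-z mean of all pairwise
subject correlations, with a circular-shift permutation p-value.  Networks
from the two routes are compared by thresholding maps, labeling clusters
under 18-connectivity (discarding clusters ≤ 125 voxels at full scale), and
classifying voxel-wise/IC overlap; functional connectivity between cluster
mean time courses is tested against a max-correlation circular-shift null.

## Worked example

Run the full pipeline on a generated desk-scale study (3 subjects, 120
volumes at TR 2 s, 500 voxels, 4 planted networks driven by the annotation
model):

```python
from naturalscan import IcaConfig, PipelineConfig, SynthConfig, run_pipeline

cfg = PipelineConfig(
    synth=SynthConfig(n_subjects=3, n_timepoints=120, n_voxels=500,
                      mask_shape=(10, 10, 5), seed=7),
    ica=IcaConfig(n_components=4, n_runs=6, random_seed=0),
    alpha=0.01, isc_permutations=200, connectivity_permutations=5000,
    min_cluster_size=5, out_dir="example-run", seed=7)
summary = run_pipeline(cfg)
```

The summary (also written to `example-run/summary.json` along with maps,
time courses, screening tables and an overlap volume) contains, for this
seed:

```
stability_index       [0.999, 0.999, 0.999, 0.998]
isc_mean_r            [0.845, 0.870, 0.893, 0.883]
auditory_r2           [0.868, 0.153, 0.211, 0.868]
visual_r2             [0.170, 0.862, 0.799, 0.053]
auditory_threshold    0.585
visual_threshold      0.546
selected_components   [0, 1, 2, 3]
map_recovery          [0.931, 0.925, 0.956, 0.948]
```

Reading: all four extracted components are stable across bootstrapped runs
(stability ≈ 1) and strongly synchronized across subjects (ISC ≈ 0.85–0.89,
the shared planted signal).  Components 0 and 3 follow the auditory
stimulus model (R² ≈ 0.87), components 1 and 2 the visual model; every
component exceeds at least one model's circular-shift threshold and all
four planted networks are selected.  `map_recovery` is the |spatial ρ|
between each planted map and its best-matching recovered component.

A command-line interface mirrors the stages:

```bash
naturalscan synth --seed 1 --out study/           # generate a study
naturalscan features audio soundtrack.wav         # audio annotation tracks
naturalscan design study/annotations.tsv --model auditory --timepoints 300
naturalscan ica study/sub-*.nii.gz --mask study/mask.nii.gz
naturalscan run --synthetic --seed 1 --out run/   # everything end to end
```

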