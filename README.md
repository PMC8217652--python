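# fearleak

Analysis pipeline for *leaked fear* in facial action-unit (AU) time series:
given per-frame facial features in the OpenFace 2.x CSV dialect (68 landmarks,
AU intensities `AUxx_r`, AU presences `AUxx_c`), it

1. scores the seven fear AUs (AU01, AU02, AU04, AU05, AU07, AU20, AU26) per
   frame as *presence x intensity* and averages them per clip
   (`fear_features`);
2. segments contiguous AU activations into onset/apex/offset episodes,
   decomposes durations additively (rise = [onset..apex], decay =
   (apex..offset]), converts frames to milliseconds, and counts
   micro/macro expressions at the 200 ms / 500 ms thresholds
   (`episode_dynamics`);
3. measures left/right facial symmetry as the magnitude-squared wavelet
   coherence (analytic Morlet, omega0 = 6, Torrence–Webster smoothing) of the
   eyebrow–eye distance signals from landmark pairs 20/40 and 25/43
   (`facial_symmetry`);
4. runs the statistics: paired bootstrap t-tests with Bonferroni correction,
   independent-sample bootstrap comparison of episode durations, effect sizes
   (paired d = |t|/sqrt(n), independent d = pooled-SD standardized
   difference), and a two-sample permutation test for coherence
   (`inference_stats`);
5. classifies frames as truth vs lie with SMOTE oversampling and three
   classifiers (random forest, 1-NN, bagged trees), evaluated with a 12-of-16
   participant train/test split, frame-level 10-fold CV, and
   leave-one-person-out CV, reporting WEKA-style weighted metrics and kappa
   (`deception_ml`).

Because the original game-show videos are not distributable, the package
includes a first-class synthetic cohort generator (`synthetic_cohort`) that
emits OpenFace-dialect CSVs with the structure the analysis assumes:
truth/lie clip pairs with strongly unequal lengths, gamma-distributed episode
phases with a shorter decay in the lie group (means 11.35 vs 6.98 frames by
default), and left/right distance signals with controllable lag and
independent-noise mixing.

## CLI

```bash
# full pipeline on a synthetic cohort (default) or a manifest of CSV clips
fearleak run --config config.yaml --seed 1 --mode paper --out report/

# generate a synthetic cohort as OpenFace-dialect CSVs + manifest
fearleak synth --spec cohort.yaml --seed 1 --out cohort/

# single stages on a cohort manifest
fearleak episodes --manifest cohort/manifest.csv --au AU20 --out episodes.csv
fearleak symmetry --manifest cohort/manifest.csv --out coherence.csv
fearleak classify --manifest cohort/manifest.csv --classifier random_forest --loocv
```

`fearleak run` writes four tables (`au_comparison.csv`,
`duration_summary.csv`, `coherence.csv`, `classifier_report.csv`) plus
`summary.json` and a structured `run_log.jsonl`; runs are bit-reproducible
given the seed. Config files are flat YAML mirroring `PipelineConfig`
(`cohort_spec`, `au_set: seven_au|six_au`, `n_boot`, `n_perm`,
`m_comparisons`, `ml_mode: paper|leak_safe`, ...).

`--mode leak-safe` applies SMOTE inside each training fold with
participant-disjoint folds, instead of resampling the whole training pool
before cross-validation.

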