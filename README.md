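# eegmarkers

Nonlinear time-series biomarkers for discriminating Alzheimer's disease
(AD) from healthy aging in scalp EEG.

Resting-state EEG in AD shows *slowing* — spectral weight moves from the
fast rhythms (alpha 8–15 Hz, beta 15–30 Hz) into the slow ones (delta
0–4 Hz, theta 4–8 Hz) — together with a loss of signal complexity and of
inter-regional synchrony. This package implements, as one tested
pipeline, six measures that quantify those changes on 8-s, 128-Hz,
19-channel (10–20 montage) EEG segments, raw or band-filtered:

| code | measure | what it captures |
|------|---------|------------------|
| `wc` | wavelet coherence 𝒞 | frequency-resolved agreement between two channels, from smoothed Morlet cross-spectra |
| `fd` | Katz fractal dimension 𝓕 = ln(T−1) / ln(d(T−1)/D) | waveform roughness from curve length D and extent d |
| `qe` | quadratic entropy 𝒬 = −ln(A/B) + ln(2r) | irregularity via tolerance-corrected sample-entropy template matching |
| `we` | relative wavelet energy 𝓔ⱼ | fraction of squared Daubechies-4 coefficient energy in band j |
| `qg` | quantile-graph mean jump length Δₖ = (1/Q)·Σ Wₖ[i,j]·\|i−j\| | speed of movement through the amplitude distribution at lag k |
| `vg` | visibility-graph complexity index 𝓘 = 4c(1−c) | structural complexity from the largest visibility-adjacency eigenvalue |

Around the measures the package provides: dyadic wavelet band
extraction (delta/theta/alpha/beta), group screening by one-way ANOVA p
value and rank-based ROC AUC with the study parameter grids (entropy:
r = 0.05…1.00, m ∈ {1,2}; quantile graph: Q = 20, k = 1…25), SVM
classification with stratified K-fold cross-validation (Acc/Sen/Spe, AD
positive), a wall-time cost benchmark, and a synthetic cohort generator
that reproduces the four-group design (A/B healthy, C/D probable AD ×
eyes open/closed) with tunable AD effect sizes and an exact null.

Intended users: methods researchers who want reference implementations
of these measures with oracle-verified tests, and anyone who needs a
reproducible synthetic testbed for EEG biomarker screening protocols.

## Worked example

```python
from eegmarkers import RunConfig, run_pipeline
from eegmarkers.synthetic import effect_spec

spec = effect_spec(0.8, n_healthy=12, n_ad=12, n_channels=2, seed=42)
config = RunConfig(spec=spec, measures=("fd", "we", "qg", "vg"),
                   bands=("delta", "theta", "alpha", "beta"),
                   group_pairs=(("A", "C"),), k_folds=8, seed=42)
result = run_pipeline(config)
print(result.best_table.to_string(index=False))
print(result.classification_table.to_string(index=False))
```

```
measure electrode  band groups   params      p_value      auc
     fd       Fp1 delta A vs C          8.057253e-06 0.972222
     we       Fp1  beta A vs C          1.914077e-04 0.895833
     qg       Fp1 delta A vs C Q=20,k=1 1.890283e-10 1.000000
     vg       Fp2 delta A vs C          1.238469e-05 0.944444

measure electrode  band groups  k   accuracy  sensitivity  specificity
     fd       Fp1 delta A vs C  8  87.500000    91.666667    83.333333
     we       Fp1  beta A vs C  8  79.166667    75.000000    83.333333
     qg       Fp1 delta A vs C  8 100.000000   100.000000   100.000000
     vg       Fp2 delta A vs C  8 87.500000    91.666667    83.333333
```

Reading the output: each row is the electrode/band/parameter setting at
which a measure best separates healthy eyes-open subjects (group A) from
AD eyes-open subjects (group C) — the screening selects the lowest ANOVA
p over the parameter grid. At this strong synthetic effect (0.8) the
delta band dominates, and the quantile-graph jump length `qg` separates
the groups perfectly (AUC 1.0) and classifies every subject correctly
under 8-fold cross-validation — the same qualitative ordering the
measures show on clinical recordings, where slowing makes delta-band
features the strongest discriminators.

The same stages are available from the shell:

```bash
eegmarkers simulate --n-healthy 12 --n-ad 80 --seed 1 --out cohort/
eegmarkers extract  --cohort cohort/ --measure qg --band delta --out features.tsv
eegmarkers evaluate --cohort cohort/ --groups A:C --measure qg --band delta --out screen.tsv
eegmarkers classify --features features.tsv --measure qg --electrode Fp1 --band delta --k 10 --seed 1
eegmarkers benchmark --measures fd,qg,vg --repeats 3 --seed 1 --out costs.tsv
eegmarkers run-all  --seed 1 --out results/
```

## Layout

```
src/eegmarkers/
  core.py            EEGRecord, montage and group metadata
  synthetic.py       synthetic cohort generator (study conditions + nulls)
  io.py              plain-text record / cohort-directory format
  bands.py           Daubechies-4 dyadic band decomposition
  features/          the six measures + tidy feature extraction
  evaluation.py      ANOVA p / AUC screening, parameter-grid scans
  classification.py  stratified K-fold SVM (Acc/Sen/Spe)
  benchmark.py       wall-time cost curves on white noise
  pipeline.py        end-to-end orchestration with provenance
  cli.py             click-based command-line interface
docs/methods.md      model, parameter and design documentation
```
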