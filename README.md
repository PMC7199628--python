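# eegmatch

Template-matching anomaly detection for single-channel EEG, built to
study how the choice of similarity metric affects detection quality.

## The problem

Long-term EEG monitoring (seizure surveillance, sleep studies) needs to
flag recording windows that deviate from a patient's normal background
activity.  A classic approach is sequence matching: keep a set of
*templates* — feature vectors from segments known to be normal — and
compare each incoming segment against them.  The pipeline has three
stages:

1. **Feature extraction.**  Each ~20 s segment (e.g. 10,000 samples at
   512 Hz) is band-passed to the physiological range [0.1, 70] Hz, its
   power spectral density estimated by the Welch averaged-periodogram
   method, cropped to the analysis band, and normalized to unit sum so
   it can be treated as a discrete probability distribution over
   frequency.  This captures the δ (<4 Hz), θ (4–8), α (8–14),
   β (14–30) and γ (>30 Hz) rhythm structure that characterizes
   normal background EEG.

2. **Similarity measure.**  The query spectrum P is compared with each
   template spectrum Q under one of six metrics:

   | name | distance d(P, Q) | similarity s |
   |------|------------------|--------------|
   | ED   | ‖P − Q‖₂ | 1/d |
   | PCCD | Pearson correlation r(P, Q) | r |
   | SKLD | (D(P‖Q) + D(Q‖P))/2 | 1/d |
   | HD   | √(1 − BC(P, Q)) | 1/d |
   | KD   | ‖P − Q‖∞ | 1/d |
   | BD   | −ln BC(P, Q) | BC(P, Q) |

   where BC(P, Q) = Σₖ √(pₖ qₖ) is the Bhattacharyya coefficient.  HD
   and BD are both monotone transforms of BC (d_HD² = 1 − BC,
   d_BD = −ln(1 − d_HD²)).  The per-template scores are aggregated
   (nearest template, `max`, by default) and the batch of query scores
   is min–max normalized onto [0, 1].

3. **Decision.**  A threshold test: a segment with normalized
   similarity S ≤ λ is declared **abnormal**, S > λ **normal**.  λ is
   fitted by an exhaustive accuracy sweep on a labeled calibration
   group.

Evaluation uses two indicators: *accuracy* (fraction of correctly
classified test segments, cross-validated over two groups) and *AOPO* —
the crossing-point abscissa of the ascending-sorted normal-similarity
curve and the descending-sorted abnormal curve.  Smaller AOPO means the
two classes separate earlier; 0.5 is perfect separation, n + 0.5 means
no separation at all.

A seeded synthetic EEG generator (band-limited Gaussian rhythms plus
broadband noise; anomalies have disordered per-band amplitudes and a
raised noise floor) makes the whole pipeline testable with no external
data.

## Worked example

```python
from eegmatch import GeneratorConfig, generate_dataset, run_protocol
from eegmatch.evaluation import format_ranking

cfg = GeneratorConfig(seed=42)
dataset = generate_dataset(cfg, n_templates=30, n_normal_test=30, n_abnormal_test=30)
report = run_protocol(dataset, n_templates=30, group_size=30,
                      n_repetitions=20, seed=42)
print(report.per_metric.round(4))
print("ranking:", format_ranking(report.ranking))
```

prints

```
        mean_accuracy  mean_aopo  mean_lambda0
metric
ED             0.9342      1.475        0.5875
PCCD           0.9467      1.225        0.9035
SKLD           0.9650      1.000        0.5670
HD             0.9650      1.000        0.6940
KD             0.8842      1.775        0.4755
BD             0.9583      1.000        0.9490
ranking: HD = SKLD > BD > PCCD > ED > KD
```

Each row is one similarity metric evaluated over 20 repetitions of the
two-group cross-validation: `mean_accuracy` is the average fraction of
the 30 held-out segments classified correctly (threshold fitted on the
other group, then the groups swapped and the two results averaged);
`mean_aopo` is the average crossing-point index of the sorted
similarity curves (1.0 ≈ at most one abnormal segment overlaps the
normal score range); `mean_lambda0` is the average fitted threshold.
The Bhattacharyya-coefficient family (HD, BD) separates the classes at
least as early as every competitor (AOPO 1.0 vs 1.475 for plain
Euclidean matching), the qualitative outcome this detector design is
built around.

## Command line

```sh
eegmatch simulate --output-dir data/           # synthetic dataset as CSV + manifest
eegmatch evaluate --output-dir report/         # full protocol, report + fitted model
eegmatch detect --model report/model.json --input data/ --output decisions.csv
eegmatch features --input data/ --output spectra.csv
```

All commands take `--config config.yaml` (any subset of the defaults)
and `--seed`; identical config + seed reproduce byte-identical outputs.

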