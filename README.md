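# fnirsfc

Static and dynamic functional-connectivity (FC) analysis of task fNIRS
recordings, for researchers studying group differences in cortical
coupling — e.g. distinguishing adolescents with major depressive disorder
(MDD) from healthy controls (HC) during a verbal fluency task — and for
methodologists who need a fully synthetic, seeded test bed for such
pipelines.

The pipeline:

1. **QC** — channel retention by baseline signal-to-noise,
   SNR = 20·log₁₀(μ/σ) dB, threshold 40 dB at both wavelengths;
2. **Preprocessing** — optical density → modified Beer–Lambert inversion
   to ΔHbO/ΔHbR → 0.01–0.2 Hz zero-phase Butterworth band-pass →
   wavelet (db5) motion correction → hemodynamic separation
   (functional ΔHbR = k·ΔHbO, k < 0) → summation into six ROIs
   (bilateral DLPFC, mPFC, temporal lobe);
3. **Connectivity** — static FC: Fisher z = atanh(r) of each of the
   15 ROI pairs over the 150-s task period; dynamic FC: the same in 20-s
   windows stepped by 1 s, giving a 15 × 131 matrix **X** per participant;
4. **PCA features** — eigendecomposition of the window covariance of
   **X**; the component count N is the smallest whose cohort-mean
   cumulative contribution rate CCR(N) = Σₙ≤N κₙ / Σκₙ reaches 90%;
   reduced features **D** = **X U**₁..N, shifted so the cohort minimum
   is 0;
5. **Statistics** — normality-gated t / rank-sum group tests with
   Benjamini–Hochberg FDR, Spearman feature–symptom correlations
   (DASS-21 subscales, SHAPS), covariate-adjusted regression with
   fluoxetine-equivalent dosing;
6. **Classification** — random forest (Gini), 10-fold
   test/validation/train rotation, grid search over trees × leaf size ×
   bootstrap fraction, pooled test accuracy/F1/AUC with bootstrap CIs and
   out-of-bag permutation importance.

Because recordings of this kind are rarely shared, the package includes a
seeded synthetic cohort generator whose planted structure (group-wise FC
levels, pathway effects, symptom links) the pipeline must recover; see
`docs/methods.md` for the generative model and its limitations.

## Worked example

Simulate a 40-participant cohort (20 MDD / 20 HC), run the full pipeline
in memory, test the static features and classify:

```python
from fnirsfc.synthetic import SimulationConfig
from fnirsfc.experiments import run_pipeline
from fnirsfc import stats as fstats
from fnirsfc.classifier import MddClassifier, RfConfig

run = run_pipeline(SimulationConfig(n_per_group=20, seed=7))
gc = fstats.group_compare_features(
    run.features.table[run.features.static_columns], run.labels)
sig = gc[gc["q"] < 0.05].sort_values("q")
print(sig[["test", "statistic", "p", "q", "direction"]].round(4).head(6))

model = MddClassifier(
    run.features.table, run.labels,
    fold_shift_columns=[c for c in run.features.table.columns
                        if c.startswith("pc")])
print(model.fit(grid=RfConfig(70, 1, 0.8), k=5, seed=7).summary())
```

Output:

```
                              test  statistic    p       q  direction
feature
static|DLPFC(L)~TL(L)    student_t    -5.9979  0.0  0.0000       -1.0
static|DLPFC(R)~TL(L)    student_t    -5.1733  0.0  0.0001       -1.0
static|DLPFC(R)~mPFC(R)  student_t    -4.8195  0.0  0.0001       -1.0
static|DLPFC(L)~TL(R)    student_t     4.9032  0.0  0.0001        1.0
Random-forest group classification (10-fold rotation, pooled test sets)
config: 70 trees, min leaf 1, bootstrap fraction 0.8
  accuracy_pct    77.500  (95% CI 62.500-90.000)
  f1               0.769  (95% CI 0.600-0.899)
  auc              0.863  (95% CI 0.726-0.972)
  fold-mean accuracy 77.50% ; majority baseline 50.00%
  top features: static|DLPFC(L)~TL(L) (1.00), ...
```

The four features flagged at q < 0.05 are exactly the four planted
pathway effects, with the planted directions (MDD lower on three
pathways, higher on DLPFC(L)~TL(R)), and they top the importance ranking;
accuracy is well above the 50% majority baseline even at this small n.

## Command line

Each stage is a subcommand writing plain CSV/TSV/JSON artifacts with
provenance sidecars:

```bash
fnirsfc run-all --seed 1 --grid reduced --workdir out/
fnirsfc simulate --seed 1 --workdir out/     # or stage by stage
fnirsfc qc --workdir out/
fnirsfc preprocess --workdir out/
fnirsfc fc --workdir out/
fnirsfc features --workdir out/
fnirsfc stats --workdir out/
fnirsfc classify --no-grid --workdir out/
```

`--config config.yaml` overrides any parameter (window length, band, SNR
threshold, CCR band, FDR α, grid, seeds); all defaults are the reference
analysis values (20 s / 1 s windows, 0.01–0.2 Hz, 40 dB, 90–95% CCR,
α = 0.05, tree grid 10–150 × leaf 1–11 × fraction 0.5–1.0).

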