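# facescreen

Screening pipelines over pre-extracted facial-feature time series, built to
study whether per-frame facial dynamics separate a clinical (dementia) from
a healthy group. The package implements two analysis routes end to end,
driven by a synthetic cohort generator that reproduces the statistical
structure of a restricted clinical video corpus (subjects contributing 1–10
sessions of ~10 minutes at 30 FPS each):

- **Mesh branch** — 478-landmark face-mesh frames are recentered on a
  face-center landmark, isotropically rescaled to [−1, 1] (1434 features per
  frame after dropping visibility), reduced by PCA (default 16 components,
  with cumulative explained-variance reporting), and classified by a
  single-layer LSTM (hidden size 32, last hidden state → dense head, Adam,
  cross-entropy) with subject-disjoint, class-balanced test splits.
- **AU branch** — 17-channel action-unit intensity sequences (0–5 scale)
  are cut into non-overlapping 512/1024-frame clips, summarized by per-channel
  temporal mean and variance (34 features, or 22 with the 11-channel subset),
  classified per clip by an RBF-kernel SVM under leave-one-subject-out
  folds, and aggregated into subject decisions by threshold voting, with
  both the max-accuracy and the equal-error-rate operating point reported.

The LSTM (forward pass, backpropagation through time, Adam) is implemented
directly on NumPy, so no deep-learning framework is required.

## CLI

All commands are under the `facescreen` entry point and accept a YAML run
configuration (see `facescreen.io.RunConfig`; unknown keys are rejected):

```
facescreen generate      --config run.yaml --seed 1 --out cohort/
facescreen normalize-mesh cohort/H000_s0_mesh.csv --out frames.csv
facescreen fit-pca       frames.csv -k 16 --out pca.json
facescreen train-seq     --branch mesh --frames 1024 --config run.yaml --seed 1
facescreen featurize-au  cohort/*_au.csv --segment 1024 --aus all17 --out clips.csv
facescreen eval-au       --segment 1024 --aus significant11 --seed 1
facescreen run-all       --config run.yaml --seed 1 --out runs/demo
```

`run-all` generates the cohort, runs the configured branches and writes all
artifacts (clip features, PCA model, sweep tables, subject decisions, a
JSON report keyed by a config hash) under the output directory. Reports are
bit-reproducible from config + seed; the timestamp is isolated in a single
field.

## Layout

| Module | Purpose |
| --- | --- |
| `facescreen.synthetic` | cohort generator (AU / mesh / appearance streams, keyed substreams of one seed) |
| `facescreen.mesh` | frame normalization, PCA fit/transform, explained-variance table |
| `facescreen.seqmodel` | NumPy LSTM classifier, subject-disjoint splits, frame-count ablation |
| `facescreen.au` | segmentation, clip mean/variance features, AU subset tables |
| `facescreen.evaluate` | LOSO SVM folds, threshold voting, sweep, metrics (accuracy/recall/precision/F1/EER) |
| `facescreen.io` | CSV readers/writers, run configuration, pipeline driver |
| `facescreen.cli` | command-line entry points |
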