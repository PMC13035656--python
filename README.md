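# modcontrib

Occlusion-based, model- and performance-agnostic **modality contribution**
for multimodal black-box predictors.

Multimodal models — fusing medical images with clinical reports or tabular
patient data, for instance — often do not use their inputs the way their
architecture suggests: some rely overwhelmingly on a single modality
(*unimodal collapse*) while appearing to be multimodal. `modcontrib`
quantifies this for any predictor that can be called as a function, without
gradients, attention maps, or accuracy metrics. It is aimed at people who
build or audit multimodal models (deep networks or otherwise) and want a
comparable, normalised number per modality.

## The metric

For each sample k the predictor's unmasked output p₀ᵏ is compared against
outputs with one part of one modality occluded: image patches are replaced
by the image's own mean intensity, tabular scalars by their dataset column
mean (two-bit one-hot binaries by (0, 0)), words by deletion or a neutral
token. With per-class absolute differences dᵢ,ₗᵏ = |p₀ᵏ − pᵢ,ₗᵏ| averaged
over the N samples:

```
mᵢ   = 1ᵀdᵢ   / Σⱼ 1ᵀdⱼ        modality contribution,  Σᵢ mᵢ = 1
mpᵢˡ = 1ᵀdᵢ,ₗ / Σⱼ 1ᵀdᵢ,ⱼ      part importance,        Σₗ mpᵢˡ = 1
mpᵢˡ·mᵢ                         weighted contribution,  ΣᵢΣₗ = 1
```

A predictor whose output never moves is reported as *degenerate*, never as
uniform; maxᵢ mᵢ ≥ 0.95 is flagged as a unimodal `collapse` and ≥ 0.90 as a
`tendency` (both configurable). Per-sample contributions, per-class (MEAN /
MAX / single-class) importance maps, patch heatmaps, word colorings and
attribute rankings come from the same sweep. See `docs/methods.md` for
assumptions, numerical choices and limitations.

## Worked example

The package ships a synthetic-fixture generator whose predictors have
analytically known contributions, so the whole pipeline can be exercised
without any trained model:

```sh
$ modcontrib fixture --out demo --seed 3 --n-samples 6
fixture written to demo
expected modality contribution: image=0.0286, tabular=0.3366, text=0.6348

$ modcontrib run --config demo/config.yaml --data demo --out demo_out --render mean
loaded 6 samples, 3 modalities
  m[image] = 0.0286
  m[tabular] = 0.3366
  m[text] = 0.6348
verdict: balanced (dominant: text)
renders written under demo_out
report written to demo_out/report.json
```

The recovered `m` matches the fixture's closed-form ground truth to
~1e-16: the text modality drives 63 % of this predictor's output dynamic,
the image only 3 % — far from the 0.90 tendency threshold, hence
`balanced`. `demo_out/` contains `report.json` (m, mp, weighted
contributions, per-sample contributions, verdict), `report.csv` (one row
per modality part), a patch heatmap PNG, a word-coloring HTML and an
attribute bar chart. `--dry-run` prints the sweep size (N·(1 + Σᵢ hᵢ)
predictor calls) without touching the predictor.

As a library:

```python
from modcontrib import FixtureSpec, make_fixture, run_sweep, build_report

fx = make_fixture(FixtureSpec(seed=3, n_samples=6))
acc = run_sweep(fx.predictor, fx.samples, fx.descs, fx.stats)
report = build_report(acc, fx.descs)
print(report.m, report.verdict.label)   # [0.0286 0.3366 0.6348] balanced
```

Any object mapping a `MultimodalSample` to a fixed-length output vector can
stand in for `fx.predictor`; wrap a real model (e.g. a torch module with
dropout disabled) in such a callable and declare it in the YAML config via
`predictor: {import: "your.module:factory", args: {...}}`.

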