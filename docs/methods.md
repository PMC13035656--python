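# Methods

## The metric

`modcontrib` measures how much each modality of a multimodal dataset
contributes to a black-box predictor's output, by occlusion. For sample
k with unmasked output vector p₀ᵏ (length C), each modality i is split
into hᵢ parts; occluding part l and re-forwarding gives pᵢ,ₗᵏ and the
per-class absolute difference dᵢ,ₗᵏ = |p₀ᵏ − pᵢ,ₗᵏ|. Averaging over the N
samples and summing over parts and classes yields the modality's output
dynamic 1ᵀdᵢ, and

- modality contribution mᵢ = 1ᵀdᵢ / Σⱼ 1ᵀdⱼ, with Σᵢ mᵢ = 1,
- part importance mpᵢˡ = 1ᵀdᵢ,ₗ / Σⱼ 1ᵀdᵢ,ⱼ, with Σₗ mpᵢˡ = 1 per modality,
- globally weighted part contribution mpᵢˡ·mᵢ, with ΣᵢΣₗ mpᵢˡ·mᵢ = 1.

The method is model-agnostic (only input → output access is needed) and
performance-agnostic (it measures output dynamics, not task accuracy). A
literature-standard ε ≈ 1e-7 guards the denominators; because the all-zero
case is detected and reported explicitly (below), the non-degenerate
normalisations are computed exactly, which is what makes the Σ = 1
identities hold to 1e-9 in the test suite rather than only up to ε.

Assumptions: the predictor is deterministic (dropout/sampling disabled) with
a fixed output length C, and modalities enter the model independently enough
that occluding one part leaves the others' encodings unchanged at the input
level. Cross-modality interaction terms are not modelled; mᵢ attributes the
*marginal* output dynamic of occluding modality i.

## Partitioning and masking

- **Images (2D/3D)**: non-overlapping patches in row-major order, 0-based,
  half-open per axis; hᵢ = Π ⌈extent/patch⌉. When an axis is not divisible by
  the patch size the final patch is truncated at the boundary (no padding —
  padding would fabricate intensities); a warning notes the truncation.
  Replacement is the mean intensity of the *same* image (per channel for
  multi-channel rasters), which keeps the masked input close to the training
  distribution and avoids attributing domain-shift sensitivity to the
  modality. `zero` replacement is available as an alternative.
- **Tabular**: one part per attribute. Continuous attributes are replaced by
  their column mean over the analysis dataset; two-bit one-hot binary
  attributes are replaced by (0, 0), a state outside both valid codes, so
  "masked" is distinguishable from either category. `onehot_null` applied to
  a continuous attribute is an error.
- **Text**: one part per word (whitespace tokenization after punctuation
  stripping). The default occlusion is word deletion (`remove`);
  substitution with a neutral token (`mask_token`) is available because
  input-level text occlusion can reasonably be realised either way and the
  choice is surfaced in configuration rather than hidden. Empty documents
  yield zero parts and are flagged degenerate for that modality.

Masking is copy-on-write throughout; a source sample is never mutated, and a
masked variant differs from its source only inside the targeted part (tested
element-wise). One caveat on re-masking: replacement strategies with a fixed
target value (`zero`, `dataset_mean`, `onehot_null`, `mask_token`) are
idempotent, but `self_mean` is only idempotent at its fixed points (constant
images), since a second pass uses the already-perturbed image's mean, and
`remove` shifts word indices. This is a property of the replacement rules,
not a defect to be corrected.

## Choosing hᵢ

hᵢ is the resolution/cost dial. For tabular data the natural choice is one
part per attribute; for text, one per word. For images hᵢ must stay small
enough (patches big enough) that one patch can occlude decision-relevant
structure — masking single pixels leaves the output unchanged and
underestimates the vision modality. Typical grids: 16×16 patches on 224×224
rasters (196 parts) down to half-extent patches on 3D volumes (8 parts) when
the signal is a single large structure. The sweep costs N·(1 + Σᵢ hᵢ)
forward passes; `run --dry-run` prints the plan size before committing. No
correction is applied for unequal hᵢ across modalities: mᵢ sums patch
distances as defined, and this dependence on the partition choice is a
documented property of the metric.

## Numerical and degenerate-input choices

- **Degenerate reports**: if every accumulated distance is exactly zero (a
  constant predictor), m is reported as the zero vector with an explicit
  `degenerate` flag — a uniform fallback would fabricate a conclusion.
  Weighted contributions raise on degenerate reports. A single modality with
  all-zero distances is flagged per-modality the same way.
- **Collapse verdict**: `collapse` when maxᵢ mᵢ ≥ 0.95, `tendency` when
  ≥ 0.90, else `balanced`. Published analyses label 0.98–1.00 splits
  collapses and a 0.92 split a tendency, but no cutoffs are standard, so
  both thresholds are configurable and echoed next to the verdict.
- **Ties and ordering**: part order is fixed (row-major / attribute order /
  word position), so reports are reproducible bit-for-bit across repeated
  runs. Top-k highlighting in the tabular renderer breaks ties by attribute
  order and annotates them.
- **Per-sample text length**: text hᵢ varies per sample; the accumulator
  pads part sums to the longest document, so dataset-level text mp is
  word-*position* importance, while the per-sample word scores retained in
  the report drive word-level rendering.
- **Permutation invariance**: reordering samples permutes float additions,
  so reports agree to accumulation accuracy (≲1e-12 on unit-scale values),
  not bit-for-bit; batch size and output rescaling leave results exactly
  unchanged.
- **Output space**: whether the predictor emits logits or probabilities is
  the caller's contract (`output_space` is echoed in the report). Bounded
  outputs (probabilities) are the safer default for classifiers since
  distances are then commensurable across classes.

## The synthetic generator

`fixtures.make_dataset` emulates a desk-scale multimodal study: an 8×8
raster with 4×4 patches (h = 4), a mixed continuous/one-hot tabular row, and
a short document over a toy vocabulary. Pixels are i.i.d. discrete-uniform
integers 0–255 stored as floats (so the PNG round trip is exact and
end-to-end comparisons can be made at 1e-9), continuous attributes are
standard normal, binary attributes are fair one-hot pairs, documents have
3–6 words. Generation is pure and fully determined by the spec and its seed.

Oracle predictor families provide analytically known contributions:
`unimodal` (indicator ground truth; note that with dataset-mean masking and
N = 1 a column equals its own mean, so tabular-driven fixtures need N ≥ 2 to
be non-degenerate), `additive_linear` (part-local features, so expected
distances — and m, mp — follow in closed form, evaluated by plain loops
independent of the sweep), `two_class_separable` (per-class importance maps
concentrate on distinct parts) and `constant` (degenerate by construction).
A separate naive triple-loop reimplementation of the sweep
(`modcontrib.reference`) duplicates the masking arithmetic inline and serves
as a second, independent validation route.

What the generator does *not* emulate: spatial structure in images,
inter-attribute correlation, realistic language, class imbalance, or any
trained model's representation geometry. Passing tests therefore establish
the correctness of the metric's arithmetic, invariances and plumbing — not
that any particular clinical model balances its modalities.

## Problem sizes

Default validation sizes are deliberately small so all oracle loops are
effectively instant: randomized checks use N ≤ 5 samples, ≤ 3 modalities and
hᵢ ≤ 8; ground-truth recovery uses N = 6–8. The sweep itself scales linearly
in N·Σhᵢ predictor calls and is limited in practice by the model's forward
pass, not by the accumulator.

## Known limitations

- Attribution quality depends on the mask-size choice for modalities without
  natural sequencing (images, continuous signals); the package reports, but
  cannot validate, the user's hᵢ.
- Replacement values (image mean, column mean) reduce but do not eliminate
  domain shift; the metric cannot distinguish genuine contribution from
  residual shift sensitivity.
- No cross-modality interaction terms and no uncertainty quantification on
  mᵢ are provided.
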