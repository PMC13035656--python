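"""Synthetic multimodal datasets and oracle predictors with known contributions.

Every engine path is testable without downloads or trained models: the
generator emits small multimodal datasets (raster image or volume + tabular
row + free text) together with simple analytic predictors whose modality
contributions are known in closed form.

Predictor families
------------------
``unimodal``
    Output depends on exactly one modality; the expected contribution vector
    is the indicator of that modality.
``additive_linear``
    Scalar output Σ w_{i,l}·φ_{i,l}(x), where φ is the patch intensity sum
    (image), the attribute value (tabular; first bit of a one-hot pair), or a
    per-word weight summed over the document (text).  Because the features
    are part-local, occluding part l changes the output by exactly
    w_{i,l}·(φ − φ_masked), so the expected distances — and hence m and mp —
    follow in closed form.  The closed form is evaluated by plain loops in
    :func:`expected_additive_contribution`, independently of the sweep.
``two_class_separable``
    Two output components, each driven by a different image patch (or
    tabular attribute), so class-resolved importance maps each concentrate
    on one part.
``constant``
    Output never changes; every distance is zero and the report must be
    flagged degenerate.

Image pixels are i.i.d. discrete-uniform integers 0–255 stored as floats, so
the PNG round trip through the on-disk layout is bit-exact; tabular
continuous attributes are standard normal; binary attributes are two-bit
one-hot pairs; text is drawn from a fixed toy vocabulary.  Generation is
pure: identical spec + seed → identical dataset and predictor.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    DatasetStatistics,
    ModalityDescriptor,
    MultimodalSample,
    compute_dataset_statistics,
)

FAMILIES = ("unimodal", "additive_linear", "two_class_separable", "constant")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative recipe for one synthetic dataset + predictor pair."""

    seed: int = 0
    n_samples: int = 8
    modalities: tuple[str, ...] = ("image", "tabular", "text")
    image_kind: str = "image2d"
    image_shape: tuple[int, ...] = (8, 8)
    image_patch: tuple[int, ...] = (4, 4)
    tabular_kinds: tuple[str, ...] = (
        "continuous",
        "continuous",
        "binary_onehot",
        "continuous",
    )
    text_vocab: tuple[str, ...] = (
        "no",
        "acute",
        "disease",
        "catheter",
        "normal",
        "chest",
        "pain",
        "clear",
    )
    text_len_range: tuple[int, int] = (3, 6)
    family: str = "additive_linear"
    unimodal_target: str = "image"
    weights: dict | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown predictor family {self.family!r}")
        if not self.modalities:
            raise ValueError("at least one modality is required")
        for f in ("modalities", "image_shape", "image_patch", "tabular_kinds",
                  "text_vocab", "text_len_range"):
            object.__setattr__(self, f, tuple(getattr(self, f)))


def make_descriptors(spec: FixtureSpec) -> list[ModalityDescriptor]:
    descs = []
    for name in spec.modalities:
        if name == "image":
            descs.append(
                ModalityDescriptor(
                    name="image",
                    kind=spec.image_kind,
                    shape=spec.image_shape,
                    patch_shape=spec.image_patch,
                    mask_strategy="self_mean",
                )
            )
        elif name == "tabular":
            descs.append(
                ModalityDescriptor(
                    name="tabular",
                    kind="tabular",
                    mask_strategy="dataset_mean",
                    feature_kinds=spec.tabular_kinds,
                )
            )
        elif name == "text":
            descs.append(
                ModalityDescriptor(name="text", kind="text", mask_strategy="remove")
            )
        else:
            raise ValueError(f"unknown fixture modality {name!r}")
    return descs


def make_dataset(
    spec: FixtureSpec,
) -> tuple[list[MultimodalSample], list[ModalityDescriptor], DatasetStatistics]:
    """Draw the dataset declared by ``spec``; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    descs = make_descriptors(spec)
    by_name = {d.name: d for d in descs}
    samples = []
    for k in range(spec.n_samples):
        parts: dict[str, object] = {}
        if "image" in by_name:
            parts["image"] = rng.integers(0, 256, size=spec.image_shape).astype(float)
        if "tabular" in by_name:
            row = []
            for kind in spec.tabular_kinds:
                if kind == "continuous":
                    row.append(rng.normal())
                else:
                    bit = rng.integers(0, 2)
                    row.extend([float(bit), float(1 - bit)])
            parts["tabular"] = np.array(row, dtype=float)
        if "text" in by_name:
            lo, hi = spec.text_len_range
            length = int(rng.integers(lo, hi + 1))
            parts["text"] = [str(w) for w in rng.choice(spec.text_vocab, size=length)]
        samples.append(MultimodalSample(sample_id=f"s{k:04d}", parts=parts))
    stats = compute_dataset_statistics(samples, descs)
    return samples, descs, stats


# -- geometry helpers (plain loops, shared by predictor and closed form) ----


def _image_patches(spec: FixtureSpec) -> list[tuple[slice, ...]]:
    nd = 2 if spec.image_kind == "image2d" else 3
    extents = spec.image_shape[:nd]
    patch = spec.image_patch
    counts = [math.ceil(e / p) for e, p in zip(extents, patch)]
    slabs = []
    for cell in np.ndindex(*counts):
        slabs.append(
            tuple(
                slice(c * p, min((c + 1) * p, e))
                for c, p, e in zip(cell, patch, extents)
            )
        )
    return slabs


def _tabular_spans(spec: FixtureSpec) -> list[tuple[int, int]]:
    spans, start = [], 0
    for kind in spec.tabular_kinds:
        width = 2 if kind == "binary_onehot" else 1
        spans.append((start, start + width))
        start += width
    return spans


def default_weights(spec: FixtureSpec) -> dict:
    """Deterministic per-part weights for the additive family.

    Image weights are scaled by 1/(255·patch pixels) so that image, tabular
    and text terms have comparable magnitude and no single modality dwarfs
    the others by units alone.
    """
    rng = np.random.default_rng([spec.seed, 99991])
    weights: dict = {}
    if "image" in spec.modalities:
        slabs = _image_patches(spec)
        npix = int(np.prod(spec.image_patch))
        weights["image"] = rng.normal(size=len(slabs)) / (255.0 * npix)
    if "tabular" in spec.modalities:
        weights["tabular"] = rng.normal(size=len(spec.tabular_kinds))
    if "text" in spec.modalities:
        weights["text"] = {
            w: float(v) for w, v in zip(spec.text_vocab, rng.normal(size=len(spec.text_vocab)))
        }
    return weights


class OraclePredictor:
    """A black-box predictor with its analytically expected contributions.

    ``expected_m`` (and ``expected_mp`` for the additive family) are attached
    ground truth under the fixture's declared masking strategies; they are
    computed by plain closed-form loops, not by the sweep under test.
    """

    def __init__(self, fn, family: str, n_classes: int,
                 expected_m: np.ndarray | None = None,
                 expected_mp: dict[str, np.ndarray] | None = None):
        self._fn = fn
        self.family = family
        self.n_classes = n_classes
        self.expected_m = expected_m
        self.expected_mp = expected_mp
        self.output_space = "raw"
        self.n_calls = 0

    def __call__(self, sample: MultimodalSample) -> np.ndarray:
        self.n_calls += 1
        return self._fn(sample)

    def predict_batch(self, samples: Sequence[MultimodalSample]) -> np.ndarray:
        self.n_calls += len(samples)
        return np.stack([self._fn(s) for s in samples])


def _additive_fn(spec: FixtureSpec, weights: dict):
    slabs = _image_patches(spec) if "image" in spec.modalities else []
    spans = _tabular_spans(spec) if "tabular" in spec.modalities else []

    def fn(sample: MultimodalSample) -> np.ndarray:
        total = 0.0
        if "image" in sample.parts and "image" in weights:
            arr = np.asarray(sample.parts["image"], dtype=float)
            for l, slab in enumerate(slabs):
                total += weights["image"][l] * float(arr[slab].sum())
        if "tabular" in sample.parts and "tabular" in weights:
            row = np.asarray(sample.parts["tabular"], dtype=float)
            for a, (start, _stop) in enumerate(spans):
                total += weights["tabular"][a] * float(row[start])
        if "text" in sample.parts and "text" in weights:
            for tok in sample.parts["text"]:
                total += weights["text"].get(tok, 0.0)
        return np.array([total])

    return fn


def expected_additive_contribution(
    spec: FixtureSpec,
    samples: Sequence[MultimodalSample],
    stats: DatasetStatistics,
    weights: dict,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Closed-form m and mp for the additive family under the fixture's
    masking rules (image self-mean, tabular dataset-mean/one-hot-null, text
    word removal), evaluated by direct loops over samples and parts."""
    per_part: dict[str, np.ndarray] = {}

    if "image" in spec.modalities:
        slabs = _image_patches(spec)
        sums = np.zeros(len(slabs))
        for s in samples:
            arr = np.asarray(s.parts["image"], dtype=float)
            mu = arr.mean()
            for l, slab in enumerate(slabs):
                npix = arr[slab].size
                sums[l] += abs(weights["image"][l] * (arr[slab].sum() - npix * mu))
        per_part["image"] = sums

    if "tabular" in spec.modalities:
        spans = _tabular_spans(spec)
        mu = stats.column_means["tabular"]
        sums = np.zeros(len(spans))
        for s in samples:
            row = np.asarray(s.parts["tabular"], dtype=float)
            for a, (start, _stop) in enumerate(spans):
                if spec.tabular_kinds[a] == "binary_onehot":
                    delta = row[start]  # first bit nulled to 0
                else:
                    delta = row[start] - mu[start]
                sums[a] += abs(weights["tabular"][a] * delta)
        per_part["tabular"] = sums

    if "text" in spec.modalities:
        max_len = max(len(s.parts["text"]) for s in samples)
        sums = np.zeros(max_len)
        for s in samples:
            for l, tok in enumerate(s.parts["text"]):
                sums[l] += abs(weights["text"].get(tok, 0.0))
        per_part["text"] = sums

    totals = np.array([per_part[name].sum() for name in spec.modalities])
    grand = totals.sum()
    m = totals / grand if grand > 0 else np.zeros_like(totals)
    mp = {}
    for name in spec.modalities:
        tot = per_part[name].sum()
        mp[name] = per_part[name] / tot if tot > 0 else np.zeros_like(per_part[name])
    return m, mp


def _unimodal_fn(spec: FixtureSpec):
    target = spec.unimodal_target
    if target not in spec.modalities:
        raise ValueError(f"unimodal target {target!r} not in layout {spec.modalities}")
    vocab_w = {w: 1.0 + i for i, w in enumerate(spec.text_vocab)}

    def fn(sample: MultimodalSample) -> np.ndarray:
        value = sample.parts[target]
        if target == "image":
            out = float(np.asarray(value, dtype=float).mean())
        elif target == "tabular":
            out = float(np.asarray(value, dtype=float).sum())
        else:
            out = float(sum(vocab_w.get(tok, 0.5) for tok in value))
        return np.array([out])

    return fn


def _two_class_fn(spec: FixtureSpec):
    if "image" in spec.modalities:
        slabs = _image_patches(spec)
        if len(slabs) < 2:
            raise ValueError("two_class_separable needs an image with >= 2 patches")
        npix = float(np.prod(spec.image_patch))

        def fn(sample: MultimodalSample) -> np.ndarray:
            arr = np.asarray(sample.parts["image"], dtype=float)
            return np.array(
                [arr[slabs[0]].sum() / (255.0 * npix), arr[slabs[1]].sum() / (255.0 * npix)]
            )

        return fn, "image"

    if "tabular" in spec.modalities and len(spec.tabular_kinds) >= 2:
        spans = _tabular_spans(spec)

        def fn(sample: MultimodalSample) -> np.ndarray:
            row = np.asarray(sample.parts["tabular"], dtype=float)
            return np.array([row[spans[0][0]], row[spans[1][0]]])

        return fn, "tabular"
    raise ValueError("two_class_separable needs an image or a >=2-attribute table")


def make_predictor(
    spec: FixtureSpec,
    samples: Sequence[MultimodalSample] | None = None,
    stats: DatasetStatistics | None = None,
) -> OraclePredictor:
    """Build the predictor declared by ``spec`` with attached ground truth.

    The additive family requires explicit weights (see
    :func:`default_weights`); its expected m/mp depend on the dataset, which
    is regenerated from the spec when not supplied.
    """
    names = list(spec.modalities)
    if spec.family == "constant":
        return OraclePredictor(
            lambda sample: np.array([0.5]), "constant", 1,
            expected_m=np.zeros(len(names)),
        )
    if spec.family == "unimodal":
        indicator = np.array([1.0 if n == spec.unimodal_target else 0.0 for n in names])
        return OraclePredictor(_unimodal_fn(spec), "unimodal", 1, expected_m=indicator)
    if spec.family == "two_class_separable":
        fn, driven = _two_class_fn(spec)
        indicator = np.array([1.0 if n == driven else 0.0 for n in names])
        return OraclePredictor(fn, "two_class_separable", 2, expected_m=indicator)

    # additive_linear
    if spec.weights is None:
        raise ValueError("additive_linear requires weights (see default_weights)")
    weights = _weights_from_jsonable(spec.weights)
    if samples is None or stats is None:
        samples, _descs, stats = make_dataset(spec)
    m, mp = expected_additive_contribution(spec, samples, stats, weights)
    return OraclePredictor(
        _additive_fn(spec, weights), "additive_linear", 1, expected_m=m, expected_mp=mp
    )


@dataclass
class Fixture:
    """A generated dataset, its descriptors and statistics, and the oracle
    predictor with attached ground truth."""

    spec: FixtureSpec
    samples: list[MultimodalSample]
    descs: list[ModalityDescriptor]
    stats: DatasetStatistics
    predictor: OraclePredictor


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Convenience bundle; fills in default additive weights when absent."""
    if spec.family == "additive_linear" and spec.weights is None:
        spec = dataclasses.replace(spec, weights=_weights_to_jsonable(default_weights(spec)))
    samples, descs, stats = make_dataset(spec)
    predictor = make_predictor(spec, samples, stats)
    return Fixture(spec=spec, samples=samples, descs=descs, stats=stats, predictor=predictor)


def random_spec(seed: int) -> FixtureSpec:
    """A small randomized fixture spec (N ≤ 5, n ≤ 3, h_i ≤ 8) for
    oracle-equivalence and normalization sweeps."""
    rng = np.random.default_rng(seed)
    layouts = [
        ("image",),
        ("tabular",),
        ("text",),
        ("image", "tabular"),
        ("image", "text"),
        ("tabular", "text"),
        ("image", "tabular", "text"),
    ]
    modalities = layouts[int(rng.integers(len(layouts)))]
    image_kind = "image2d" if rng.random() < 0.7 else "image3d"
    if image_kind == "image2d":
        image_shape, image_patch = (6, 6), (3, 3)  # h = 4
        if rng.random() < 0.3:
            image_shape, image_patch = (5, 4), (2, 2)  # remainder policy, h = 6
    else:
        image_shape, image_patch = (4, 4, 4), (2, 2, 2)  # h = 8
    n_attrs = int(rng.integers(1, 5))
    tabular_kinds = tuple(
        "binary_onehot" if rng.random() < 0.4 else "continuous" for _ in range(n_attrs)
    )
    family = FAMILIES[int(rng.integers(len(FAMILIES)))]
    target = modalities[int(rng.integers(len(modalities)))]
    if family == "two_class_separable" and "image" not in modalities and (
        "tabular" not in modalities or n_attrs < 2
    ):
        family = "unimodal"
    spec = FixtureSpec(
        seed=int(rng.integers(2**31 - 1)),
        n_samples=int(rng.integers(1, 6)),
        modalities=modalities,
        image_kind=image_kind,
        image_shape=image_shape,
        image_patch=image_patch,
        tabular_kinds=tabular_kinds,
        text_len_range=(1, 4),
        family=family,
        unimodal_target=target,
    )
    if family == "additive_linear":
        spec = dataclasses.replace(
            spec, weights=_weights_to_jsonable(default_weights(spec))
        )
    return spec


# -- serialization and the on-disk layout -----------------------------------


def _weights_to_jsonable(weights: dict) -> dict:
    out: dict = {}
    for key, value in weights.items():
        out[key] = dict(value) if isinstance(value, dict) else [float(v) for v in value]
    return out


def _weights_from_jsonable(weights: dict) -> dict:
    out: dict = {}
    for key, value in weights.items():
        out[key] = (
            {k: float(v) for k, v in value.items()}
            if isinstance(value, dict)
            else np.asarray(value, dtype=float)
        )
    return out


def spec_to_dict(spec: FixtureSpec) -> dict:
    doc = dataclasses.asdict(spec)
    for key, value in doc.items():
        if isinstance(value, tuple):
            doc[key] = list(value)
    return doc


def spec_from_dict(doc: dict) -> FixtureSpec:
    return FixtureSpec(**doc)


def predictor_from_json(path: str | Path) -> OraclePredictor:
    """Rebuild a fixture predictor from its serialized spec (the CLI's
    built-in predictor loader)."""
    doc = json.loads(Path(path).read_text())
    return make_predictor(spec_from_dict(doc["spec"]))


def tabular_column_names(spec: FixtureSpec) -> list[str]:
    names = []
    for a, kind in enumerate(spec.tabular_kinds):
        if kind == "binary_onehot":
            names.extend([f"attr{a}_yes", f"attr{a}_no"])
        else:
            names.append(f"attr{a}")
    return names


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Emit the standard on-disk layout (config.yaml, CSV/PNG/NIfTI/JSONL,
    predictor.json) so the CLI path can be exercised end-to-end."""
    import pandas as pd
    import yaml
    from PIL import Image

    fixture = make_fixture(spec)
    spec = fixture.spec  # weights filled in
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    modality_cfg = []
    for desc in fixture.descs:
        block: dict = {"name": desc.name, "kind": desc.kind,
                       "mask_strategy": desc.mask_strategy}
        if desc.kind in ("image2d", "image3d"):
            block["patch_shape"] = list(desc.patch_shape)
        if desc.kind == "tabular":
            block["feature_kinds"] = list(desc.feature_kinds)
        modality_cfg.append(block)

    if "image" in spec.modalities:
        img_dir = out / "image"
        img_dir.mkdir(exist_ok=True)
        for s in fixture.samples:
            arr = np.asarray(s.parts["image"])
            if spec.image_kind == "image2d":
                Image.fromarray(arr.astype(np.uint8), mode="L").save(
                    img_dir / f"{s.sample_id}.png"
                )
            else:
                import nibabel as nib

                nib.save(
                    nib.Nifti1Image(arr.astype(np.float32), np.eye(4)),
                    img_dir / f"{s.sample_id}.nii.gz",
                )

    if "tabular" in spec.modalities:
        frame = pd.DataFrame(
            [np.asarray(s.parts["tabular"]) for s in fixture.samples],
            columns=tabular_column_names(spec),
        )
        frame.insert(0, "sample_id", [s.sample_id for s in fixture.samples])
        # %.17g round-trips doubles exactly through the CSV
        frame.to_csv(out / "tabular.csv", index=False, float_format="%.17g")

    if "text" in spec.modalities:
        with open(out / "text.jsonl", "w") as fh:
            for s in fixture.samples:
                fh.write(
                    json.dumps(
                        {"sample_id": s.sample_id, "text": " ".join(s.parts["text"])}
                    )
                    + "\n"
                )

    (out / "predictor.json").write_text(json.dumps({"spec": spec_to_dict(spec)}, indent=2))
    config = {
        "modalities": modality_cfg,
        "predictor": {
            "import": "modcontrib.fixtures:predictor_from_json",
            "args": {"path": "predictor.json"},
        },
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return fixture
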