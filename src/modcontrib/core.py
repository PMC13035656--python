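"""Multimodal sample model, occlusion partitioning and masking.

A multimodal sample bundles one aligned observation per modality: a 2D raster
or 3D volume, a tabular row, or a tokenized free-text document.  To measure a
black-box model's reliance on each modality, every modality is split into
``h_i`` parts (image patches, single tabular attributes, single words) and
each part is occluded in turn by a replacement rule chosen to minimise domain
shift:

* ``self_mean``  — image patch replaced by the mean intensity of that same
  image (per channel for multi-channel rasters);
* ``dataset_mean`` — tabular scalar replaced by its column mean over the
  analysis dataset; a two-bit one-hot binary attribute is nulled to (0, 0);
* ``zero``       — part overwritten with zeros;
* ``onehot_null``— explicit (0, 0) replacement, valid only for two-bit
  binary attributes;
* ``remove`` / ``mask_token`` — a word is deleted, or substituted with a
  neutral token.

Masking is always copy-on-write: the source sample is never mutated.  Image
patches are enumerated in row-major order with 0-based, half-open geometry so
part indices are reproducible across runs and renderers.  When an image axis
is not divisible by the patch size the final patch along that axis is
truncated to the boundary (no padding; a warning is emitted).
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

IMAGE_KINDS = ("image2d", "image3d")
KINDS = IMAGE_KINDS + ("tabular", "text")

#: masking strategies admissible for each modality kind
STRATEGIES_BY_KIND: dict[str, tuple[str, ...]] = {
    "image2d": ("self_mean", "zero"),
    "image3d": ("self_mean", "zero"),
    "tabular": ("dataset_mean", "zero", "onehot_null"),
    "text": ("remove", "mask_token"),
}

FEATURE_KINDS = ("continuous", "binary_onehot")

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


class MaskingError(ValueError):
    """A masking request violates the descriptor contract."""


def tokenize(text: str) -> list[str]:
    """Split free text into words: strip punctuation, then whitespace-split."""
    return [w for w in text.translate(_PUNCT_TABLE).split() if w]


@dataclass(frozen=True)
class ModalityDescriptor:
    """Declares one modality: its kind, shape, partitioning and masking rule.

    Parameters
    ----------
    name : str
        Modality identifier, unique within a dataset.
    kind : {"image2d", "image3d", "tabular", "text"}
    shape : tuple of int
        Spatial dims for images (optionally with a trailing channel axis),
        total column count for tabular, empty for text.
    patch_shape : tuple of int, optional
        Occlusion patch extent per spatial axis; image kinds only.
    mask_strategy : str
        Replacement rule; must be admissible for ``kind`` (see module
        docstring).  Defaults to the field-standard rule per kind.
    feature_kinds : tuple of str, optional
        Per-attribute tag for tabular modalities: ``continuous`` occupies one
        column, ``binary_onehot`` two adjacent one-hot columns.
    mask_token : str
        Neutral token used by the ``mask_token`` strategy.
    """

    name: str
    kind: str
    shape: tuple[int, ...] = ()
    patch_shape: tuple[int, ...] | None = None
    mask_strategy: str = ""
    feature_kinds: tuple[str, ...] | None = None
    mask_token: str = "<mask>"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown modality kind {self.kind!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.patch_shape is not None:
            object.__setattr__(
                self, "patch_shape", tuple(int(p) for p in self.patch_shape)
            )
        if self.feature_kinds is not None:
            object.__setattr__(self, "feature_kinds", tuple(self.feature_kinds))

        strategy = self.mask_strategy or STRATEGIES_BY_KIND[self.kind][0]
        object.__setattr__(self, "mask_strategy", strategy)
        if strategy not in STRATEGIES_BY_KIND[self.kind]:
            raise ValueError(
                f"mask strategy {strategy!r} is not valid for kind {self.kind!r}"
            )

        if self.kind in IMAGE_KINDS:
            nd = self.spatial_ndim
            if len(self.shape) not in (nd, nd + 1):
                raise ValueError(
                    f"{self.kind} shape must have {nd} spatial dims "
                    f"(+ optional channel axis), got {self.shape}"
                )
            if self.patch_shape is None or len(self.patch_shape) != nd:
                raise ValueError(f"{self.kind} requires a {nd}-dim patch_shape")
            for extent, patch in zip(self.spatial_shape, self.patch_shape):
                if not 1 <= patch <= extent:
                    raise ValueError(
                        f"patch extent {patch} outside [1, {extent}] for {self.name}"
                    )
        elif self.kind == "tabular":
            if not self.feature_kinds:
                raise ValueError("tabular modality requires feature_kinds")
            for fk in self.feature_kinds:
                if fk not in FEATURE_KINDS:
                    raise ValueError(f"unknown feature kind {fk!r}")
            ncols = sum(2 if fk == "binary_onehot" else 1 for fk in self.feature_kinds)
            if self.shape and self.shape != (ncols,):
                raise ValueError(
                    f"tabular shape {self.shape} inconsistent with feature_kinds "
                    f"(expected ({ncols},))"
                )
            object.__setattr__(self, "shape", (ncols,))

    # -- geometry -----------------------------------------------------------

    @property
    def spatial_ndim(self) -> int:
        return {"image2d": 2, "image3d": 3}.get(self.kind, 0)

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.shape[: self.spatial_ndim]

    @property
    def n_channels(self) -> int:
        extra = self.shape[self.spatial_ndim :]
        return extra[0] if extra else 1

    @property
    def grid_shape(self) -> tuple[int, ...]:
        """Patches per spatial axis (ceil division; final patch truncated)."""
        if self.kind not in IMAGE_KINDS:
            raise ValueError(f"{self.kind} modality has no patch grid")
        return tuple(
            math.ceil(extent / patch)
            for extent, patch in zip(self.spatial_shape, self.patch_shape)
        )

    @property
    def h(self) -> int | None:
        """Partition count h_i; ``None`` for text (per-sample word count)."""
        if self.kind in IMAGE_KINDS:
            return int(np.prod(self.grid_shape))
        if self.kind == "tabular":
            return len(self.feature_kinds)
        return None

    def column_spans(self) -> list[tuple[int, int]]:
        """Half-open column span per tabular attribute, in attribute order."""
        if self.kind != "tabular":
            raise ValueError("column_spans is tabular-only")
        spans, start = [], 0
        for fk in self.feature_kinds:
            width = 2 if fk == "binary_onehot" else 1
            spans.append((start, start + width))
            start += width
        return spans


@dataclass
class MultimodalSample:
    """One subject's aligned inputs across all modalities.

    ``parts`` maps modality name to the raw value: a float array for image
    and tabular modalities, a list of word tokens for text.
    """

    sample_id: str
    parts: dict[str, object]

    def replaced(self, name: str, value: object) -> "MultimodalSample":
        """New sample with one modality's value substituted (shallow copy)."""
        parts = dict(self.parts)
        parts[name] = value
        return MultimodalSample(self.sample_id, parts)


@dataclass(frozen=True)
class DatasetStatistics:
    """Per-modality, per-column means over the N samples of the analysis set."""

    column_means: dict[str, np.ndarray]
    n_samples: int


@dataclass(frozen=True)
class PartGeometry:
    """One occludable part: an image patch slab, a column span, or a word.

    ``geometry`` is a tuple of slices (image), a half-open ``(start, stop)``
    column pair (tabular), or a word index (text).
    """

    modality: str
    index: int
    geometry: object


@dataclass(frozen=True)
class OcclusionPlan:
    """Ordered parts 0 … h_i−1 for one modality of one sample."""

    modality: str
    entries: tuple[PartGeometry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PartGeometry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> PartGeometry:
        return self.entries[i]


def validate_sample(sample: MultimodalSample, descs: Iterable[ModalityDescriptor]) -> None:
    """Check that every declared modality is present with a conforming value."""
    for desc in descs:
        if desc.name not in sample.parts:
            raise ValueError(
                f"sample {sample.sample_id!r} is missing modality {desc.name!r}"
            )
        value = sample.parts[desc.name]
        if desc.kind in IMAGE_KINDS or desc.kind == "tabular":
            arr = np.asarray(value)
            if tuple(arr.shape) != desc.shape:
                raise ValueError(
                    f"sample {sample.sample_id!r}, modality {desc.name!r}: "
                    f"shape {arr.shape} does not match descriptor {desc.shape}"
                )
        elif not all(isinstance(tok, str) for tok in value):
            raise ValueError(
                f"sample {sample.sample_id!r}: text modality {desc.name!r} "
                "must be a sequence of word tokens"
            )


def plan_partition(desc: ModalityDescriptor, sample: MultimodalSample) -> OcclusionPlan:
    """Enumerate the h_i occludable parts of one modality for one sample.

    Image parts are non-overlapping patches in row-major order (last axis
    fastest); tabular parts are singleton attributes; text parts are single
    words.  Empty text yields a zero-part plan (degenerate modality).
    """
    if desc.kind in IMAGE_KINDS:
        if any(extent % patch for extent, patch in zip(desc.spatial_shape, desc.patch_shape)):
            warnings.warn(
                f"modality {desc.name!r}: shape {desc.spatial_shape} not divisible "
                f"by patch {desc.patch_shape}; final patch truncated at the boundary",
                RuntimeWarning,
                stacklevel=2,
            )
        entries = []
        for index, cell in enumerate(np.ndindex(*desc.grid_shape)):
            slab = tuple(
                slice(c * p, min((c + 1) * p, extent))
                for c, p, extent in zip(cell, desc.patch_shape, desc.spatial_shape)
            )
            entries.append(PartGeometry(desc.name, index, slab))
        return OcclusionPlan(desc.name, tuple(entries))

    if desc.kind == "tabular":
        entries = tuple(
            PartGeometry(desc.name, i, span)
            for i, span in enumerate(desc.column_spans())
        )
        return OcclusionPlan(desc.name, entries)

    tokens = sample.parts[desc.name]
    entries = tuple(PartGeometry(desc.name, i, i) for i in range(len(tokens)))
    return OcclusionPlan(desc.name, entries)


def mask_part(
    sample: MultimodalSample,
    desc: ModalityDescriptor,
    l: int,
    stats: DatasetStatistics | None = None,
    plan: OcclusionPlan | None = None,
) -> MultimodalSample:
    """Return a new sample with part ``l`` of one modality occluded.

    Only the targeted part differs from the input; the source sample is left
    untouched.  ``stats`` is required for the ``dataset_mean`` strategy.
    """
    if plan is None:
        plan = plan_partition(desc, sample)
    if not 0 <= l < len(plan):
        raise MaskingError(
            f"part index {l} outside [0, {len(plan)}) for modality {desc.name!r}"
        )
    strategy = desc.mask_strategy
    geometry = plan[l].geometry

    if desc.kind in IMAGE_KINDS:
        arr = np.asarray(sample.parts[desc.name], dtype=float).copy()
        if strategy == "self_mean":
            # per-channel mean over the spatial axes of this same image
            fill = arr.mean(axis=tuple(range(desc.spatial_ndim)))
        else:
            fill = 0.0
        arr[geometry] = fill
        return sample.replaced(desc.name, arr)

    if desc.kind == "tabular":
        if strategy == "dataset_mean" and stats is None:
            raise MaskingError("dataset_mean masking requires DatasetStatistics")
        row = np.asarray(sample.parts[desc.name], dtype=float).copy()
        start, stop = geometry
        attr_kind = desc.feature_kinds[l]
        if strategy == "zero":
            row[start:stop] = 0.0
        elif strategy == "onehot_null":
            if attr_kind != "binary_onehot":
                raise MaskingError(
                    f"onehot_null is invalid for {attr_kind} attribute {l} "
                    f"of modality {desc.name!r}"
                )
            row[start:stop] = 0.0
        else:  # dataset_mean; binary attributes are nulled to (0, 0)
            if attr_kind == "binary_onehot":
                row[start:stop] = 0.0
            else:
                row[start:stop] = stats.column_means[desc.name][start:stop]
        return sample.replaced(desc.name, row)

    tokens = list(sample.parts[desc.name])
    if strategy == "remove":
        del tokens[geometry]
    else:
        tokens[geometry] = desc.mask_token
    return sample.replaced(desc.name, tokens)


def compute_dataset_statistics(
    dataset: Sequence[MultimodalSample],
    descs: Iterable[ModalityDescriptor],
) -> DatasetStatistics:
    """Column means per tabular modality over exactly the given samples.

    Missing (non-finite) values raise: no imputation is performed.
    """
    samples = list(dataset)
    if not samples:
        raise ValueError("dataset statistics require at least one sample")
    means: dict[str, np.ndarray] = {}
    for desc in descs:
        if desc.kind != "tabular":
            continue
        rows = np.stack(
            [np.asarray(s.parts[desc.name], dtype=float) for s in samples]
        )
        if not np.all(np.isfinite(rows)):
            bad = [s.sample_id for s, r in zip(samples, rows) if not np.all(np.isfinite(r))]
            raise ValueError(
                f"modality {desc.name!r} has missing values in samples {bad}"
            )
        means[desc.name] = rows.mean(axis=0)
    return DatasetStatistics(column_means=means, n_samples=len(samples))
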