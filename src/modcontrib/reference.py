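"""Naive triple-loop reference implementation, used as a validation oracle.

This module restates the occlusion sweep in the most literal form possible:
three nested Python loops (samples, modalities, parts) with the masking
arithmetic written inline.  It deliberately shares no code with
:mod:`modcontrib.core` or :mod:`modcontrib.engine` beyond the sample
dataclass, so that agreement between the two paths is evidence rather than
tautology.  It is slow and only meant for small instances.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import DatasetStatistics, ModalityDescriptor, MultimodalSample


def _masked_values(sample, desc, stats):
    """Yield the modality value with each part masked, one part at a time."""
    value = sample.parts[desc.name]

    if desc.kind in ("image2d", "image3d"):
        arr = np.asarray(value, dtype=float)
        nd = 2 if desc.kind == "image2d" else 3
        extents = desc.shape[:nd]
        patches = desc.patch_shape
        fill = arr.mean(axis=tuple(range(nd))) if desc.mask_strategy == "self_mean" else 0.0
        counts = [math.ceil(e / p) for e, p in zip(extents, patches)]
        if nd == 2:
            for ci in range(counts[0]):
                for cj in range(counts[1]):
                    out = arr.copy()
                    out[
                        ci * patches[0] : min((ci + 1) * patches[0], extents[0]),
                        cj * patches[1] : min((cj + 1) * patches[1], extents[1]),
                    ] = fill
                    yield out
        else:
            for ci in range(counts[0]):
                for cj in range(counts[1]):
                    for ck in range(counts[2]):
                        out = arr.copy()
                        out[
                            ci * patches[0] : min((ci + 1) * patches[0], extents[0]),
                            cj * patches[1] : min((cj + 1) * patches[1], extents[1]),
                            ck * patches[2] : min((ck + 1) * patches[2], extents[2]),
                        ] = fill
                        yield out

    elif desc.kind == "tabular":
        row = np.asarray(value, dtype=float)
        col = 0
        for kind in desc.feature_kinds:
            width = 2 if kind == "binary_onehot" else 1
            out = row.copy()
            if desc.mask_strategy == "dataset_mean" and kind == "continuous":
                out[col] = stats.column_means[desc.name][col]
            else:
                out[col : col + width] = 0.0
            col += width
            yield out

    else:  # text
        tokens = list(value)
        for i in range(len(tokens)):
            if desc.mask_strategy == "remove":
                yield tokens[:i] + tokens[i + 1 :]
            else:
                yield tokens[:i] + [desc.mask_token] + tokens[i + 1 :]


def naive_sweep(
    predictor,
    dataset: Sequence[MultimodalSample],
    descs: Sequence[ModalityDescriptor],
    stats: DatasetStatistics | None = None,
):
    """Literal restatement of the sweep: per-part summed class distances.

    Returns ``(part_sums, n_classes)`` where ``part_sums[name]`` is the
    (h, C) array of Σ_k |p_0^k − p_{i,l}^k| (h padded to the longest
    per-sample part list for variable-length text).
    """
    part_sums: dict[str, list] = {d.name: [] for d in descs}
    n_classes = None
    for sample in dataset:
        p0 = np.asarray(predictor(sample), dtype=float).ravel()
        n_classes = p0.size
        for desc in descs:
            for l, masked_value in enumerate(_masked_values(sample, desc, stats)):
                variant = MultimodalSample(
                    sample.sample_id, {**sample.parts, desc.name: masked_value}
                )
                p = np.asarray(predictor(variant), dtype=float).ravel()
                d = np.abs(p0 - p)
                sums = part_sums[desc.name]
                if l == len(sums):
                    sums.append(np.zeros(p0.size))
                sums[l] = sums[l] + d
    return (
        {
            name: (np.stack(rows) if rows else np.zeros((0, n_classes)))
            for name, rows in part_sums.items()
        },
        n_classes,
    )


def naive_contribution(predictor, dataset, descs, stats=None):
    """Modality contributions m and part importances mp via the naive sweep.

    Degenerate cases (all distances zero) yield zero vectors, mirroring the
    engine's explicit-flag convention.
    """
    part_sums, _ = naive_sweep(predictor, dataset, descs, stats)
    totals = np.array([float(part_sums[d.name].sum()) for d in descs])
    grand = totals.sum()
    m = totals / grand if grand > 0 else np.zeros_like(totals)
    mp = {}
    for d in descs:
        s = part_sums[d.name].sum(axis=1)
        tot = s.sum()
        mp[d.name] = s / tot if tot > 0 else np.zeros_like(s)
    return m, mp
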