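"""Occlusion sweep and modality-contribution metrics.

The sweep forwards each sample once unmasked, then once per (modality, part)
with that part occluded, and accumulates the per-class absolute output
differences d_{i,l}^k = |p_0^k − p_{i,l}^k| over the dataset.  From the
accumulated distances it computes

* the modality contribution  m_i = 1ᵀd_i / Σ_j 1ᵀd_j            (sums to 1),
* the within-modality part importance  mp_i^l = 1ᵀd_{i,l} / Σ_j 1ᵀd_{i,j},
* the globally weighted part contribution  mp_i^l · m_i          (sums to 1),
* per-sample contributions (the N = 1 specialisation of m_i), and
* a collapse verdict: a model whose output dynamic concentrates on a single
  modality beyond a threshold is flagged as a unimodal collapse (default
  threshold 0.95) or a tendency to collapse (default 0.90).

The method is black-box — it needs only input → output access — and
performance-agnostic: it measures output dynamics, not correctness.  When
every accumulated distance is exactly zero (a constant predictor) the report
is flagged degenerate and all contributions are zero; no uniform vector is
fabricated.  The ε guard in the normalisation denominators only matters in
that degenerate branch, so in the non-degenerate case the normalisations are
exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import (
    DatasetStatistics,
    ModalityDescriptor,
    MultimodalSample,
    mask_part,
    plan_partition,
    validate_sample,
)

#: a predictor is any callable MultimodalSample -> length-C real vector;
#: an optional ``predict_batch(list) -> (B, C)`` method enables batching.
Predictor = Callable[[MultimodalSample], np.ndarray]


class EngineError(RuntimeError):
    """Sweep aborted: predictor contract violated or inputs inconsistent."""


class DegenerateReportError(ValueError):
    """Requested quantity is undefined on an all-zero-distance report."""


@dataclass
class EngineConfig:
    """Sweep and metric configuration.

    epsilon
        Division guard in the contribution formulas (default 1e-7);
        only reached when all distances vanish, which is reported as
        degenerate instead.
    batch_size
        Masked variants per predictor call when the predictor exposes
        ``predict_batch``; results are independent of this value.
    collapse_threshold, tendency_threshold
        max_i m_i at or above which the verdict is ``collapse`` resp.
        ``tendency``.
    retain_per_sample_parts
        Keep per-sample, per-part class distance vectors (needed for
        per-sample word/patch rendering).
    """

    epsilon: float = 1e-7
    batch_size: int = 1
    collapse_threshold: float = 0.95
    tendency_threshold: float = 0.90
    retain_per_sample_parts: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.5 < self.collapse_threshold <= 1.0:
            raise ValueError("collapse_threshold must lie in (0.5, 1]")
        if not self.tendency_threshold < self.collapse_threshold:
            raise ValueError("tendency_threshold must be < collapse_threshold")

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "batch_size": self.batch_size,
            "collapse_threshold": self.collapse_threshold,
            "tendency_threshold": self.tendency_threshold,
        }


class DistanceAccumulator:
    """Running sums of per-class absolute output differences.

    Per (modality, part): Σ_k d_{i,l}^k as an (h_i, C) array (rows grow to the
    longest per-sample plan, relevant for variable-length text).  Per
    modality: the class-summed per-sample totals d_i^k.  Optionally the full
    per-sample, per-part vectors.
    """

    def __init__(self, modalities: Sequence[str], n_classes: int, retain: bool = True):
        self.modalities = list(modalities)
        self.n_classes = int(n_classes)
        self.part_class_sums: dict[str, np.ndarray] = {
            m: np.zeros((0, self.n_classes)) for m in self.modalities
        }
        self.sample_totals: dict[str, list[float]] = {m: [] for m in self.modalities}
        self.per_sample_parts: dict[str, list[np.ndarray]] | None = (
            {m: [] for m in self.modalities} if retain else None
        )
        self.sample_ids: list[str] = []

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def add_sample(self, sample_id: str, distances: Mapping[str, np.ndarray]) -> None:
        """Fold one sample's (h_k, C) distance matrices into the sums."""
        self.sample_ids.append(sample_id)
        for name in self.modalities:
            d = np.asarray(distances[name], dtype=float).reshape(-1, self.n_classes)
            sums = self.part_class_sums[name]
            if d.shape[0] > sums.shape[0]:
                grown = np.zeros((d.shape[0], self.n_classes))
                grown[: sums.shape[0]] = sums
                sums = grown
            sums[: d.shape[0]] += d
            self.part_class_sums[name] = sums
            self.sample_totals[name].append(float(d.sum()))
            if self.per_sample_parts is not None:
                self.per_sample_parts[name].append(d.copy())

    def h_of(self, name: str) -> int:
        return self.part_class_sums[name].shape[0]


def _validate_output(out: object, n_classes: int | None, sample_id: str) -> np.ndarray:
    vec = np.asarray(out, dtype=float).ravel()
    if vec.size == 0:
        raise EngineError(f"predictor returned an empty output for sample {sample_id!r}")
    if not np.all(np.isfinite(vec)):
        raise EngineError(f"predictor returned non-finite output for sample {sample_id!r}")
    if n_classes is not None and vec.size != n_classes:
        raise EngineError(
            f"predictor output length changed to {vec.size} (expected {n_classes}) "
            f"on sample {sample_id!r}"
        )
    return vec


def _predict_many(
    predictor: Predictor,
    samples: Sequence[MultimodalSample],
    n_classes: int,
    batch_size: int,
) -> np.ndarray:
    if not samples:
        return np.zeros((0, n_classes))
    outs = []
    if batch_size > 1 and hasattr(predictor, "predict_batch"):
        for i in range(0, len(samples), batch_size):
            chunk = samples[i : i + batch_size]
            batch_out = np.asarray(predictor.predict_batch(chunk), dtype=float)
            batch_out = batch_out.reshape(len(chunk), -1)
            for s, row in zip(chunk, batch_out):
                outs.append(_validate_output(row, n_classes, s.sample_id))
    else:
        for s in samples:
            outs.append(_validate_output(predictor(s), n_classes, s.sample_id))
    return np.stack(outs)


def run_sweep(
    predictor: Predictor,
    dataset: Sequence[MultimodalSample],
    descs: Sequence[ModalityDescriptor],
    stats: DatasetStatistics | None = None,
    config: EngineConfig | None = None,
) -> DistanceAccumulator:
    """Run the full occlusion sweep and accumulate output distances.

    For every sample k the unmasked output p_0^k is computed exactly once;
    every (modality, part) pair then costs exactly one masked forward pass.
    """
    config = config or EngineConfig()
    dataset = list(dataset)
    if not dataset:
        raise EngineError("occlusion sweep requires a non-empty dataset")
    descs = list(descs)

    acc: DistanceAccumulator | None = None
    for sample in dataset:
        validate_sample(sample, descs)
        p0 = _validate_output(predictor(sample), None if acc is None else acc.n_classes,
                              sample.sample_id)
        if acc is None:
            acc = DistanceAccumulator(
                [d.name for d in descs], p0.size, retain=config.retain_per_sample_parts
            )
        distances: dict[str, np.ndarray] = {}
        for desc in descs:
            plan = plan_partition(desc, sample)
            masked = [
                mask_part(sample, desc, entry.index, stats=stats, plan=plan)
                for entry in plan
            ]
            outs = _predict_many(predictor, masked, acc.n_classes, config.batch_size)
            distances[desc.name] = np.abs(outs - p0[None, :])
        acc.add_sample(sample.sample_id, distances)
    return acc


# -- metrics ----------------------------------------------------------------


def _normalize(values: np.ndarray, epsilon: float) -> tuple[np.ndarray, bool]:
    """Exact normalisation with an explicit degenerate branch."""
    total = float(values.sum())
    if total <= 0.0:
        # epsilon would guard the division here; the degenerate branch
        # reports zeros instead of fabricating a uniform vector
        return np.zeros_like(values), True
    return values / total, False


def modality_totals(acc: DistanceAccumulator) -> np.ndarray:
    """Class-summed average distance 1ᵀd_i per modality, in modality order."""
    n = max(acc.n_samples, 1)
    return np.array([acc.part_class_sums[m].sum() / n for m in acc.modalities])


def modality_contribution(
    acc: DistanceAccumulator, config: EngineConfig | None = None
) -> np.ndarray:
    """Modality contributions m_i; the zero vector when degenerate."""
    config = config or EngineConfig()
    m, _ = _normalize(modality_totals(acc), config.epsilon)
    return m


def is_degenerate(acc: DistanceAccumulator) -> bool:
    """True when every accumulated distance is exactly zero."""
    return float(modality_totals(acc).sum()) <= 0.0


def patch_importance(
    acc: DistanceAccumulator, modality: str, config: EngineConfig | None = None
) -> np.ndarray:
    """Part importances mp_i^l for one modality; zeros when that modality's
    distances all vanish (modality-degenerate)."""
    config = config or EngineConfig()
    per_part = acc.part_class_sums[modality].sum(axis=1)
    mp, _ = _normalize(per_part, config.epsilon)
    return mp


def per_sample_contribution(
    acc: DistanceAccumulator, k: int, config: EngineConfig | None = None
) -> np.ndarray:
    """Modality contribution evaluated on sample k alone (N = 1 case)."""
    config = config or EngineConfig()
    totals = np.array([acc.sample_totals[m][k] for m in acc.modalities])
    vec, _ = _normalize(totals, config.epsilon)
    return vec


def _resolve_mode(d: np.ndarray, mode: object, n_classes: int) -> np.ndarray:
    """Reduce an (h, C) class-distance matrix to per-part scores."""
    if isinstance(mode, str) and mode.startswith("class:"):
        mode = int(mode.split(":", 1)[1])
    if mode == "mean":
        return d.mean(axis=1)
    if mode == "max":
        return d.max(axis=1) if d.size else d.sum(axis=1)
    if isinstance(mode, int):
        if not 0 <= mode < n_classes:
            raise ValueError(f"class index {mode} outside [0, {n_classes})")
        return d[:, mode]
    raise ValueError(f"unknown importance mode {mode!r}")


def class_resolved_importance(
    acc: DistanceAccumulator, modality: str, mode: object = "mean"
) -> np.ndarray:
    """Per-part importance under a class reduction: ``"mean"`` over output
    components, ``"max"`` over components, or a single class index
    (``3`` or ``"class:3"``).  Normalised to sum 1 unless degenerate."""
    scores = _resolve_mode(acc.part_class_sums[modality], mode, acc.n_classes)
    vec, _ = _normalize(scores, 1e-7)
    return vec


@dataclass(frozen=True)
class Verdict:
    """Collapse diagnosis: balanced / tendency / collapse, with the dominant
    modality and its share."""

    label: str
    dominant: str | None
    dominant_share: float


def classify_collapse(
    m: np.ndarray,
    modalities: Sequence[str] | None = None,
    config: EngineConfig | None = None,
) -> Verdict:
    """Diagnose unimodal collapse from a valid (non-degenerate) m vector."""
    config = config or EngineConfig()
    m = np.asarray(m, dtype=float)
    i = int(np.argmax(m))
    share = float(m[i])
    if share >= config.collapse_threshold:
        label = "collapse"
    elif share >= config.tendency_threshold:
        label = "tendency"
    else:
        label = "balanced"
    name = modalities[i] if modalities is not None else str(i)
    return Verdict(label=label, dominant=name, dominant_share=share)


# -- report -----------------------------------------------------------------


@dataclass
class ContributionReport:
    """Final attribution report: m, mp, weighted contributions, per-sample
    contributions, retained class-resolved distances, and the verdict."""

    modalities: list[str]
    m: np.ndarray
    mp: dict[str, np.ndarray]
    weighted: dict[str, np.ndarray]
    per_sample_m: np.ndarray
    sample_ids: list[str]
    verdict: Verdict
    degenerate: bool
    degenerate_modalities: dict[str, bool]
    part_class_distances: dict[str, np.ndarray]
    per_sample_part_distances: dict[str, list[np.ndarray]] | None
    h: dict[str, int]
    n_classes: int
    n_samples: int
    output_space: str
    config: EngineConfig

    def class_scores(self, modality: str, mode: object = "mean") -> np.ndarray:
        """Per-part importance under a class reduction (see
        :func:`class_resolved_importance`), from the retained distances."""
        scores = _resolve_mode(
            self.part_class_distances[modality], mode, self.n_classes
        )
        total = scores.sum()
        return scores / total if total > 0 else np.zeros_like(scores)

    def to_dict(self) -> dict:
        doc = {
            "modalities": self.modalities,
            "m": [float(v) for v in self.m],
            "mp": {k: [float(v) for v in vec] for k, vec in self.mp.items()},
            "weighted": {k: [float(v) for v in vec] for k, vec in self.weighted.items()},
            "per_sample_m": [[float(v) for v in row] for row in self.per_sample_m],
            "sample_ids": self.sample_ids,
            "verdict": {
                "label": self.verdict.label,
                "dominant": self.verdict.dominant,
                "dominant_share": self.verdict.dominant_share,
            },
            "degenerate": self.degenerate,
            "degenerate_modalities": self.degenerate_modalities,
            "part_class_distances": {
                k: [[float(v) for v in row] for row in mat]
                for k, mat in self.part_class_distances.items()
            },
            "h": self.h,
            "n_classes": self.n_classes,
            "n_samples": self.n_samples,
            "output_space": self.output_space,
            "config": self.config.to_dict(),
        }
        if self.per_sample_part_distances is not None:
            doc["per_sample_part_distances"] = {
                k: [[[float(v) for v in row] for row in mat] for mat in per_sample]
                for k, per_sample in self.per_sample_part_distances.items()
            }
        return doc

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def csv_rows(self) -> list[dict]:
        rows = []
        for name in self.modalities:
            for l, (imp, w) in enumerate(zip(self.mp[name], self.weighted[name])):
                rows.append(
                    {"modality": name, "part": l, "mp": float(imp), "weighted": float(w)}
                )
        return rows


def overall_patch_contribution(report: ContributionReport) -> dict[str, np.ndarray]:
    """Globally weighted part contributions mp_i^l · m_i (sum to 1)."""
    if report.degenerate:
        raise DegenerateReportError(
            "weighted patch contributions are undefined for a degenerate report"
        )
    return {name: w.copy() for name, w in report.weighted.items()}


def build_report(
    acc: DistanceAccumulator,
    descs: Sequence[ModalityDescriptor] | None = None,
    config: EngineConfig | None = None,
    output_space: str = "raw",
) -> ContributionReport:
    """Assemble the full contribution report from a finalized accumulator."""
    config = config or EngineConfig()
    names = acc.modalities
    m = modality_contribution(acc, config)
    degenerate = is_degenerate(acc)
    mp = {name: patch_importance(acc, name, config) for name in names}
    degenerate_modalities = {
        name: bool(acc.part_class_sums[name].sum() <= 0.0) for name in names
    }
    weighted = {name: mp[name] * m[i] for i, name in enumerate(names)}
    per_sample_m = (
        np.stack([per_sample_contribution(acc, k, config) for k in range(acc.n_samples)])
        if acc.n_samples
        else np.zeros((0, len(names)))
    )
    n = max(acc.n_samples, 1)
    part_class_distances = {
        name: acc.part_class_sums[name] / n for name in names
    }
    per_sample_dists = None
    if acc.per_sample_parts is not None:
        per_sample_dists = {
            name: [d.copy() for d in acc.per_sample_parts[name]] for name in names
        }
    if degenerate:
        verdict = Verdict(label="degenerate", dominant=None, dominant_share=0.0)
    else:
        verdict = classify_collapse(m, names, config)
    return ContributionReport(
        modalities=list(names),
        m=m,
        mp=mp,
        weighted=weighted,
        per_sample_m=per_sample_m,
        sample_ids=list(acc.sample_ids),
        verdict=verdict,
        degenerate=degenerate,
        degenerate_modalities=degenerate_modalities,
        part_class_distances=part_class_distances,
        per_sample_part_distances=per_sample_dists,
        h={name: acc.h_of(name) for name in names},
        n_classes=acc.n_classes,
        n_samples=acc.n_samples,
        output_space=output_space,
        config=config,
    )
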