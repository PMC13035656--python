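"""Attribution renderers: patch heatmaps, word coloring, attribute bars.

All renderers read importances straight from a ContributionReport and never
alter them: rendered color ranks equal numeric ranks (blue = low, red =
high, via a diverging colormap).  Color scales use per-artifact min–max
normalisation, recorded in the render metadata.
"""

from __future__ import annotations

import html as _html
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps

from .core import ModalityDescriptor, plan_partition, MultimodalSample
from .engine import ContributionReport, _resolve_mode

DEFAULT_CMAP = "bwr"  # blue -> white -> red, low to high


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min–max normalise to [0, 1]; a constant vector maps to 0.5."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi - lo <= 0:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def scores_to_colors(scores: np.ndarray, cmap: str = DEFAULT_CMAP) -> np.ndarray:
    """RGBA color per score under per-artifact min–max scaling."""
    return colormaps[cmap](normalize_scores(scores))


def patch_score_map(
    scores: np.ndarray, desc: ModalityDescriptor, sample: MultimodalSample
) -> np.ndarray:
    """Paint per-patch scores onto the modality's spatial grid.

    Returns an array of the modality's spatial shape where every pixel/voxel
    carries its patch's (raw, unnormalised) score.
    """
    plan = plan_partition(desc, sample)
    if len(scores) != len(plan):
        raise ValueError(
            f"{len(scores)} scores for {len(plan)} patches of modality {desc.name!r}"
        )
    canvas = np.zeros(desc.spatial_shape)
    for entry, score in zip(plan, scores):
        canvas[entry.geometry] = score
    return canvas


def render_image_heatmap(
    report: ContributionReport,
    modality: str,
    sample: MultimodalSample,
    desc: ModalityDescriptor,
    out_path: str | Path | None = None,
    mode: object = "mean",
    slice_index: int | None = None,
    alpha: float = 0.5,
    cmap: str = DEFAULT_CMAP,
) -> np.ndarray:
    """Overlay per-patch importance on the source image; returns the raw
    per-pixel score map.  3D volumes are rendered as one axial slice
    (middle slice by default)."""
    scores = report.class_scores(modality, mode)
    score_map = patch_score_map(scores, desc, sample)
    image = np.asarray(sample.parts[modality], dtype=float)

    if desc.kind == "image3d":
        depth = score_map.shape[-1]
        if slice_index is None:
            slice_index = depth // 2
        if not 0 <= slice_index < depth:
            raise ValueError(f"slice {slice_index} outside [0, {depth})")
        plane = score_map[..., slice_index]
        base = image[..., slice_index]
    else:
        plane = score_map
        base = image if image.ndim == 2 else image.mean(axis=-1)

    if out_path is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(base, cmap="gray", interpolation="nearest")
        im = ax.imshow(
            normalize_scores(plane),
            cmap=cmap,
            alpha=alpha,
            vmin=0.0,
            vmax=1.0,
            interpolation="nearest",
        )
        fig.colorbar(im, ax=ax, label=f"importance ({mode}, min-max scaled)")
        ax.set_title(f"{modality}: part importance")
        ax.set_axis_off()
        fig.savefig(out_path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return score_map


def render_text_importance(
    report: ContributionReport,
    modality: str,
    sample: MultimodalSample,
    sample_index: int,
    out_path: str | Path | None = None,
    mode: object = "mean",
    cmap: str = DEFAULT_CMAP,
) -> str:
    """Color one sample's words by their occlusion importance; returns HTML.

    ``mode`` is ``"mean"`` / ``"max"`` over output components or a class
    index, resolved on the per-sample class distances retained in the
    report.
    """
    if report.per_sample_part_distances is None:
        raise ValueError("report was built without per-sample part distances")
    tokens = list(sample.parts[modality])
    dists = report.per_sample_part_distances[modality][sample_index]
    if len(tokens) != dists.shape[0]:
        raise ValueError(
            f"{len(tokens)} words but {dists.shape[0]} stored scores for "
            f"sample {sample.sample_id!r}"
        )
    scores = _resolve_mode(dists, mode, report.n_classes)
    colors = scores_to_colors(scores, cmap)

    spans = []
    for tok, score, rgba in zip(tokens, scores, colors):
        r, g, b = (int(round(255 * c)) for c in rgba[:3])
        spans.append(
            f'<span title="{score:.6g}" style="background-color: rgb({r},{g},{b}); '
            f'padding: 1px 3px; margin: 1px; border-radius: 3px;">'
            f"{_html.escape(tok)}</span>"
        )
    body = (
        f"<p><b>{_html.escape(modality)}</b> — sample {_html.escape(sample.sample_id)}, "
        f"mode {mode}: word importance, blue (low) to red (high), "
        f"min–max scaled per sample.</p>\n<p>" + " ".join(spans) + "</p>"
    )
    doc = f"<!DOCTYPE html>\n<html><body>\n{body}\n</body></html>\n"
    if out_path is not None:
        Path(out_path).write_text(doc)
    return doc


def render_tabular_importance(
    report: ContributionReport,
    modality: str,
    attribute_names: list[str] | None = None,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
    top_k: int = 3,
) -> pd.DataFrame:
    """Tabular attribute importance table (and bar chart).

    Emits both the within-modality importance ``mp`` and the globally
    weighted contribution ``weighted`` = mp·m_i per attribute; the top-k
    attributes by mp are flagged, ties broken by attribute order and
    annotated.
    """
    mp = np.asarray(report.mp[modality], dtype=float)
    weighted = np.asarray(report.weighted[modality], dtype=float)
    h = len(mp)
    if attribute_names is None:
        attribute_names = [f"attr{l}" for l in range(h)]
    if len(attribute_names) != h:
        raise ValueError(f"{len(attribute_names)} names for {h} attributes")

    # stable rank: descending mp, ties by original attribute order
    order = sorted(range(h), key=lambda l: (-mp[l], l))
    rank = np.empty(h, dtype=int)
    for r, l in enumerate(order):
        rank[l] = r
    top = rank < top_k
    cutoff = mp[order[min(top_k, h) - 1]] if h else 0.0
    tied = (mp == cutoff) & (np.sum(mp == cutoff) > 1) if h else np.zeros(0, bool)

    frame = pd.DataFrame(
        {
            "attribute": attribute_names,
            "part": np.arange(h),
            "mp": mp,
            "weighted": weighted,
            "rank": rank,
            "top": top,
            "tied": tied,
        }
    )
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    if out_png is not None:
        fig, ax = plt.subplots(figsize=(6, 0.5 * max(h, 4) + 1))
        colors = scores_to_colors(mp)
        ax.barh(np.arange(h)[::-1], mp, color=colors)
        ax.set_yticks(np.arange(h)[::-1])
        ax.set_yticklabels(attribute_names)
        ax.set_xlabel("within-modality importance mp")
        ax.set_title(f"{modality}: attribute importance (top {top_k} flagged)")
        fig.savefig(out_png, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return frame
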