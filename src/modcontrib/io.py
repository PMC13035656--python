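"""Configuration and on-disk dataset handling.

The standard layout under a data directory, declared by a YAML config:

* tabular modality ``name`` → ``name.csv`` with a header row and a required
  ``sample_id`` column; one row per sample.
* 2D image modality → ``name/<sample_id>.png`` (8/16-bit, 1 or 3 channels).
* 3D volume modality → ``name/<sample_id>.nii`` or ``.nii.gz``.
* text modality → ``name.jsonl`` with ``{"sample_id": ..., "text": ...}``
  lines, or ``name/<sample_id>.txt`` files.

The config's ``modalities`` list carries per-modality blocks
``{name, kind, patch_shape, mask_strategy, feature_kinds}``; image shapes
are inferred from the first loaded file.  ``predictor`` declares a dotted
``module:attr`` import, optionally with ``args`` (then the object is called
as a factory; path-like args resolve relative to the data directory).
"""

from __future__ import annotations

import importlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DatasetStatistics,
    ModalityDescriptor,
    MultimodalSample,
    compute_dataset_statistics,
    tokenize,
)


class ConfigError(ValueError):
    """The run configuration or data directory violates the schema."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "modalities" not in cfg:
        raise ConfigError(f"{path}: config must be a mapping with a 'modalities' list")
    for block in cfg["modalities"]:
        if "name" not in block or "kind" not in block:
            raise ConfigError(f"{path}: each modality block needs 'name' and 'kind'")
    return cfg


def _load_image2d(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img, dtype=float)


def _load_image3d(path: Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def _discover_ids(block: dict, data_dir: Path) -> list[str]:
    name, kind = block["name"], block["kind"]
    if kind == "tabular":
        frame = pd.read_csv(data_dir / f"{name}.csv", dtype={"sample_id": str})
        return list(frame["sample_id"])
    if kind in ("image2d", "image3d"):
        suffixes = (".png",) if kind == "image2d" else (".nii", ".nii.gz")
        ids = []
        for p in sorted((data_dir / name).iterdir()):
            for suf in suffixes:
                if p.name.endswith(suf):
                    ids.append(p.name[: -len(suf)])
                    break
        return ids
    jsonl = data_dir / f"{name}.jsonl"
    if jsonl.exists():
        return [json.loads(line)["sample_id"] for line in jsonl.read_text().splitlines() if line]
    return [p.stem for p in sorted((data_dir / name).glob("*.txt"))]


def load_dataset(
    config: dict | str | Path, data_dir: str | Path
) -> tuple[list[MultimodalSample], list[ModalityDescriptor], DatasetStatistics]:
    """Load all modalities for all samples and compute dataset statistics.

    Sample ids are taken from the first declared modality, sorted, and must
    be present in every other modality.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    data_dir = Path(data_dir)
    blocks = config["modalities"]

    ids = sorted(_discover_ids(blocks[0], data_dir))
    if not ids:
        raise ConfigError(f"no samples found for modality {blocks[0]['name']!r}")

    values: dict[str, dict[str, object]] = {}
    descs: list[ModalityDescriptor] = []
    for block in blocks:
        name, kind = block["name"], block["kind"]
        per_id: dict[str, object] = {}
        if kind == "tabular":
            frame = pd.read_csv(
                data_dir / f"{name}.csv",
                dtype={"sample_id": str},
                float_precision="round_trip",
            )
            frame = frame.set_index("sample_id")
            for sid in ids:
                if sid not in frame.index:
                    raise ConfigError(f"modality {name!r}: missing sample {sid!r}")
                per_id[sid] = frame.loc[sid].to_numpy(dtype=float)
            desc = ModalityDescriptor(
                name=name,
                kind=kind,
                mask_strategy=block.get("mask_strategy", ""),
                feature_kinds=tuple(block["feature_kinds"]),
            )
            if desc.shape[0] != frame.shape[1]:
                raise ConfigError(
                    f"modality {name!r}: feature_kinds imply {desc.shape[0]} columns, "
                    f"CSV has {frame.shape[1]}"
                )
        elif kind in ("image2d", "image3d"):
            loader = _load_image2d if kind == "image2d" else _load_image3d
            suffix = ".png" if kind == "image2d" else None
            for sid in ids:
                if suffix:
                    path = data_dir / name / f"{sid}{suffix}"
                else:
                    path = data_dir / name / f"{sid}.nii.gz"
                    if not path.exists():
                        path = data_dir / name / f"{sid}.nii"
                if not path.exists():
                    raise ConfigError(f"modality {name!r}: missing file for sample {sid!r}")
                per_id[sid] = loader(path)
            shape = np.asarray(per_id[ids[0]]).shape
            desc = ModalityDescriptor(
                name=name,
                kind=kind,
                shape=shape,
                patch_shape=tuple(block["patch_shape"]),
                mask_strategy=block.get("mask_strategy", ""),
            )
        elif kind == "text":
            jsonl = data_dir / f"{name}.jsonl"
            if jsonl.exists():
                for line in jsonl.read_text().splitlines():
                    if not line:
                        continue
                    doc = json.loads(line)
                    per_id[str(doc["sample_id"])] = tokenize(doc["text"])
            else:
                for sid in ids:
                    txt = data_dir / name / f"{sid}.txt"
                    if not txt.exists():
                        raise ConfigError(f"modality {name!r}: missing text for {sid!r}")
                    per_id[sid] = tokenize(txt.read_text())
            missing = [sid for sid in ids if sid not in per_id]
            if missing:
                raise ConfigError(f"modality {name!r}: missing samples {missing}")
            desc = ModalityDescriptor(
                name=name, kind=kind, mask_strategy=block.get("mask_strategy", "")
            )
        else:
            raise ConfigError(f"unknown modality kind {kind!r}")
        values[name] = per_id
        descs.append(desc)

    samples = [
        MultimodalSample(sample_id=sid, parts={name: values[name][sid] for name in values})
        for sid in ids
    ]
    stats = compute_dataset_statistics(samples, descs)
    return samples, descs, stats


def load_predictor(config: dict, data_dir: str | Path):
    """Resolve the config's predictor declaration to a callable."""
    block = config.get("predictor")
    if not block or "import" not in block:
        raise ConfigError("config must declare predictor.import as 'module:attr'")
    module_name, _, attr = block["import"].partition(":")
    if not attr:
        raise ConfigError("predictor.import must look like 'module:attr'")
    obj = getattr(importlib.import_module(module_name), attr)
    args = dict(block.get("args") or {})
    if not args:
        return obj
    data_dir = Path(data_dir)
    for key, value in args.items():
        if isinstance(value, str) and (key == "path" or key.endswith("_path")):
            candidate = data_dir / value
            if candidate.exists():
                args[key] = str(candidate)
    return obj(**args)
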