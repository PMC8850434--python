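"""Format plumbing: TIFF, CSV, JSON, YAML, and run manifests.

Conventions: single-channel grayscale TIFF (16-bit unsigned by default for
images, float32 on request), 8-bit label TIFF for masks, CSV with '.'
decimal and a header row, UTF-8 JSON for summaries and transforms, YAML
for configurations.  A multi-page TIFF is a stack with page order equal to
tile order (row-major montage).
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_label_map",
    "write_json",
    "read_yaml",
    "write_yaml",
    "write_manifest",
]

DEFAULT_LABEL_MAP = {"background": 0, "membrane": 1, "flat": 2, "dome": 3, "sphere": 4}


def _package_version() -> str:
    try:
        return version("nanomap")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def read_image(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray, dtype: str = "uint16") -> None:
    """Write a 2-D image; ``uint16`` clips/rounds, ``float32`` preserves."""
    image = np.asarray(image)
    if dtype == "uint16":
        data = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = image.astype(np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(str(path), data)


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D image or 3-D stack, got shape {arr.shape}")
    return arr.astype(float)


def write_stack(path: str | Path, stack: np.ndarray, dtype: str = "float32") -> None:
    stack = np.asarray(stack)
    if dtype == "uint16":
        data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = stack.astype(np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(str(path), data)


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D mask, got shape {arr.shape}")
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = mask.astype(np.uint8) * 255
    tifffile.imwrite(str(path), mask.astype(np.uint8))


def read_label_map(path: str | Path | None) -> dict[str, int]:
    """Label-map sidecar JSON ``{"background": 0, ...}``; defaults if absent."""
    if path is None:
        return dict(DEFAULT_LABEL_MAP)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    # accept either name->value or value->name
    if all(isinstance(v, int) for v in raw.values()):
        label_map = {str(k): int(v) for k, v in raw.items()}
    else:
        label_map = {str(v): int(k) for k, v in raw.items()}
    missing = set(DEFAULT_LABEL_MAP) - set(label_map)
    if missing:
        raise ValueError(f"label map {path} is missing entries for {sorted(missing)}")
    return label_map


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_yaml(path: str | Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_jsonable(payload), fh, sort_keys=True)


def write_manifest(out_dir: str | Path, command: str, config: dict) -> Path:
    """Echo the fully resolved run configuration next to the outputs.

    The manifest contains no timestamps so identical config + seed reruns
    are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    write_json(path, {"command": command, "version": _package_version(), "config": config})
    return path
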