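"""Shared file I/O: images, stacks, result tables, configuration.

Accepted raster formats are 8/16-bit grayscale TIFF (including multi-page)
and 8-bit grayscale PNG; colour images are rejected. Result tables are CSV
with unit-bearing headers plus a deterministic JSON provenance sidecar (tool
version, configuration hash, input checksums — no timestamps, so identical
inputs and configuration produce byte-identical outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imcore import BinaryMask, CalibratedImage, InvalidInputError, LabelMap
from .wound import ImageStack

__all__ = [
    "load_image",
    "load_stack",
    "save_mask",
    "save_labels",
    "write_results",
    "load_config",
    "config_hash",
]

log = logging.getLogger("motilityq")


def _as_grayscale(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise InvalidInputError(
            f"{path}: expected a 2-D grayscale image, got shape {arr.shape}"
        )
    return arr


def _tiff_px_size(path) -> float | None:
    """Pixel size (μm) from TIFF resolution tags, if resolvable."""
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            if num == 0:
                return None
            per_unit = num / den  # pixels per unit
            unit_um = {2: 25400.0, 3: 10000.0}.get(
                getattr(unit, "value", None) and int(unit.value), None
            )
            if unit_um is None:
                return None
            return unit_um / per_unit
    except Exception:
        return None


def load_image(path, px_size: float | None = None) -> CalibratedImage:
    """Load one grayscale TIFF/PNG frame with calibration.

    An explicit ``px_size`` always wins over embedded TIFF resolution tags
    (a conflict is logged); tags are used only when the argument is omitted.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] not in (1,):  # multi-page: take page 0
            arr = arr[0]
        tag_px = _tiff_px_size(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        tag_px = None
    else:
        raise InvalidInputError(f"{path}: unsupported image format {suffix!r}")
    arr = _as_grayscale(np.asarray(arr), path)
    if px_size is None:
        if tag_px is not None:
            log.info("%s: using pixel size %.4g um from TIFF tags", path, tag_px)
            px_size = tag_px
        else:
            px_size = 1.0
    elif tag_px is not None and not np.isclose(tag_px, px_size):
        log.warning(
            "%s: TIFF tags give %.4g um/px but configuration says %.4g; "
            "configuration wins",
            path, tag_px, px_size,
        )
    depth = 16 if arr.dtype == np.uint16 else 8
    return CalibratedImage(arr, px_size=px_size, bit_depth=depth)


def load_stack(source, px_size: float | None, time_interval: float) -> ImageStack:
    """Load a time-lapse from a multi-page TIFF or an ordered file list.

    A single path is read as a multi-page TIFF (page order = acquisition
    order); a list of paths is loaded file by file in the given order (sort
    a glob lexically before passing it). All frames must share one shape.
    """
    if isinstance(source, (str, os.PathLike)):
        import tifffile

        path = Path(source)
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise InvalidInputError(f"{path}: unreadable TIFF ({exc})") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise InvalidInputError(f"{path}: expected a grayscale stack, got {arr.shape}")
        tag_px = _tiff_px_size(path)
        if px_size is None:
            px_size = tag_px if tag_px is not None else 1.0
            if tag_px is not None:
                log.info("%s: using pixel size %.4g um from TIFF tags", path, tag_px)
        elif tag_px is not None and not np.isclose(tag_px, px_size):
            log.warning(
                "%s: TIFF tags give %.4g um/px but configuration says %.4g; "
                "configuration wins", path, tag_px, px_size,
            )
        frames = tuple(CalibratedImage(a, px_size=px_size) for a in arr)
    else:
        paths = list(source)
        if not paths:
            raise InvalidInputError("empty frame list")
        frames = tuple(load_image(p, px_size) for p in paths)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise InvalidInputError(f"frames have mixed shapes: {sorted(shapes)}")
    return ImageStack(frames=frames, time_interval=time_interval)


def save_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit TIFF (foreground 255)."""
    import tifffile

    tifffile.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def save_labels(labels: LabelMap, path) -> None:
    """Write a label map as a 16-bit TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), labels.pixels.astype(np.uint16))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_results(
    table: pd.DataFrame,
    path,
    config: dict | None = None,
    inputs: list | None = None,
    allow_empty: bool = False,
) -> None:
    """Write a result table as CSV plus a JSON provenance sidecar.

    Column order is preserved as given (deterministic); the sidecar records
    the tool version, a hash of the configuration and checksums of the input
    files. No timestamp is written, so re-running with identical inputs and
    configuration reproduces the files byte for byte.
    """
    if table.empty and not allow_empty:
        raise InvalidInputError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    sidecar = {
        "tool": "motilityq",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "config": {k: str(v) for k, v in sorted((config or {}).items())},
        "inputs": {str(p): _checksum(Path(p)) for p in (inputs or []) if Path(p).is_file()},
    }
    with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path, allowed_keys: set[str] | None = None) -> dict:
    """Load a YAML key-value configuration file; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: configuration must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise InvalidInputError(
                f"{path}: unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
    return cfg
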