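"""Transwell (Boyden chamber) migration / invasion counting.

Counts fluorescently stained nuclei (bright blobs on a dark background) in
membrane fields imaged before and after the non-migrated cells are scraped
off, and reports the percentage of migrated (or invaded) cells. Whether the
membrane carried a Matrigel coat (invasion) or not (migration) changes no
computation and is carried as metadata only.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imcore import CalibratedImage, InvalidInputError, find_maxima

__all__ = [
    "FieldCount",
    "TranswellResult",
    "CountParseError",
    "estimate_noise_sd",
    "count_nuclei",
    "import_manual_counts",
    "migration_percentage",
]


class CountParseError(ValueError):
    """A manual click-coordinate table could not be parsed."""


@dataclass(frozen=True)
class FieldCount:
    """Cell count of one microscope field, with optional peak coordinates."""

    image_id: str
    n_cells: int
    coordinates: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise InvalidInputError("n_cells must be >= 0")
        if self.coordinates is not None and len(self.coordinates) != self.n_cells:
            raise InvalidInputError("n_cells must equal the number of coordinates")


@dataclass(frozen=True)
class TranswellResult:
    """Pooled counts of one insert and the migrated/invaded percentage.

    ``inconsistent`` is set (never silently clipped) when more cells are
    counted after scraping than before.
    """

    total_count: int
    migrated_count: int
    percent: float
    inconsistent: bool = False
    mode: str = "pooled"


def estimate_noise_sd(image: CalibratedImage) -> float:
    """Robust noise SD from the median absolute deviation of the intensities."""
    px = image.pixels.astype(np.float64)
    return float(1.4826 * np.median(np.abs(px - np.median(px))))


def count_nuclei(
    image: CalibratedImage,
    noise_tolerance: float | None = None,
    image_id: str = "",
) -> FieldCount:
    """Count nuclei as prominence-filtered local maxima.

    ``noise_tolerance`` is the minimum prominence for a maximum to count as a
    nucleus; when omitted it defaults to 5× the robust noise SD estimated
    from the image's median absolute deviation. The count is monotone
    non-increasing in the tolerance.
    """
    if noise_tolerance is None:
        noise_tolerance = 5.0 * estimate_noise_sd(image)
    peaks = find_maxima(image, noise_tolerance)
    return FieldCount(image_id=image_id, n_cells=len(peaks), coordinates=tuple(peaks))


def import_manual_counts(table) -> list[FieldCount]:
    """Import externally produced click coordinates as per-field counts.

    Accepts a path, CSV text, or a DataFrame with columns (image_id, x, y);
    each row is one clicked nucleus, so a field's count is its row count.
    An empty table yields an empty list. Malformed rows raise with their
    line number.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        if isinstance(table, (str, os.PathLike)) and "\n" not in str(table) and os.path.exists(table):
            with open(table, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(table)
        if not text.strip():
            return []
        try:
            df = pd.read_csv(_io.StringIO(text))
        except Exception as exc:
            raise CountParseError(f"could not parse coordinate table: {exc}") from exc
    required = {"image_id", "x", "y"}
    cols = {c.strip().lower(): c for c in df.columns}
    if not required <= set(cols):
        missing = sorted(required - set(cols))
        raise CountParseError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []
    for col in ("x", "y"):
        vals = pd.to_numeric(df[cols[col]], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering
            raise CountParseError(
                f"malformed {col} value on line {int(bad[0]) + 2}"
            )
        df[cols[col]] = vals
    out = []
    for image_id, grp in df.groupby(cols["image_id"], sort=True):
        coords = tuple(zip(grp[cols["y"]], grp[cols["x"]]))
        out.append(FieldCount(image_id=str(image_id), n_cells=len(grp), coordinates=coords))
    return out


def migration_percentage(
    total_fields: list[FieldCount],
    migrated_fields: list[FieldCount],
    mode: str = "pooled",
) -> TranswellResult:
    """Percentage of migrated (or invaded) cells.

    ``pooled`` (default): 100 · Σ migrated / Σ total across all fields of one
    insert, appropriate when the fields tile the whole membrane.
    ``per_field``: mean of per-field percentages over position-paired fields,
    for the random-fields sampling design. A migrated count exceeding the
    total flags the result as inconsistent instead of clipping it.
    """
    if not total_fields or not migrated_fields:
        raise InvalidInputError("both field groups must be non-empty")
    total = sum(f.n_cells for f in total_fields)
    migrated = sum(f.n_cells for f in migrated_fields)
    if total == 0:
        raise InvalidInputError("total count is zero; percentage undefined")
    if mode == "pooled":
        percent = 100.0 * migrated / total
    elif mode == "per_field":
        if len(total_fields) != len(migrated_fields):
            raise InvalidInputError("per_field mode requires paired field lists")
        percents = []
        for ft, fm in zip(total_fields, migrated_fields):
            if ft.n_cells == 0:
                raise InvalidInputError(
                    f"field {ft.image_id!r} has zero total cells; "
                    "per-field percentage undefined"
                )
            percents.append(100.0 * fm.n_cells / ft.n_cells)
        percent = float(np.mean(percents))
    else:
        raise InvalidInputError("mode must be 'pooled' or 'per_field'")
    return TranswellResult(
        total_count=total,
        migrated_count=migrated,
        percent=percent,
        inconsistent=migrated > total,
        mode=mode,
    )
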