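"""Cell-spreading classification from phase-contrast images.

Classifies fixed cells as *unspread* (round, refringent — bright in phase
contrast) versus *spread* (flattened, darker, with visible cytoplasm) by two
parallel thresholding branches over the same background-subtracted image:

* **unspread branch** — Yen threshold keeps only the brightest regions (the
  refringent round cells), then binary polishing, watershed splitting of
  touching cells, and a particle count with a minimum-size filter.
* **total branch** — edge detection highlights every cell outline, the less
  restrictive Triangle threshold keeps the high-gradient class, hole filling
  turns outlines into solid cells, then the same watershed + particle count.

Spread cells are inferred as total − unspread; the headline readout is the
percentage of spread cells. The display-polarity inversions of the original
interactive workflow are expressed here as explicit keep-above/below class
choices, so no global inversion state exists. Cells touching the image
border are counted by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imcore import (
    CalibratedImage,
    InvalidInputError,
    MotilityWarning,
    NoThresholdError,
    analyze_particles,
    auto_threshold,
    binary_polish,
    edge_magnitude,
    rolling_ball_subtract,
    threshold_mask,
    to_8bit,
    watershed_split,
)

__all__ = ["SpreadingConfig", "SpreadingResult", "count_unspread", "count_all",
           "spreading_result"]


@dataclass(frozen=True)
class SpreadingConfig:
    """Tunable parameters of the two counting branches.

    Defaults follow the reference workflow: a 10 px rolling ball, a 100 px²
    minimum particle size, one erode + one dilate + a hole fill per branch
    (order as each branch lists it).
    """

    rolling_ball_radius: float = 10.0
    min_particle_area: float = 100.0
    unspread_polish: tuple[str, ...] = ("erode", "dilate", "fill_holes")
    total_polish: tuple[str, ...] = ("fill_holes", "erode", "dilate")
    unspread_method: str = "yen"
    total_method: str = "triangle"
    watershed_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.rolling_ball_radius <= 0:
            raise InvalidInputError("rolling_ball_radius must be > 0")
        if self.min_particle_area < 0:
            raise InvalidInputError("min_particle_area must be >= 0")


@dataclass(frozen=True)
class SpreadingResult:
    """Counts of one image: unspread, total, inferred spread and its percent.

    An unspread count exceeding the total is flagged inconsistent; the spread
    count is floored at zero with a warning rather than reported negative.
    """

    n_unspread: int
    n_total: int
    inconsistent: bool = False

    @property
    def n_spread(self) -> int:
        return max(self.n_total - self.n_unspread, 0)

    @property
    def percent_spread(self) -> float:
        return 100.0 * self.n_spread / self.n_total


def _background_subtracted(image: CalibratedImage, cfg: SpreadingConfig) -> CalibratedImage:
    return rolling_ball_subtract(to_8bit(image), cfg.rolling_ball_radius)


def _count(pre: CalibratedImage, cfg: SpreadingConfig, method: str,
           polish: tuple[str, ...]) -> int:
    try:
        img8 = to_8bit(pre)
        level = auto_threshold(img8, method)
    except NoThresholdError as exc:
        warnings.warn(f"blank image: {exc}; count is 0", MotilityWarning, stacklevel=3)
        return 0
    mask = threshold_mask(img8, level, keep="above")
    mask = binary_polish(mask, polish)
    labels = watershed_split(mask, merge_tolerance=cfg.watershed_tolerance)
    return len(analyze_particles(labels, cfg.min_particle_area))


def count_unspread(image: CalibratedImage, cfg: SpreadingConfig | None = None) -> int:
    """Count round refringent (unspread) cells.

    Chain: 8-bit → rolling-ball background subtraction → Yen threshold,
    keeping the brightest class → polish (erode, dilate, fill holes) →
    watershed split → particles >= the minimum size.
    """
    cfg = cfg or SpreadingConfig()
    pre = _background_subtracted(image, cfg)
    return _count(pre, cfg, cfg.unspread_method, cfg.unspread_polish)


def count_all(image: CalibratedImage, cfg: SpreadingConfig | None = None) -> int:
    """Count all cells regardless of phenotype.

    Chain: 8-bit → rolling-ball background subtraction → edge magnitude →
    8-bit → Triangle threshold, keeping the high-gradient class → polish
    (fill holes, erode, dilate) → watershed split → particles >= the
    minimum size. Both branches start from the same background-subtracted
    image.
    """
    cfg = cfg or SpreadingConfig()
    pre = _background_subtracted(image, cfg)
    edges = edge_magnitude(pre)
    return _count(edges, cfg, cfg.total_method, cfg.total_polish)


def spreading_result(image: CalibratedImage, cfg: SpreadingConfig | None = None) -> SpreadingResult:
    """Run both branches and combine them into a spreading readout.

    percent_spread = 100 · (total − unspread) / total. A zero total count is
    an error; unspread > total is flagged and the spread count floored at 0.
    """
    cfg = cfg or SpreadingConfig()
    n_unspread = count_unspread(image, cfg)
    n_total = count_all(image, cfg)
    if n_total == 0:
        raise InvalidInputError("no cells detected; percentage undefined")
    inconsistent = n_unspread > n_total
    if inconsistent:
        warnings.warn(
            f"unspread count ({n_unspread}) exceeds total ({n_total}); "
            "spread count floored at 0",
            MotilityWarning,
            stacklevel=2,
        )
    return SpreadingResult(n_unspread=n_unspread, n_total=n_total,
                           inconsistent=inconsistent)
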