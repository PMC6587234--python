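"""ImageJ-style raster primitives used by all quantification pipelines.

This module re-implements, with explicit contracts, the small set of image
operations that the assay pipelines are built from: 8-bit conversion, Sobel
edge magnitude, Gaussian blur, automatic histogram thresholding (Minimum,
Yen and Triangle, plus a delegated roster of further methods), binary
morphology, rolling-ball background subtraction, prominence-based maxima
detection, distance-transform watershed splitting, and particle analysis.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; row increases downward.
* Auto-thresholds operate on the 256-bin histogram of the min–max-rescaled
  (8-bit) image; :func:`auto_threshold` enforces this internally, so the
  returned level always refers to the scale of :func:`to_8bit` output.
* Binary images use 8-connectivity for component labeling and 4-connectivity
  for the background of hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "LabelMap",
    "Peak",
    "Particle",
    "InvalidInputError",
    "NoThresholdError",
    "MotilityWarning",
    "to_8bit",
    "histogram256",
    "edge_magnitude",
    "gaussian_blur",
    "auto_threshold",
    "threshold_mask",
    "open_mask",
    "binary_polish",
    "rolling_ball_subtract",
    "find_maxima",
    "watershed_split",
    "analyze_particles",
    "THRESHOLD_METHODS",
]


class InvalidInputError(ValueError):
    """An argument violates an operation's precondition."""


class NoThresholdError(ValueError):
    """The histogram admits no threshold (constant image, or no bimodality)."""


class MotilityWarning(UserWarning):
    """Non-fatal analysis condition (e.g. a frame that failed segmentation)."""


_S8 = np.ones((3, 3), bool)  # 8-connected structuring element


@dataclass
class CalibratedImage:
    """A 2-D grayscale raster with spatial calibration.

    Parameters
    ----------
    pixels : ndarray
        Rectangular, non-empty 2-D array of nonnegative intensities.
    px_size : float
        Micrometres per pixel; must be finite and > 0.
    bit_depth : int, optional
        Source bit-depth tag (8 or 16 for file input; None for derived data).
    """

    pixels: np.ndarray
    px_size: float = 1.0
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("image must be a non-empty 2-D raster")
        if not np.isfinite(self.px_size) or self.px_size <= 0:
            raise InvalidInputError("px_size must be finite and > 0")
        if np.issubdtype(px.dtype, np.floating) and not np.all(np.isfinite(px)):
            raise InvalidInputError("image intensities must be finite")
        if px.min() < 0:
            raise InvalidInputError("image intensities must be nonnegative")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A boolean raster sharing the source image's shape and calibration."""

    pixels: np.ndarray
    px_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("mask must be a non-empty 2-D raster")
        if px.dtype != bool:
            px = px.astype(bool)
        if not np.isfinite(self.px_size) or self.px_size <= 0:
            raise InvalidInputError("px_size must be finite and > 0")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.px_size**2


@dataclass
class LabelMap:
    """Integer raster: 0 = background, k > 0 = region k (contiguous 1..K)."""

    pixels: np.ndarray
    px_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("label map must be a non-empty 2-D raster")
        if not np.issubdtype(px.dtype, np.integer):
            raise InvalidInputError("label map must hold integers")
        self.pixels = px

    @property
    def n_labels(self) -> int:
        return int(self.pixels.max())


@dataclass(frozen=True)
class Peak:
    """A local intensity maximum.

    ``row``/``col`` are the centroid of the maximal plateau (floats; integers
    for single-pixel maxima). ``prominence`` is the intensity drop from the
    peak to the highest saddle connecting it to higher (or dominating
    equal-height) terrain; the global maximum's prominence is its height above
    the image minimum.
    """

    row: float
    col: float
    height: float
    prominence: float


@dataclass(frozen=True)
class Particle:
    """A connected region measured by :func:`analyze_particles`."""

    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]


# ---------------------------------------------------------------------------
# intensity operations
# ---------------------------------------------------------------------------

def to_8bit(image: CalibratedImage) -> CalibratedImage:
    """Linear min–max rescale of the intensity range to integers in [0, 255].

    A constant image maps to all zeros (degenerate min = max case). Applying
    the operation twice equals applying it once: the output always spans
    exactly [0, 255] for non-constant input. Rounding is half-up, matching
    ImageJ's ``(int)(v + 0.5)``.
    """
    px = image.pixels.astype(np.float64)
    lo = px.min()
    hi = px.max()
    if hi == lo:
        out = np.zeros(px.shape, np.uint8)
    else:
        out = np.floor((px - lo) * (255.0 / (hi - lo)) + 0.5).astype(np.uint8)
    return CalibratedImage(out, image.px_size, bit_depth=8)


def histogram256(image: CalibratedImage) -> np.ndarray:
    """256-bin histogram of the min–max-rescaled image (bin i = 8-bit level i)."""
    img8 = image if image.pixels.dtype == np.uint8 else to_8bit(image)
    return np.bincount(img8.pixels.ravel(), minlength=256).astype(np.int64)


def edge_magnitude(image: CalibratedImage) -> CalibratedImage:
    """Sobel gradient magnitude, ImageJ "Find Edges" style.

    Per-pixel sqrt(Gx² + Gy²) from the unnormalised 3×3 Sobel kernels, with
    replicated borders. Requires an image of at least 3×3 pixels.
    """
    px = image.pixels.astype(np.float64)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise InvalidInputError("edge_magnitude requires an image of at least 3x3")
    kx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
    gx = ndi.convolve(px, kx, mode="nearest")
    gy = ndi.convolve(px, kx.T, mode="nearest")
    return CalibratedImage(np.hypot(gx, gy), image.px_size)


def gaussian_blur(image: CalibratedImage, sigma: float) -> CalibratedImage:
    """Separable Gaussian convolution with replicated borders; sigma 0 = identity."""
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    px = image.pixels.astype(np.float64)
    if sigma == 0:
        return CalibratedImage(px.copy(), image.px_size)
    out = ndi.gaussian_filter(px, sigma, mode="nearest")
    return CalibratedImage(out, image.px_size)


# ---------------------------------------------------------------------------
# automatic thresholding
# ---------------------------------------------------------------------------

_MINIMUM_MAX_ITER = 10_000  # historical ImageJ cap on smoothing passes


def _hist_local_maxima(hist: np.ndarray) -> list[int]:
    """Indices of local maxima of a 1-D histogram (plateau: first bin counts)."""
    maxima: list[int] = []
    direction = 1
    for i in range(hist.shape[0] - 1):
        if direction > 0:
            if hist[i + 1] < hist[i]:
                direction = -1
                maxima.append(i)
        else:
            if hist[i + 1] > hist[i]:
                direction = 1
    return maxima


def _threshold_minimum(counts: np.ndarray) -> int:
    h = counts.astype(np.float64)
    kernel = np.full(3, 1.0 / 3.0)
    for _ in range(_MINIMUM_MAX_ITER + 1):
        maxima = _hist_local_maxima(h)
        if len(maxima) == 2:
            lo, hi = maxima
            return lo + int(np.argmin(h[lo : hi + 1]))
        h = np.convolve(h, kernel, mode="same")
    raise NoThresholdError(
        "minimum method: histogram did not become bimodal within "
        f"{_MINIMUM_MAX_ITER} smoothing passes"
    )


def _threshold_yen(counts: np.ndarray) -> int:
    # direct per-candidate class sums: immune to the catastrophic cancellation
    # a reversed cumulative sum suffers in the near-degenerate tails
    p = counts.astype(np.float64) / counts.sum()
    psq = p * p
    best_t, best_val = 0, -np.inf
    for t in range(256):
        p1 = p[: t + 1].sum()
        if p1 <= 0.0 or p1 >= 1.0:
            continue
        s1 = psq[: t + 1].sum()
        s2 = psq[t + 1 :].sum()
        if s1 <= 0.0 or s2 <= 0.0:
            continue
        val = 2.0 * np.log(p1 * (1.0 - p1)) - np.log(s1 * s2)
        if val > best_val:
            best_val, best_t = val, t
    return best_t


def _threshold_triangle(counts: np.ndarray) -> int:
    h = counts.astype(np.float64)
    nz = np.flatnonzero(h)
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(h))
    # chord runs from the histogram peak to the end of the longer tail
    if last - peak >= peak - first:
        x1, x2 = peak, last
    else:
        x1, x2 = peak, first
    y1, y2 = h[x1], h[x2]
    lo, hi = (x1, x2) if x1 < x2 else (x2, x1)
    xs = np.arange(lo + 1, hi)
    if xs.size == 0:
        return lo
    # perpendicular distance of (x, h[x]) from the chord
    d = np.abs((y2 - y1) * xs - (x2 - x1) * h[xs] + x2 * y1 - y2 * x1)
    return int(xs[int(np.argmax(d))])


def _skimage_threshold(name: str, img8: np.ndarray) -> int:
    from skimage import filters

    fns = {
        "otsu": filters.threshold_otsu,
        "isodata": filters.threshold_isodata,
        "li": filters.threshold_li,
        "mean": filters.threshold_mean,
    }
    return int(fns[name](img8))


THRESHOLD_METHODS = ("minimum", "yen", "triangle", "otsu", "isodata", "li", "mean")


def auto_threshold(image: CalibratedImage, method: str = "minimum") -> int:
    """Automatic histogram threshold; returns a cut level in [0, 255].

    The level splits the min–max-rescaled 8-bit data into the two classes
    ``{<= t}`` and ``{> t}``, both non-empty for non-constant input. The
    ``minimum`` method iteratively smooths the 256-bin histogram with a 3-bin
    moving average until exactly two local maxima remain and returns the bin
    of the minimum between them; ``yen`` maximises Yen's entropic-correlation
    criterion; ``triangle`` maximises the distance from the histogram to the
    peak–tail chord. Further methods are delegated to scikit-image.

    Raises
    ------
    NoThresholdError
        For a constant image, or when the minimum method exceeds its
        smoothing-iteration cap without reaching bimodality.
    """
    if method not in THRESHOLD_METHODS:
        raise InvalidInputError(f"unknown threshold method {method!r}")
    img8 = to_8bit(image)
    counts = histogram256(img8)
    nz = np.flatnonzero(counts)
    if nz.size <= 1:
        raise NoThresholdError("constant image admits no threshold")
    if method == "minimum":
        t = _threshold_minimum(counts)
    elif method == "yen":
        t = _threshold_yen(counts)
    elif method == "triangle":
        t = _threshold_triangle(counts)
    else:
        t = _skimage_threshold(method, img8.pixels)
    # guarantee both classes non-empty
    return int(np.clip(t, nz[0], nz[-1] - 1))


def threshold_mask(image: CalibratedImage, level: int, keep: str = "below") -> BinaryMask:
    """Binarise an 8-bit image at ``level``: keep ``{<= level}`` or ``{> level}``."""
    if image.pixels.dtype != np.uint8:
        raise InvalidInputError(
            "threshold_mask expects 8-bit data; convert with to_8bit first"
        )
    if not 0 <= int(level) <= 255:
        raise InvalidInputError("level must lie in [0, 255]")
    if keep == "below":
        m = image.pixels <= level
    elif keep == "above":
        m = image.pixels > level
    else:
        raise InvalidInputError("keep must be 'below' or 'above'")
    return BinaryMask(m, image.px_size)


# ---------------------------------------------------------------------------
# binary morphology
# ---------------------------------------------------------------------------

def open_mask(mask: BinaryMask, radius: float) -> BinaryMask:
    """Morphological opening with an exact Euclidean disk of the given radius.

    Erosion keeps a pixel iff no background pixel lies within distance
    ``radius`` of it (outside-image pixels count as foreground — replicate
    convention); dilation is the dual. Implemented via distance transforms,
    which is exact disk morphology. Removes every connected component that
    contains no disk of the given radius. ``radius`` 0 is the identity.
    """
    if radius < 0:
        raise InvalidInputError("radius must be >= 0")
    m = mask.pixels
    if radius == 0 or not m.any() or m.all():
        return BinaryMask(m.copy(), mask.px_size)
    eroded = ndi.distance_transform_edt(m) > radius
    if not eroded.any():
        return BinaryMask(np.zeros_like(m), mask.px_size)
    opened = ndi.distance_transform_edt(~eroded) <= radius
    return BinaryMask(opened, mask.px_size)


_POLISH_OPS = ("erode", "dilate", "fill_holes")


def binary_polish(mask: BinaryMask, steps: list[str] | tuple[str, ...]) -> BinaryMask:
    """Apply ``erode``/``dilate``/``fill_holes`` steps in order.

    Erode and dilate use a 3×3 square structuring element per application
    (the image border is treated as replicated, so a full mask stays full);
    ``fill_holes`` fills background regions not 4-connected to the border.
    An empty step list is the identity.
    """
    out = mask.pixels.copy()
    for step in steps:
        if step == "erode":
            out = ndi.binary_erosion(out, structure=_S8, border_value=1)
        elif step == "dilate":
            out = ndi.binary_dilation(out, structure=_S8, border_value=0)
        elif step == "fill_holes":
            out = ndi.binary_fill_holes(out)
        else:
            raise InvalidInputError(
                f"unknown polish step {step!r}; expected one of {_POLISH_OPS}"
            )
    return BinaryMask(out, mask.px_size)


# ---------------------------------------------------------------------------
# rolling-ball background subtraction
# ---------------------------------------------------------------------------

def _ball_structure(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= radius**2
    heights = np.zeros_like(d2, dtype=np.float64)
    heights[footprint] = np.sqrt(radius**2 - d2[footprint])
    return footprint, heights


def rolling_ball_subtract(image: CalibratedImage, radius: float) -> CalibratedImage:
    """Subtract a rolling-ball background estimate.

    The background is the grayscale opening of the image with a non-flat
    ball-shaped structuring element of the given radius (the classic
    rolling-ball construction: a sphere slid beneath the intensity surface).
    The result is clipped at zero; a constant image maps to zeros. Bright
    features narrower than the ball are preserved with their amplitude.
    """
    if radius <= 0:
        raise InvalidInputError("radius must be > 0")
    px = image.pixels.astype(np.float64)
    footprint, heights = _ball_structure(radius)
    eroded = ndi.grey_erosion(px, footprint=footprint, structure=heights, mode="nearest")
    background = ndi.grey_dilation(
        eroded, footprint=footprint, structure=heights, mode="nearest"
    )
    return CalibratedImage(np.clip(px - background, 0.0, None), image.px_size)


# ---------------------------------------------------------------------------
# prominence-based maxima
# ---------------------------------------------------------------------------

def _prominence_components(
    px: np.ndarray, tol: float
) -> list[tuple[float, float, float, float, bool, int, int]]:
    """Flood-based prominence analysis.

    Returns records ``(row, col, height, prominence, touches_edge, rep_r,
    rep_c)`` for every maximum with prominence >= ``tol``. ``row/col`` is the
    centroid of the birth plateau; ``rep_r/rep_c`` is its first pixel in
    row-major order (always on the plateau). Ties between equal-height peaks
    are broken toward the smaller (row, col) centroid, which survives.

    The algorithm processes intensity levels in descending order, labels each
    level's pixels (8-connectivity), and merges components with a union-find;
    a component born above the current level that merges into a dominating
    component dies with prominence ``height - level``. Components alive at the
    end take prominence ``height - min``.
    """
    H, W = px.shape
    vmin = px.min()
    levels = np.unique(px)[::-1]
    regmap = np.zeros((H, W), np.int64)  # 0 = inactive, else 1-based comp id
    parent = [0]
    height = [0.0]
    sum_r = [0.0]
    sum_c = [0.0]
    n_plat = [0]
    rep = [(0, 0)]
    on_edge = [False]

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    results: list[tuple[float, float, float, float, bool, int, int]] = []

    def record(root: int, prom: float) -> None:
        if prom >= tol:
            results.append(
                (
                    sum_r[root] / n_plat[root],
                    sum_c[root] / n_plat[root],
                    height[root],
                    prom,
                    on_edge[root],
                    rep[root][0],
                    rep[root][1],
                )
            )

    def dominates(a: int, b: int) -> bool:
        # does root a dominate root b (a survives a tie)?
        pa = (sum_r[a] / n_plat[a], sum_c[a] / n_plat[a])
        pb = (sum_r[b] / n_plat[b], sum_c[b] / n_plat[b])
        return pa < pb

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    for v in levels:
        newmask = px == v
        lab, k = ndi.label(newmask, structure=_S8)
        rr, cc = np.nonzero(newmask)
        lpix = lab[rr, cc]
        start = len(parent)
        sums_r = np.bincount(lpix, weights=rr, minlength=k + 1)
        sums_c = np.bincount(lpix, weights=cc, minlength=k + 1)
        cnts = np.bincount(lpix, minlength=k + 1)
        border = (rr == 0) | (rr == H - 1) | (cc == 0) | (cc == W - 1)
        edge_hits = np.bincount(lpix[border], minlength=k + 1) > 0
        # first row-major pixel per label = plateau representative
        _, first_idx = np.unique(lpix, return_index=True)
        rep_of = {}
        for lbl, fi in zip(np.unique(lpix), first_idx):
            rep_of[int(lbl)] = (int(rr[fi]), int(cc[fi]))
        for j in range(1, k + 1):
            parent.append(start + j - 1)
            height.append(float(v))
            sum_r.append(float(sums_r[j]))
            sum_c.append(float(sums_c[j]))
            n_plat.append(int(cnts[j]))
            rep.append(rep_of[j])
            on_edge.append(bool(edge_hits[j]))
        gids = start - 1 + lpix
        regmap[rr, cc] = gids
        # collect unique adjacency pairs (own component, active neighbour)
        owns: list[np.ndarray] = []
        nbs: list[np.ndarray] = []
        for dr, dc in offsets:
            r2 = rr + dr
            c2 = cc + dc
            ok = (r2 >= 0) & (r2 < H) & (c2 >= 0) & (c2 < W)
            nb = regmap[r2[ok], c2[ok]]
            own = gids[ok]
            m = (nb > 0) & (nb != own)
            if m.any():
                owns.append(own[m])
                nbs.append(nb[m])
        if not owns:
            continue
        pairs = np.unique(
            np.stack([np.concatenate(owns), np.concatenate(nbs)], axis=1), axis=0
        )
        for a, b in pairs:
            ra, rb = find(int(a)), find(int(b))
            if ra == rb:
                continue
            ha, hb = height[ra], height[rb]
            if (hb > ha) or (hb == ha and dominates(rb, ra)):
                ra, rb = rb, ra
                ha, hb = hb, ha
            # ra dominates; rb is absorbed
            if hb == v:
                if ha == v:  # same-level plateau pieces: pool the accumulator
                    sum_r[ra] += sum_r[rb]
                    sum_c[ra] += sum_c[rb]
                    n_plat[ra] += n_plat[rb]
                    on_edge[ra] = on_edge[ra] or on_edge[rb]
                # else: shoulder of higher terrain, never a peak
            else:
                record(rb, hb - v)
            parent[rb] = ra

    roots = {find(i) for i in range(1, len(parent))}
    for r in roots:
        if height[r] > vmin:
            record(r, height[r] - vmin)
    return results


def find_maxima(
    image: CalibratedImage, noise_tolerance: float, exclude_edges: bool = False
) -> list[Peak]:
    """All local maxima with prominence >= ``noise_tolerance``.

    The prominence of a maximum is the intensity drop from its height to the
    highest saddle connecting it to a higher (or dominating equal-height)
    region; the image's dominant maximum takes its height above the image
    minimum. A plateau reports one peak at the plateau centroid. Peaks are
    sorted by descending height with a row-major tie-break. A constant image
    yields an empty list. With ``exclude_edges`` set, maxima whose summit
    plateau touches the image border are dropped (off by default, matching
    ImageJ's Find Maxima default).
    """
    if noise_tolerance < 0:
        raise InvalidInputError("noise_tolerance must be >= 0")
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.max() == px.min():
        return []
    recs = _prominence_components(px, float(noise_tolerance))
    if exclude_edges:
        recs = [r for r in recs if not r[4]]
    recs.sort(key=lambda r: (-r[2], r[0], r[1]))
    return [Peak(row=r[0], col=r[1], height=r[2], prominence=r[3]) for r in recs]


# ---------------------------------------------------------------------------
# watershed splitting and particle analysis
# ---------------------------------------------------------------------------

def watershed_split(mask: BinaryMask, merge_tolerance: float = 0.5) -> LabelMap:
    """Split touching convex blobs by a distance-transform watershed.

    Markers are the maxima of the Euclidean distance map (quantised to
    half-pixel levels) with prominence >= ``merge_tolerance``; shallower
    maxima are merged into their neighbours, which suppresses spurious splits
    from boundary raggedness while still separating genuinely overlapping
    blobs. Disconnected input components are never merged, and the output
    label count is at least the input component count. Labels are contiguous
    1..K; an empty mask yields zero labels.
    """
    m = mask.pixels
    out = np.zeros(m.shape, np.int32)
    if not m.any():
        return LabelMap(out, mask.px_size)
    dist = ndi.distance_transform_edt(m)
    quantised = np.round(dist / 0.5) * 0.5
    recs = _prominence_components(quantised, float(merge_tolerance))
    markers = np.zeros(m.shape, np.int32)
    recs.sort(key=lambda r: (-r[2], r[0], r[1]))
    for i, r in enumerate(recs, start=1):
        markers[r[5], r[6]] = i
    from skimage.segmentation import watershed

    labels = watershed(-dist, markers, mask=m, connectivity=2)
    # safety: a foreground component with no marker keeps its own label
    orphan = m & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan, structure=_S8)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    # relabel to a contiguous 1..K range
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return LabelMap(remap[labels], mask.px_size)


def analyze_particles(labels: LabelMap, min_area_px: float = 0) -> list[Particle]:
    """One :class:`Particle` per label with area >= ``min_area_px``.

    Areas are exact pixel counts; centroids are per-label coordinate means.
    With ``min_area_px`` 0, the reported areas sum to the foreground pixel
    count.
    """
    if min_area_px < 0:
        raise InvalidInputError("min_area_px must be >= 0")
    lab = labels.pixels
    n = int(lab.max())
    if n == 0:
        return []
    areas = np.bincount(lab.ravel(), minlength=n + 1)
    rr, cc = np.nonzero(lab)
    vals = lab[rr, cc]
    sums_r = np.bincount(vals, weights=rr, minlength=n + 1)
    sums_c = np.bincount(vals, weights=cc, minlength=n + 1)
    out = []
    for k in range(1, n + 1):
        if areas[k] == 0 or areas[k] < min_area_px:
            continue
        out.append(
            Particle(
                label=k,
                area_px=int(areas[k]),
                area_um2=float(areas[k]) * labels.px_size**2,
                centroid=(sums_r[k] / areas[k], sums_c[k] / areas[k]),
            )
        )
    return out
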