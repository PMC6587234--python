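"""Independent brute-force reference implementations used only by tests.

Each function here re-derives an operation's expected output from first
principles (explicit loops, exhaustive search, level-set enumeration),
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

_S8 = np.ones((3, 3), bool)


# ---------------------------------------------------------------------------
# convolution / filtering references
# ---------------------------------------------------------------------------

def conv3x3_replicate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 3x3 convolution with replicated borders, pixel by pixel."""
    padded = np.pad(img.astype(float), 1, mode="edge")
    out = np.zeros_like(img, dtype=float)
    kf = np.flipud(np.fliplr(kernel)).astype(float)  # convolution, not correlation
    H, W = img.shape
    for r in range(H):
        for c in range(W):
            out[r, c] = float(np.sum(padded[r : r + 3, c : c + 3] * kf))
    return out


def sobel_magnitude_ref(img: np.ndarray) -> np.ndarray:
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    gx = conv3x3_replicate(img, kx)
    gy = conv3x3_replicate(img, kx.T)
    return np.hypot(gx, gy)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Truncated (4 sigma) discrete Gaussian, normalised to unit sum."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


# ---------------------------------------------------------------------------
# binary disk opening reference
# ---------------------------------------------------------------------------

def _disk_offsets(radius: float) -> list[tuple[int, int]]:
    r = int(np.ceil(radius))
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def disk_opening_ref(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erosion then dilation by an explicit Euclidean disk.

    Outside-image pixels count as foreground for the erosion (replicate
    convention) and are ignored by the dilation.
    """
    offsets = _disk_offsets(radius)
    H, W = mask.shape
    eroded = np.zeros_like(mask, dtype=bool)
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            ok = True
            for dy, dx in offsets:
                rr, cc = r + dy, c + dx
                if 0 <= rr < H and 0 <= cc < W and not mask[rr, cc]:
                    ok = False
                    break
            eroded[r, c] = ok
    opened = np.zeros_like(mask, dtype=bool)
    for r in range(H):
        for c in range(W):
            for dy, dx in offsets:
                rr, cc = r + dy, c + dx
                if 0 <= rr < H and 0 <= cc < W and eroded[rr, cc]:
                    opened[r, c] = True
                    break
    return opened


# ---------------------------------------------------------------------------
# grayscale rolling-ball reference
# ---------------------------------------------------------------------------

def rolling_ball_background_ref(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with an explicit ball structuring element."""
    r = int(np.ceil(radius))
    offsets = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offsets.append((dy, dx, float(np.sqrt(radius * radius - d2))))
    H, W = img.shape
    padded = np.pad(img.astype(float), r, mode="edge")
    eroded = np.zeros((H, W))
    for row in range(H):
        for c in range(W):
            eroded[row, c] = min(
                padded[row + r + dy, c + r + dx] - h for dy, dx, h in offsets
            )
    padded_e = np.pad(eroded, r, mode="edge")
    dilated = np.zeros((H, W))
    for row in range(H):
        for c in range(W):
            dilated[row, c] = max(
                padded_e[row + r + dy, c + r + dx] + h for dy, dx, h in offsets
            )
    return dilated


# ---------------------------------------------------------------------------
# threshold references (exhaustive, independent codings)
# ---------------------------------------------------------------------------

def _count_hist_maxima(h: np.ndarray) -> list[int]:
    """Local maxima via an up/down direction walk (plateau: first bin)."""
    out = []
    going_up = True
    for i in range(len(h) - 1):
        if going_up and h[i + 1] < h[i]:
            out.append(i)
            going_up = False
        elif not going_up and h[i + 1] > h[i]:
            going_up = True
    return out


def minimum_threshold_ref(counts: np.ndarray, max_iter: int = 10_000) -> int:
    h = counts.astype(float).copy()
    for _ in range(max_iter + 1):
        maxima = _count_hist_maxima(h)
        if len(maxima) == 2:
            between = h[maxima[0] : maxima[1] + 1]
            best = maxima[0]
            for i, v in enumerate(between):
                if v < h[best]:
                    best = maxima[0] + i
            return best
        smoothed = np.empty_like(h)
        for i in range(len(h)):
            lo = max(i - 1, 0)
            hi = min(i + 1, len(h) - 1)
            # 3-bin moving average with zero padding at the ends
            total = h[i]
            total += h[i - 1] if i - 1 >= 0 else 0.0
            total += h[i + 1] if i + 1 <= len(h) - 1 else 0.0
            smoothed[i] = total / 3.0
        h = smoothed
    raise ValueError("no bimodality within the iteration cap")


def yen_threshold_ref(counts: np.ndarray) -> int:
    p = counts.astype(float) / counts.sum()
    best_t, best_val = None, -np.inf
    for t in range(256):
        p1 = p[: t + 1].sum()
        if p1 <= 0 or p1 >= 1:
            continue
        s1 = (p[: t + 1] ** 2).sum()
        s2 = (p[t + 1 :] ** 2).sum()
        if s1 <= 0 or s2 <= 0:
            continue
        val = 2.0 * np.log(p1 * (1 - p1)) - np.log(s1 * s2)
        if val > best_val:
            best_val, best_t = val, t
    return best_t


def triangle_threshold_ref(counts: np.ndarray) -> int:
    h = counts.astype(float)
    nz = np.flatnonzero(h)
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(h))
    end = last if (last - peak) >= (peak - first) else first
    x1, y1 = float(peak), float(h[peak])
    x2, y2 = float(end), float(h[end])
    lo, hi = (peak, end) if peak < end else (end, peak)
    best_t, best_d = lo, -1.0
    denom = np.hypot(x2 - x1, y2 - y1)
    for x in range(lo + 1, hi):
        d = abs((y2 - y1) * x - (x2 - x1) * h[x] + x2 * y1 - y2 * x1) / denom
        if d > best_d:
            best_d, best_t = d, x
    return best_t


# ---------------------------------------------------------------------------
# prominence-based maxima reference (level-set enumeration)
# ---------------------------------------------------------------------------

def prominence_peaks_ref(px: np.ndarray, tol: float) -> list[tuple[float, float, float, float]]:
    """All maxima with prominence >= tol, via explicit superlevel sets.

    Candidate peaks are connected equal-value plateaus with no strictly
    higher 8-neighbour. A candidate's saddle level is the highest intensity
    level at which the superlevel-set component containing it also contains
    a dominating candidate (higher, or equal-height with smaller centroid);
    prominence = height − saddle level. The overall dominant maximum takes
    height − image minimum. Returns (row, col, height, prominence) sorted by
    descending height then row-major centroid.
    """
    px = np.asarray(px, float)
    vmin = float(px.min())
    if px.max() == vmin:
        return []
    H, W = px.shape
    # --- candidates: plateaus with no higher neighbour
    higher = np.zeros((H, W), bool)
    padded = np.pad(px, 1, mode="constant", constant_values=-np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            higher |= padded[1 + dr : H + 1 + dr, 1 + dc : W + 1 + dc] > px
    candidates = []  # (height, centroid_r, centroid_c, member pixel)
    for v in np.unique(px):
        lab, k = ndi.label(px == v, structure=_S8)
        for j in range(1, k + 1):
            sel = lab == j
            if not higher[sel].any():
                rr, cc = np.nonzero(sel)
                candidates.append((float(v), rr.mean(), cc.mean(), (rr[0], cc[0])))

    def dom_key(c):
        # larger key = more dominant: higher, then smaller (row, col) centroid
        return (c[0], -c[1], -c[2])

    levels = np.unique(px)[::-1]
    prominence = {id(c): c[0] - vmin for c in candidates}  # default: never killed
    settled: set[int] = set()
    # walk levels descending; the first level whose superlevel component joins
    # a candidate with a dominating one fixes that candidate's saddle
    for v in levels:
        lab, _ = ndi.label(px >= v, structure=_S8)
        best_by_comp: dict[int, tuple] = {}
        for c in candidates:
            if c[0] < v:
                continue  # not yet present in the superlevel set
            comp = int(lab[c[3]])
            if comp not in best_by_comp or dom_key(c) > dom_key(best_by_comp[comp]):
                best_by_comp[comp] = c
        for c in candidates:
            if id(c) in settled or c[0] <= v:
                continue
            comp = int(lab[c[3]])
            if best_by_comp[comp] is not c:
                prominence[id(c)] = c[0] - float(v)
                settled.add(id(c))
    out = [
        (c[1], c[2], c[0], prominence[id(c)])
        for c in candidates
        if prominence[id(c)] >= tol
    ]
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out
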