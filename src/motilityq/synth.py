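"""Seeded synthetic fixtures with analytic ground truth.

Every pipeline in this package is exercised against images and tracks
generated here — the package's only "dataset". All generators are pure
functions of (parameters, seed): the same seed reproduces the fixture
bit-for-bit, and every ground-truth field depends only on the geometry
parameters, never on the noise realisation (except the track step ledger,
which is realisation-exact by design).

Fixtures
--------
* :func:`make_wound_stack` — a confluent-monolayer time-lapse: textured cell
  regions (clipped Gaussian speckle, smoothed at 1 px) flanking a smooth
  low-texture vertical gap whose width shrinks linearly, floored at zero.
  Per-row edge jitter with configurable SD emulates the difference between a
  culture-insert gap (straight, low jitter) and a pipette-tip scratch
  (ragged, high jitter). The rasterised gap area is forced to equal the
  analytic ``round(height · width)`` exactly, so the truth is seed-free.
* :func:`make_nuclei_image` — fluorescent nuclei as Gaussian spots on noisy
  background, placed by rejection sampling under a minimum-separation
  constraint.
* :func:`make_spreading_image` — a phase-contrast-like scene mixing small
  bright uniform disks (unspread cells) and larger darker textured blobs
  with a bright rim (spread cells), non-overlapping by construction and all
  larger than the 100 px² particle floor.
* :func:`make_tracks` — biased random walks: each step is a constant drift
  vector plus isotropic Gaussian jitter; the exact per-track accumulated
  distances are emitted as a ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imcore import CalibratedImage, InvalidInputError
from .tracks import Track, TrackSet
from .wound import ImageStack

__all__ = [
    "WoundFixture",
    "NucleiFixture",
    "SpreadFixture",
    "TrackFixture",
    "make_wound_stack",
    "make_insert_wound",
    "make_scratch_wound",
    "make_nuclei_image",
    "make_spreading_image",
    "make_tracks",
    "expected_fmi_x",
    "INSERT_JITTER_SD_UM",
    "SCRATCH_JITTER_SD_UM",
]

# Edge-raggedness presets: a removed culture insert leaves nearly straight
# gap edges, a pipette-tip scratch leaves ragged ones.
INSERT_JITTER_SD_UM = 3.0
SCRATCH_JITTER_SD_UM = 12.0


@dataclass(frozen=True)
class WoundFixture:
    """A synthetic wound time-lapse plus its analytic truth.

    ``true_areas`` (μm²) and ``true_widths`` (μm) are exact functions of the
    geometry parameters and identical across seeds.
    """

    stack: ImageStack
    true_areas: np.ndarray
    true_widths: np.ndarray
    params: dict


@dataclass(frozen=True)
class NucleiFixture:
    """A synthetic nuclei field with the true spot positions (row, col)."""

    image: CalibratedImage
    positions: np.ndarray
    params: dict


@dataclass(frozen=True)
class SpreadFixture:
    """A synthetic spreading scene with per-phenotype placement truth."""

    image: CalibratedImage
    n_unspread: int
    n_spread: int
    centers_unspread: np.ndarray
    centers_spread: np.ndarray
    params: dict

    @property
    def true_percent_spread(self) -> float:
        return 100.0 * self.n_spread / (self.n_spread + self.n_unspread)


@dataclass(frozen=True)
class TrackFixture:
    """A cohort of biased random walks with an exact step-length ledger."""

    trackset: TrackSet
    accumulated_ledger: np.ndarray
    params: dict


# ---------------------------------------------------------------------------
# wound stacks
# ---------------------------------------------------------------------------

def _smooth_jitter(rng: np.random.Generator, n: int, sd: float, corr: float) -> np.ndarray:
    """Zero-mean per-row jitter with SD ``sd`` and ~``corr``-row correlation."""
    if sd == 0:
        return np.zeros(n)
    raw = ndi.gaussian_filter1d(rng.standard_normal(n), corr, mode="wrap")
    raw -= raw.mean()
    s = raw.std()
    if s == 0:
        return np.zeros(n)
    return raw * (sd / s)


def make_wound_stack(
    shape: tuple[int, int] = (512, 512),
    n_frames: int = 10,
    px_size: float = 1.0,
    time_interval: float = 2.0,
    initial_width_um: float = 300.0,
    closure_rate_um_per_h: float = 8.0,
    edge_jitter_sd_um: float = INSERT_JITTER_SD_UM,
    jitter_corr_rows: float = 8.0,
    texture_mean: float = 100.0,
    texture_sd: float = 40.0,
    texture_smooth_px: float = 1.0,
    gap_noise_sd: float = 1.0,
    seed: int = 0,
) -> WoundFixture:
    """Simulate a linearly closing vertical wound in a textured monolayer.

    The nominal gap width at frame k is ``initial_width_um − rate · k · Δt``,
    floored at zero; per-row integer widths are jittered around it and then
    adjusted so their sum equals ``round(H · width_px)`` exactly, which makes
    ``true_areas`` independent of the seed. The jitter pattern is fixed over
    time (the wound edges move inward without re-roughening) while the
    speckle texture is redrawn per frame, as in a live acquisition.
    """
    if initial_width_um < 0 or closure_rate_um_per_h < 0:
        raise InvalidInputError("initial width and closure rate must be >= 0")
    H, W = shape
    if initial_width_um / px_size > W:
        raise InvalidInputError("initial gap width exceeds the frame")
    rng = np.random.default_rng(seed)
    jitter_px = _smooth_jitter(rng, H, edge_jitter_sd_um / px_size, jitter_corr_rows) - \
        _smooth_jitter(rng, H, edge_jitter_sd_um / px_size, jitter_corr_rows)
    col_idx = np.arange(W)[None, :]
    frames = []
    true_areas = np.empty(n_frames)
    true_widths = np.empty(n_frames)
    for k in range(n_frames):
        w_um = max(0.0, initial_width_um - closure_rate_um_per_h * k * time_interval)
        w_px = w_um / px_size
        target = int(round(H * w_px))
        true_widths[k] = w_um
        true_areas[k] = target * px_size**2
        if target > 0:
            wr = np.clip(w_px + jitter_px, 0.0, W)
            wi = np.floor(wr).astype(np.int64)
            resid = wr - wi
            deficit = target - int(wi.sum())
            if deficit > 0:
                bump = np.argsort(-resid)[:deficit]
                wi[bump] += 1
            elif deficit < 0:
                candidates = np.argsort(resid)
                candidates = candidates[wi[candidates] > 0][: -deficit]
                wi[candidates] -= 1
            left = np.clip(np.round(W / 2 - wi / 2).astype(np.int64), 0, W)
            gap = (col_idx >= left[:, None]) & (col_idx < (left + wi)[:, None])
        else:
            gap = np.zeros((H, W), bool)
        texture = texture_mean + rng.normal(0.0, texture_sd, size=(H, W))
        if texture_smooth_px > 0:
            texture = ndi.gaussian_filter(texture, texture_smooth_px, mode="nearest")
        img = np.where(gap, texture_mean + rng.normal(0.0, gap_noise_sd, size=(H, W)),
                       texture)
        frames.append(CalibratedImage(np.clip(img, 0.0, 255.0), px_size))
    stack = ImageStack(frames=tuple(frames), time_interval=time_interval)
    params = dict(
        orientation="vertical",
        shape=shape,
        n_frames=n_frames,
        px_size=px_size,
        time_interval=time_interval,
        initial_width_um=initial_width_um,
        closure_rate_um_per_h=closure_rate_um_per_h,
        edge_jitter_sd_um=edge_jitter_sd_um,
        seed=seed,
    )
    return WoundFixture(stack=stack, true_areas=true_areas, true_widths=true_widths,
                        params=params)


def make_insert_wound(seed: int = 0, **kwargs) -> WoundFixture:
    """Culture-insert-like wound: nearly straight, low-jitter gap edges."""
    kwargs.setdefault("edge_jitter_sd_um", INSERT_JITTER_SD_UM)
    return make_wound_stack(seed=seed, **kwargs)


def make_scratch_wound(seed: int = 0, **kwargs) -> WoundFixture:
    """Pipette-tip-scratch-like wound: ragged, high-jitter gap edges."""
    kwargs.setdefault("edge_jitter_sd_um", SCRATCH_JITTER_SD_UM)
    return make_wound_stack(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# nuclei fields
# ---------------------------------------------------------------------------

_PLACEMENT_CAP = 1000  # attempts per requested point before giving up


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    margin: float,
) -> np.ndarray:
    H, W = shape
    if n == 0:
        return np.empty((0, 2))
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= _PLACEMENT_CAP * n:
            raise InvalidInputError(
                f"could not place {n} points with separation {min_separation}; "
                "lower n or the separation"
            )
        attempts += 1
        p = np.array(
            [rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)]
        )
        if all(np.hypot(*(p - q)) >= min_separation for q in placed):
            placed.append(p)
    return np.array(placed)


def make_nuclei_image(
    n: int = 200,
    shape: tuple[int, int] = (512, 512),
    amplitude: float = 100.0,
    spot_sigma: float = 3.0,
    noise_sd: float = 10.0,
    min_separation: float = 20.0,
    background: float = 20.0,
    px_size: float = 1.0,
    seed: int = 0,
) -> NucleiFixture:
    """Simulate a Hoechst-stained transwell field: Gaussian nuclei on noise.

    ``n`` spots of the given amplitude and width are placed uniformly with a
    minimum pairwise separation (rejection sampling with an attempt cap);
    Gaussian read noise is added and the image rounded to integer levels in
    [0, 255]. With n = 0 the image is pure noise.
    """
    rng = np.random.default_rng(seed)
    margin = 3.0 * spot_sigma + 2.0
    positions = _place_points(rng, n, shape, min_separation, margin)
    H, W = shape
    canvas = np.zeros((H, W))
    r = int(np.ceil(4 * spot_sigma))
    for row, col in positions:
        r0 = max(int(np.floor(row)) - r, 0)
        r1 = min(int(np.floor(row)) + r + 1, H)
        c0 = max(int(np.floor(col)) - r, 0)
        c1 = min(int(np.floor(col)) + r + 1, W)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * spot_sigma**2)
        )
    img = background + canvas + rng.normal(0.0, noise_sd, size=(H, W))
    img = np.round(np.clip(img, 0.0, 255.0))
    params = dict(
        n=n, shape=shape, amplitude=amplitude, spot_sigma=spot_sigma,
        noise_sd=noise_sd, min_separation=min_separation, background=background,
        seed=seed,
    )
    return NucleiFixture(
        image=CalibratedImage(img, px_size), positions=positions, params=params
    )


# ---------------------------------------------------------------------------
# spreading scenes
# ---------------------------------------------------------------------------

def make_spreading_image(
    n_unspread: int = 30,
    n_spread: int = 50,
    shape: tuple[int, int] = (768, 768),
    unspread_radius: float = 9.0,
    spread_radius: float = 18.0,
    rim_width: float = 2.0,
    background: float = 120.0,
    noise_sd: float = 2.0,
    unspread_intensity: float = 235.0,
    spread_mean: float = 75.0,
    spread_texture_sd: float = 15.0,
    rim_intensity: float = 150.0,
    min_gap: float = 8.0,
    px_size: float = 1.0,
    seed: int = 0,
) -> SpreadFixture:
    """Simulate a phase-contrast spreading field.

    Unspread cells render as small uniform bright disks (round and
    refringent); spread cells as larger disks with a dark textured interior
    and a thin bright rim. Footprints are non-overlapping with at least
    ``min_gap`` pixels between boundaries, and every footprint exceeds the
    100 px² particle-analysis floor by construction.
    """
    if min(unspread_radius, spread_radius) ** 2 * np.pi <= 100:
        raise InvalidInputError("cell radii must give footprints above 100 px²")
    rng = np.random.default_rng(seed)
    H, W = shape
    n_total = n_unspread + n_spread
    sep = 2 * spread_radius + min_gap  # conservative: any pair of cells
    margin = spread_radius + min_gap
    centers = _place_points(rng, n_total, shape, sep, margin)
    perm = rng.permutation(n_total)
    centers = centers[perm]
    cu = centers[:n_unspread]
    cs = centers[n_unspread:]
    img = background + rng.normal(0.0, noise_sd, size=(H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    for row, col in cs:
        d = np.hypot(yy - row, xx - col)
        interior = d <= spread_radius - rim_width
        rim = (d <= spread_radius) & ~interior
        texture = spread_mean + ndi.gaussian_filter(
            rng.normal(0.0, spread_texture_sd, size=(H, W)), 1.0
        )
        img[interior] = texture[interior]
        img[rim] = rim_intensity
    for row, col in cu:
        d = np.hypot(yy - row, xx - col)
        img[d <= unspread_radius] = unspread_intensity
    img = np.round(np.clip(img, 0.0, 255.0))
    params = dict(
        n_unspread=n_unspread, n_spread=n_spread, shape=shape,
        unspread_radius=unspread_radius, spread_radius=spread_radius,
        rim_width=rim_width, seed=seed,
    )
    return SpreadFixture(
        image=CalibratedImage(img, px_size),
        n_unspread=n_unspread,
        n_spread=n_spread,
        centers_unspread=cu,
        centers_spread=cs,
        params=params,
    )


# ---------------------------------------------------------------------------
# biased random-walk tracks
# ---------------------------------------------------------------------------

def make_tracks(
    n_tracks: int = 300,
    n_steps: int = 60,
    drift: tuple[float, float] = (1.0, 0.0),
    step_sd: float = 4.0,
    time_interval: float = 1.0 / 3.0,
    field_um: float = 400.0,
    seed: int = 0,
) -> TrackFixture:
    """Simulate biased random walks in μm.

    Each of the ``n_steps`` steps is the ``drift`` vector (per-step μm along
    x and y) plus isotropic Gaussian jitter with SD ``step_sd``. Start points
    are uniform in a ``field_um``-sized square. The emitted ledger holds each
    track's exact accumulated distance, computed with the same arithmetic the
    track-statistics module uses.
    """
    if n_steps < 1:
        raise InvalidInputError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    starts = rng.uniform(0.0, field_um, size=(n_tracks, 2))
    steps = np.asarray(drift) + rng.normal(0.0, step_sd, size=(n_tracks, n_steps, 2))
    positions = starts[:, None, :] + np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    # ledger from the emitted positions, not the raw steps: bitwise-identical
    # to the arithmetic the track-statistics module performs
    dxy = np.diff(positions, axis=1)
    ledger = np.hypot(dxy[:, :, 0], dxy[:, :, 1]).sum(axis=1)
    frames = np.arange(n_steps + 1)
    tracks = tuple(
        Track(track_id=i + 1, frames=frames, x=positions[i, :, 0], y=positions[i, :, 1])
        for i in range(n_tracks)
    )
    ts = TrackSet(tracks=tracks, time_interval=time_interval, px_size=1.0,
                  calibrated=True)
    params = dict(
        n_tracks=n_tracks, n_steps=n_steps, drift=tuple(drift), step_sd=step_sd,
        time_interval=time_interval, seed=seed,
    )
    return TrackFixture(trackset=ts, accumulated_ledger=ledger, params=params)


def expected_fmi_x(
    drift: tuple[float, float] = (1.0, 0.0),
    step_sd: float = 4.0,
    n_steps: int = 60,
    n_pilot: int = 100_000,
    seed: int = 12345,
) -> tuple[float, float]:
    """Simulation-truth mean and SD of per-track FMI_x for given walk parameters.

    Estimated from a large vectorised pilot cohort; used as the reference
    value when checking parameter recovery on finite cohorts.
    """
    rng = np.random.default_rng(seed)
    steps = np.asarray(drift) + rng.normal(0.0, step_sd, size=(n_pilot, n_steps, 2))
    accumulated = np.hypot(steps[:, :, 0], steps[:, :, 1]).sum(axis=1)
    net_x = steps[:, :, 0].sum(axis=1)
    fmi = np.where(accumulated > 0, net_x / accumulated, 0.0)
    return float(fmi.mean()), float(fmi.std(ddof=1))
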