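"""Synthetic lake stacks with known ground truth.

Emulates the error structure of pixel-based monthly surface-water products:
a lake's true extent at time t is the sub-level set of a fixed bathymetry at
the current water level; the observed stack corrupts it with asymmetric
label flips (water labels more reliable than land labels) and with two
kinds of missingness — class-independent cloud-like disks (MCAR) and
class-conditional missingness concentrated near the shoreline, where
upstream classifiers are least confident.

All randomness flows from a single integer seed; identical configs produce
bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import LAND, MISSING, WATER, Georef, TernaryStack

BATHYMETRY_KINDS = ("bowl", "tilted_plane", "two_basin", "flat_ephemeral", "ribbon")


@dataclass(frozen=True)
class LevelParams:
    """Water-level model: mean + seasonal sine + linear trend + white noise."""

    mean: float = 0.5
    seasonal_amplitude: float = 0.25
    trend_per_step: float = 0.0
    noise_sd: float = 0.05


@dataclass(frozen=True)
class NoiseParams:
    """Per-pixel label flip probabilities.

    Water observations are more trustworthy than land observations in the
    source product, so the default water->land flip rate is lower.
    """

    p_water_flip: float = 0.05
    p_land_flip: float = 0.15


@dataclass(frozen=True)
class MissingParams:
    """Missingness model: MCAR cloud disks plus shoreline-conditional gaps."""

    mcar_rate: float = 0.2
    blob_radius_px: int = 3
    shoreline_rate: float = 0.3
    shoreline_band_px: int = 1


@dataclass(frozen=True)
class SyntheticLakeConfig:
    bathymetry_kind: str = "bowl"
    shape: tuple[int, int] = (40, 40)
    level_params: LevelParams = field(default_factory=LevelParams)
    T: int = 60
    noise: NoiseParams = field(default_factory=NoiseParams)
    missing: MissingParams = field(default_factory=MissingParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bathymetry_kind not in BATHYMETRY_KINDS:
            raise ValueError(f"unknown bathymetry kind {self.bathymetry_kind!r}")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        for p in (self.noise.p_water_flip, self.noise.p_land_flip,
                  self.missing.mcar_rate, self.missing.shoreline_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic stack.

    bathymetry : elevation grid (dimensionless, roughly [0, 1] inside the basin)
    levels : length-T water-surface elevations
    true_stack : (T, R, C) boolean water masks, water where bathymetry < level
    lake_mask : union of all true extents (pixels ever wet)
    """

    bathymetry: np.ndarray
    levels: np.ndarray
    true_stack: np.ndarray
    lake_mask: np.ndarray


def make_bathymetry(kind: str, shape: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Deterministic elevation grid of the requested archetype.

    bowl            paraboloid in Chebyshev distance from the grid centre
                    (single minimum: the monotone single-basin case)
    tilted_plane    elevation increases linearly with column
    two_basin       two bowls joined over a sill — deliberately violates the
                    single-basin assumption
    flat_ephemeral  near-constant elevation: tiny level changes flood or
                    drain the whole footprint
    ribbon          thin low-elevation channel along the grid's long axis
                    (river-like, for the morphological filter)

    A seeded jitter of amplitude 1e-4 breaks elevation ties so pixel
    orderings are unique; it is far below any level increment.
    """
    if kind not in BATHYMETRY_KINDS:
        raise ValueError(f"unknown bathymetry kind {kind!r}")
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    rng = np.random.default_rng(seed)

    if kind == "bowl":
        cr, cc = (rows - 1) / 2, (cols - 1) / 2
        d = np.maximum(np.abs(r - cr), np.abs(c - cc))
        dmax = max(d.max(), 1.0)
        elev = (d / dmax) ** 2
    elif kind == "tilted_plane":
        elev = c / max(cols - 1, 1) * np.ones((rows, cols))
    elif kind == "two_basin":
        c1 = (rows / 2, cols / 4)
        c2 = (rows / 2, 3 * cols / 4)
        scale = max(rows, cols) / 2
        b1 = ((r - c1[0]) ** 2 + (c - c1[1]) ** 2) / scale**2
        b2 = ((r - c2[0]) ** 2 + (c - c2[1]) ** 2) / scale**2
        elev = np.minimum(b1, b2)
    elif kind == "flat_ephemeral":
        elev = np.full((rows, cols), 0.5)
    else:  # ribbon
        # channel runs along the long axis; offset measured across the short one
        if rows >= cols:
            off = np.abs(c - (cols - 1) / 2) * np.ones((rows, cols))
        else:
            off = np.abs(r - (rows - 1) / 2) * np.ones((rows, cols))
        halfwidth = max((min(rows, cols)) / 2, 1.0)
        elev = (off / halfwidth) ** 2 * np.ones((rows, cols))

    return elev + rng.uniform(0, 1e-4, size=(rows, cols))


def simulate_levels(params: LevelParams, T: int, seed: int = 0) -> np.ndarray:
    """Monthly water levels: mean + amplitude*sin(2*pi*t/12) + trend*t + noise."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    levels = (
        params.mean
        + params.seasonal_amplitude * np.sin(2 * np.pi * t / 12)
        + params.trend_per_step * t
        + rng.normal(0, params.noise_sd, size=T)
    )
    return levels


def render_truth(bathymetry: np.ndarray, levels: np.ndarray) -> SyntheticTruth:
    """Flood-fill the bathymetry at each level: water where elevation < level."""
    bathymetry = np.asarray(bathymetry, dtype=float)
    levels = np.asarray(levels, dtype=float)
    true_stack = bathymetry[None, :, :] < levels[:, None, None]
    return SyntheticTruth(
        bathymetry=bathymetry,
        levels=levels,
        true_stack=true_stack,
        lake_mask=true_stack.any(axis=0),
    )


def _shoreline_band(water: np.ndarray, band_px: int) -> np.ndarray:
    """Pixels within Chebyshev distance band_px of the water/land boundary."""
    if band_px < 1 or not water.any():
        return np.zeros_like(water, dtype=bool)
    se = np.ones((2 * band_px + 1, 2 * band_px + 1), dtype=bool)
    dil = ndimage.binary_dilation(water, structure=se)
    ero = ndimage.binary_erosion(water, structure=se, border_value=0)
    return dil & ~ero


def corrupt(
    true_stack: np.ndarray,
    noise: NoiseParams,
    missing: MissingParams,
    seed: int = 0,
    timestamps: list[tuple[int, int]] | None = None,
    pixel_area_km2: float | None = None,
    georef: Georef | None = None,
) -> TernaryStack:
    """Corrupt a boolean truth stack into an observed ternary stack.

    Order of application: class-conditional label flips first, then
    missingness overwrites (a cell cannot be both flipped and missing).
    MCAR missingness is placed as random disks of ``blob_radius_px`` whose
    expected coverage matches ``mcar_rate``; shoreline missingness hits a
    Chebyshev band around each frame's true boundary at ``shoreline_rate``.
    """
    true_stack = np.asarray(true_stack, dtype=bool)
    T, R, C = true_stack.shape
    rng = np.random.default_rng(seed)

    labels = np.where(true_stack, WATER, LAND).astype(np.uint8)

    u = rng.random(size=(T, R, C))
    flip = (true_stack & (u < noise.p_water_flip)) | (~true_stack & (u < noise.p_land_flip))
    labels[flip] = np.where(true_stack[flip], LAND, WATER).astype(np.uint8)

    miss = np.zeros((T, R, C), dtype=bool)
    rad = int(missing.blob_radius_px)
    if missing.mcar_rate > 0:
        if rad < 1:
            miss |= rng.random(size=(T, R, C)) < missing.mcar_rate
        else:
            yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
            disk = (yy**2 + xx**2) <= rad**2
            disk_area = int(disk.sum())
            n_disks = max(1, round(missing.mcar_rate * R * C / disk_area))
            for t in range(T):
                centers = np.zeros((R, C), dtype=bool)
                rs = rng.integers(0, R, size=n_disks)
                cs = rng.integers(0, C, size=n_disks)
                centers[rs, cs] = True
                miss[t] |= ndimage.binary_dilation(centers, structure=disk)
    if missing.shoreline_rate > 0 and missing.shoreline_band_px >= 1:
        for t in range(T):
            band = _shoreline_band(true_stack[t], missing.shoreline_band_px)
            miss[t] |= band & (rng.random(size=(R, C)) < missing.shoreline_rate)

    labels[miss] = MISSING

    if timestamps is None:
        timestamps = [(2000 + i // 12, 1 + i % 12) for i in range(T)]
    kwargs = {} if pixel_area_km2 is None else {"pixel_area_km2": pixel_area_km2}
    return TernaryStack(labels=labels, timestamps=timestamps, georef=georef, **kwargs)


def generate(config: SyntheticLakeConfig) -> tuple[TernaryStack, SyntheticTruth]:
    """Run the full generator: bathymetry -> levels -> truth -> corruption.

    Sub-seeds for each stage are derived deterministically from config.seed.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    bathy = make_bathymetry(config.bathymetry_kind, config.shape, seed=sub[0])
    levels = simulate_levels(config.level_params, config.T, seed=sub[1])
    truth = render_truth(bathy, levels)
    stack = corrupt(truth.true_stack, config.noise, config.missing, seed=sub[2])
    return stack, truth


def generate_scene(
    configs: list[SyntheticLakeConfig],
    gap_px: int = 10,
    seed: int = 0,
) -> tuple[TernaryStack, list[SyntheticTruth], list[tuple[int, int]]]:
    """Compose several independent lakes side by side on one land canvas.

    Lakes are placed left to right separated by ``gap_px`` columns of dry
    land; all must share T.  Returns the scene stack, per-lake truths, and
    each lake's (row, col) offset in the scene.  Used to exercise the
    extraction -> correction pipeline on multi-lake inputs.
    """
    if not configs:
        raise ValueError("no lake configs supplied")
    Ts = {c.T for c in configs}
    if len(Ts) != 1:
        raise ValueError("all lakes in a scene must share T")
    T = Ts.pop()

    stacks, truths = [], []
    for i, cfg in enumerate(configs):
        cfg_seeded = SyntheticLakeConfig(
            bathymetry_kind=cfg.bathymetry_kind, shape=cfg.shape,
            level_params=cfg.level_params, T=cfg.T, noise=cfg.noise,
            missing=cfg.missing, seed=cfg.seed + 1000003 * seed,
        )
        s, tr = generate(cfg_seeded)
        stacks.append(s)
        truths.append(tr)

    rows = max(c.shape[0] for c in configs) + 2 * gap_px
    cols = sum(c.shape[1] for c in configs) + gap_px * (len(configs) + 1)
    canvas = np.full((T, rows, cols), LAND, dtype=np.uint8)
    offsets = []
    col0 = gap_px
    for s in stacks:
        r0 = gap_px
        rr, cc = s.shape
        canvas[:, r0 : r0 + rr, col0 : col0 + cc] = s.labels
        offsets.append((r0, col0))
        col0 += cc + gap_px
    scene = TernaryStack(labels=canvas, timestamps=stacks[0].timestamps)
    return scene, truths, offsets
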