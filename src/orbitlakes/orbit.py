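"""ORBIT (Ordering Based Information Transfer) label correction and imputation.

A lake confined to a single basin fills and drains along its bathymetry: a
pixel can only be wet if every lower-elevation pixel is wet too.  ORBIT
exploits this by representing a lake as (i) a relative elevation ordering of
its pixels and (ii) a per-month fill level k[t]; the corrected extent at
month t is exactly the k[t] lowest pixels (a *prefix* of the ordering).
Neither the ordering nor the levels are observed: both are estimated from
the noisy multi-temporal stack by coordinate descent on a discrete
objective that charges

* ``w_water`` for overruling an observed WATER cell (default 3),
* ``w_land``  for overruling an observed LAND cell (default 1),
* nothing for filling a MISSING cell, and
* ``lam`` per pixel of month-to-month level change, which transfers
  information from nearby months into gaps.

The asymmetric default reflects that water labels in pixel-based products
are more reliable than land labels.  The level update (given an ordering)
is solved *exactly* by dynamic programming over (month, level); the
ordering update re-sorts pixels by an observed-wetness score, with MISSING
cells voting via their current assignment (weight ``gamma``).  Sorts are
stable and ties break toward smaller levels, so the whole fit is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LAND, MISSING, WATER, TernaryStack
from .extraction import LakeRecord, _STRUCT
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrbitConfig:
    """Tunable knobs of the correction model (all echoed into metadata)."""

    w_water: float = 3.0   # cost of flipping an observed water cell to land
    w_land: float = 1.0    # cost of flipping an observed land cell to water
    lam: float = 0.5       # temporal smoothness, per pixel of level change
    gamma: float = 1.0     # weight of imputed cells in the ordering score
    max_iter: int = 10
    min_connected_count: int = 5
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.w_water <= 0 or self.w_land <= 0:
            raise ValueError("flip costs must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class PixelOrdering:
    """Permutation of a lake's pixels; position 0 = lowest (wettest) pixel."""

    order: np.ndarray  # order[r] = pixel index with elevation rank r
    rank: np.ndarray   # rank[i] = elevation rank of pixel i

    @classmethod
    def from_order(cls, order: np.ndarray) -> "PixelOrdering":
        order = np.asarray(order)
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        return cls(order=order, rank=rank)


@dataclass
class CorrectedStack:
    """Physically consistent water masks plus per-month correction metadata.

    ``binary`` is (T, R, C) on the lake-local grid; every frame's water set
    is the prefix {order[0..k[t])} of the learned ordering.  ``metadata``
    has per-frame pct_corrected (flipped observed labels, % of observed),
    pct_imputed (missing cells, % of lake cells) and all_missing_flag.
    """

    binary: np.ndarray
    ordering: PixelOrdering
    levels: np.ndarray
    mask: np.ndarray
    metadata: pd.DataFrame
    objective: float
    n_iter: int
    config: OrbitConfig = field(default_factory=OrbitConfig)
    timestamps: list[tuple[int, int]] = field(default_factory=list)
    pixel_area_km2: float = 0.0009


# ---------------------------------------------------------------------------
# Lake-local stack extraction
# ---------------------------------------------------------------------------

def extract_lake_stack(
    scene: TernaryStack,
    lake: LakeRecord,
    min_connected_count: int = 5,
    connectivity: int = 8,
    padding: int = 2,
) -> tuple[TernaryStack, np.ndarray]:
    """Crop the scene to the lake and mask out pixels of other waterbodies.

    A pixel outside the reference extent is retained only if, in at least
    ``min_connected_count`` frames, it is WATER and shares a connected water
    component with the reference extent; all other outside pixels are forced
    to LAND in every frame.  Returns the lake-local stack and the analysis
    mask (reference extent plus retained neighbours).
    """
    r0, r1, c0, c1 = lake.bbox
    R, C = scene.shape
    r0, c0 = max(0, r0 - padding), max(0, c0 - padding)
    r1, c1 = min(R, r1 + padding), min(C, c1 + padding)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("degenerate lake bounding box")
    ref = np.asarray(lake.mask, dtype=bool)[r0:r1, c0:c1]
    if not ref.any():
        raise ValueError("lake reference extent is empty")
    labels = scene.labels[:, r0:r1, c0:c1].copy()

    struct = _STRUCT[connectivity]
    co_wet = np.zeros(ref.shape, dtype=np.int64)
    for t in range(labels.shape[0]):
        water = labels[t] == WATER
        lab, n = ndimage.label(water, structure=struct)
        if n == 0:
            continue
        touching = np.unique(lab[ref & water])
        touching = touching[touching > 0]
        if touching.size:
            co_wet += np.isin(lab, touching)
    mask = ref | (co_wet >= min_connected_count)
    labels[:, ~mask] = LAND
    local = TernaryStack(
        labels=labels,
        timestamps=scene.timestamps,
        georef=None,
        pixel_area_km2=scene.pixel_area_km2,
    )
    return local, mask


# ---------------------------------------------------------------------------
# Objective and coordinate-descent steps (flat (T, N) observation arrays)
# ---------------------------------------------------------------------------

def _level_costs(obs: np.ndarray, ordering: PixelOrdering, config: OrbitConfig) -> np.ndarray:
    """c[t, k] = label-disagreement cost of assigning the k lowest pixels
    water at month t, for k = 0..N."""
    s = obs[:, ordering.order]  # (T, N) sorted by elevation rank
    land = (s == LAND).astype(np.float64)
    water = (s == WATER).astype(np.float64)
    T, N = s.shape
    c = np.zeros((T, N + 1))
    # cost(k) = w_land * (#land among first k) + w_water * (#water among last N-k)
    cum_land = np.concatenate([np.zeros((T, 1)), np.cumsum(land, axis=1)], axis=1)
    cum_water = np.concatenate([np.zeros((T, 1)), np.cumsum(water, axis=1)], axis=1)
    total_water = cum_water[:, -1:]
    c = config.w_land * cum_land + config.w_water * (total_water - cum_water)
    return c


def objective(
    obs: np.ndarray, ordering: PixelOrdering, levels: np.ndarray, config: OrbitConfig
) -> float:
    """Total cost of a (ordering, levels) state on the observations."""
    c = _level_costs(obs, ordering, config)
    levels = np.asarray(levels, dtype=np.int64)
    data_cost = float(c[np.arange(c.shape[0]), levels].sum())
    temporal = float(config.lam * np.abs(np.diff(levels)).sum())
    return data_cost + temporal


def fit_levels(obs: np.ndarray, ordering: PixelOrdering, config: OrbitConfig) -> np.ndarray:
    """Exact global minimizer of the objective over level series.

    With lam = 0 each month is an independent argmin; with lam > 0 an exact
    dynamic program over (month, level) with |Δk| transition costs is
    solved with two-pass min-convolutions in O(T·N).  Ties break toward the
    smaller level.
    """
    c = _level_costs(obs, ordering, config)
    T, K = c.shape
    if config.lam == 0:
        return np.argmin(c, axis=1).astype(np.int64)  # argmin → first (smallest) k

    D = np.empty_like(c)
    D[0] = c[0]
    lam = config.lam
    ks = np.arange(K, dtype=np.float64)
    for t in range(1, T):
        # min-convolution with lam*|k-j| via forward/backward running minima:
        # min_j D[j] + lam|k-j| = min( lam*k + min_{j<=k}(D[j]-lam*j),
        #                             -lam*k + min_{j>=k}(D[j]+lam*j) )
        fwd = np.minimum.accumulate(D[t - 1] - lam * ks) + lam * ks
        bwd = np.minimum.accumulate((D[t - 1] + lam * ks)[::-1])[::-1] - lam * ks
        D[t] = c[t] + np.minimum(fwd, bwd)

    levels = np.empty(T, dtype=np.int64)
    levels[-1] = int(np.argmin(D[-1]))
    for t in range(T - 2, -1, -1):
        trans = D[t] + lam * np.abs(np.arange(K) - levels[t + 1])
        levels[t] = int(np.argmin(trans))
    return levels


def update_ordering(
    obs: np.ndarray,
    levels: np.ndarray,
    current: PixelOrdering,
    config: OrbitConfig,
) -> PixelOrdering:
    """Re-sort pixels by observed wetness, imputed cells voting via their
    current assignment.  The sort is stable on the current ordering, so
    repeated calls with unchanged inputs are idempotent."""
    T, N = obs.shape
    n_water = (obs == WATER).sum(axis=0).astype(np.float64)
    n_land = (obs == LAND).sum(axis=0).astype(np.float64)
    miss = obs == MISSING
    assigned_water = current.rank[None, :] < np.asarray(levels)[:, None]
    mw = (miss & assigned_water).sum(axis=0).astype(np.float64)
    ml = (miss & ~assigned_water).sum(axis=0).astype(np.float64)
    score = config.w_water * n_water - config.w_land * n_land + config.gamma * (mw - ml)
    cur = current.order
    perm = np.argsort(-score[cur], kind="stable")
    return PixelOrdering.from_order(cur[perm])


def initial_ordering(obs: np.ndarray, config: OrbitConfig) -> PixelOrdering:
    """Stable sort of pixels by observed wetness (missing cells neutral),
    ties broken by raster-scan pixel index."""
    n_water = (obs == WATER).sum(axis=0).astype(np.float64)
    n_land = (obs == LAND).sum(axis=0).astype(np.float64)
    score = config.w_water * n_water - config.w_land * n_land
    order = np.argsort(-score, kind="stable")
    return PixelOrdering.from_order(order)


# ---------------------------------------------------------------------------
# Full correction
# ---------------------------------------------------------------------------

def correct_stack(
    stack: TernaryStack,
    mask: np.ndarray | None = None,
    config: OrbitConfig | None = None,
) -> CorrectedStack:
    """Coordinate descent: alternate exact level fits and ordering updates.

    Starts from the observed-wetness ordering, accepts an iteration only if
    the objective strictly decreases, and returns the best state seen, so
    the accepted objective sequence is non-increasing.  Pixels outside
    ``mask`` (default: whole grid) are land in every output frame.
    """
    config = config or OrbitConfig()
    T, R, C = stack.labels.shape
    if mask is None:
        mask = np.ones((R, C), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    pix = np.nonzero(mask.ravel())[0]
    N = pix.size
    if N == 0 or T == 0:
        logger.warning("degenerate lake stack (no pixels or frames)")
        empty_meta = pd.DataFrame(
            columns=["pct_corrected", "pct_imputed", "all_missing_flag"]
        )
        return CorrectedStack(
            binary=np.zeros((T, R, C), dtype=bool),
            ordering=PixelOrdering.from_order(np.empty(0, dtype=np.int64)),
            levels=np.zeros(T, dtype=np.int64),
            mask=mask, metadata=empty_meta, objective=0.0, n_iter=0,
            config=config, timestamps=list(stack.timestamps),
            pixel_area_km2=stack.pixel_area_km2,
        )

    obs = stack.labels.reshape(T, -1)[:, pix]

    ordering = initial_ordering(obs, config)
    levels = fit_levels(obs, ordering, config)
    obj = objective(obs, ordering, levels, config)
    best = (obj, ordering, levels)
    n_iter = 0
    for _ in range(config.max_iter):
        n_iter += 1
        new_ordering = update_ordering(obs, levels, ordering, config)
        new_levels = fit_levels(obs, new_ordering, config)
        new_obj = objective(obs, new_ordering, new_levels, config)
        if new_obj < best[0]:
            best = (new_obj, new_ordering, new_levels)
            ordering, levels, obj = new_ordering, new_levels, new_obj
        else:
            break
    obj, ordering, levels = best[0], best[1], best[2]

    assigned = ordering.rank[None, :] < levels[:, None]  # (T, N)
    binary = np.zeros((T, R * C), dtype=bool)
    binary[:, pix] = assigned
    binary = binary.reshape(T, R, C)

    observed = obs != MISSING
    n_obs = observed.sum(axis=1)
    flips = (observed & (assigned != (obs == WATER))).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_corrected = np.where(n_obs > 0, 100.0 * flips / np.maximum(n_obs, 1), 0.0)
    pct_imputed = 100.0 * (obs == MISSING).sum(axis=1) / N
    metadata = pd.DataFrame(
        {
            "pct_corrected": pct_corrected,
            "pct_imputed": pct_imputed,
            "all_missing_flag": n_obs == 0,
        }
    )
    if config.lam == 0 and (n_obs == 0).any():
        logger.warning(
            "all-missing frames with lam=0 take level 0 by the tie rule; "
            "set lam > 0 to interpolate them from neighbours"
        )
    return CorrectedStack(
        binary=binary,
        ordering=ordering,
        levels=levels,
        mask=mask,
        metadata=metadata,
        objective=obj,
        n_iter=n_iter,
        config=config,
        timestamps=list(stack.timestamps),
        pixel_area_km2=stack.pixel_area_km2,
    )


# ---------------------------------------------------------------------------
# Resolution handling for very large lakes
# ---------------------------------------------------------------------------

def downsample_stack(stack: TernaryStack, factor: int) -> TernaryStack:
    """Block-aggregate a stack by an integer factor (e.g. 10: 30 m → 300 m).

    A block becomes WATER if more than half of its non-missing cells are
    water, LAND otherwise, and MISSING only if every cell is missing.
    Non-divisible shapes are edge-padded with MISSING; pixel area scales by
    factor^2.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    T, R, C = stack.labels.shape
    Rp = -(-R // factor) * factor
    Cp = -(-C // factor) * factor
    lab = np.full((T, Rp, Cp), MISSING, dtype=np.uint8)
    lab[:, :R, :C] = stack.labels
    blocks = lab.reshape(T, Rp // factor, factor, Cp // factor, factor)
    water = (blocks == WATER).sum(axis=(2, 4))
    land = (blocks == LAND).sum(axis=(2, 4))
    valid = water + land
    out = np.where(valid == 0, MISSING, np.where(2 * water > valid, WATER, LAND))
    georef = stack.georef
    if georef is not None:
        x0, dx, rx, y0, ry, dy = georef.transform
        georef = type(georef)(
            transform=(x0, dx * factor, rx, y0, ry, dy * factor), crs=georef.crs
        )
    return TernaryStack(
        labels=out.astype(np.uint8),
        timestamps=list(stack.timestamps),
        georef=georef,
        pixel_area_km2=stack.pixel_area_km2 * factor * factor,
    )
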