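"""Phase 1: static lake database from an occurrence layer.

Pixels observed as water in more than 10% of their valid months are kept,
connected components become candidate lakes, small components (< 100 px by
default) are dropped, and river-like shapes are flagged by a morphological
score 4e^2/N, where e is the number of 3x3 binary erosions needed to empty
the component and N its pixel count.  4e^2 approximates the area of the
largest inscribed square, so low scores mean long, thin (lotic) shapes.
Records are flagged, never silently removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MISSING, WATER, Georef, OccurrenceLayer, TernaryStack, mask_to_polygon

logger = logging.getLogger(__name__)

DEFAULT_OCCURRENCE_THRESHOLD_PCT = 10.0
DEFAULT_MIN_PIXELS = 100
DEFAULT_RIVER_THRESHOLD = 0.05

_STRUCT = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class LakeRecord:
    """One delineated lake: reference extent plus shape scores and flags.

    ``mask`` is the full-scene boolean reference extent; ``bbox`` its
    (row_min, row_max, col_min, col_max) half-open bounding box.  ``cs``,
    ``es`` and ``reliable_flag`` stay None until quality scoring runs.
    """

    lake_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    n_pixels: int
    area_km2: float
    erosion_count: int | None = None
    morph_score: float | None = None
    river_flag: bool | None = None
    line_overlap_flag: bool | None = None
    cs: float | None = None
    es: int | None = None
    reliable_flag: bool | None = None
    georef: Georef | None = None


def compute_occurrence(stack: TernaryStack) -> OccurrenceLayer:
    """Percent of *observed* (non-missing) months each pixel is water.

    Cells missing in every month get NaN — "observed as water" is read as
    conditional on there being an observation at all.
    """
    water = (stack.labels == WATER).sum(axis=0)
    observed = (stack.labels != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(observed > 0, 100.0 * water / np.maximum(observed, 1), np.nan)
    return OccurrenceLayer(percent=pct, georef=stack.georef)


def binarize_occurrence(
    occ: OccurrenceLayer, threshold_pct: float = DEFAULT_OCCURRENCE_THRESHOLD_PCT
) -> np.ndarray:
    """Strictly-greater-than threshold; never-observed (NaN) cells are False."""
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in [0, 100]")
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(occ.percent, nan=-1.0) > threshold_pct


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Connected components of a binary mask as boolean masks.

    Components are ordered (and therefore id'd downstream) by the raster-scan
    position of each component's first pixel, independent of the labelling
    library's internal order.
    """
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_STRUCT[connectivity])
    if n == 0:
        return []
    flat = lab.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.nonzero(flat)[0]
    # reversed so earlier raster positions overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable")
    return [lab == (i + 1) for i in order]


def filter_by_size(components: list[np.ndarray], min_pixels: int = DEFAULT_MIN_PIXELS) -> list[np.ndarray]:
    """Keep components with at least ``min_pixels`` pixels."""
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    return [c for c in components if int(c.sum()) >= min_pixels]


def erosion_count(mask: np.ndarray) -> int:
    """Number of successive 3x3 binary erosions needed to empty the mask.

    Cells outside the raster count as background, so a shape touching the
    border erodes from the border inward like any other; a single pixel
    (no full 3x3 neighbourhood anywhere) has e = 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("erosion_count of an empty mask is undefined")
    se = np.ones((3, 3), dtype=bool)
    e = 0
    while mask.any():
        mask = ndimage.binary_erosion(mask, structure=se, border_value=0)
        e += 1
    return e


def morphological_score(e: int, n_pixels: int) -> float:
    """4e^2 / N — fraction of the lake covered by the largest inscribed
    square (approximately).  Deliberately uncapped: compact shapes can
    score slightly above 1."""
    if e < 1 or n_pixels < 1:
        raise ValueError("e and N must be >= 1")
    return 4.0 * e * e / n_pixels


def flag_rivers(
    records: list[LakeRecord], river_threshold: float = DEFAULT_RIVER_THRESHOLD
) -> list[LakeRecord]:
    """Set river_flag = (morph_score < threshold), strict less-than."""
    for rec in records:
        if rec.morph_score is None:
            rec.erosion_count = erosion_count(rec.mask)
            rec.morph_score = morphological_score(rec.erosion_count, rec.n_pixels)
        rec.river_flag = rec.morph_score < river_threshold
    return records


def flag_line_overlap(
    records: list[LakeRecord],
    lines,
    buffer_km: float = 1.0,
) -> list[LakeRecord]:
    """Flag lakes whose extent intersects a buffer around river line features.

    ``lines`` is any shapely line geometry (or iterable of them) in the same
    projected CRS as the records' georeference; the buffer distance assumes
    CRS units of metres.  With no lines supplied all flags are False.
    """
    if lines is None:
        logger.warning("no line features supplied; line_overlap_flag set to False")
        for rec in records:
            rec.line_overlap_flag = False
        return records
    from shapely.ops import unary_union

    geom = unary_union(list(lines)) if isinstance(lines, (list, tuple)) else lines
    buffered = geom.buffer(buffer_km * 1000.0)
    for rec in records:
        if rec.georef is None:
            raise ValueError(f"lake {rec.lake_id} has no georeference")
        poly = mask_to_polygon(rec.mask, rec.georef)
        rec.line_overlap_flag = poly.intersects(buffered)
    return records


def extract_lakes(
    occ: OccurrenceLayer,
    threshold_pct: float = DEFAULT_OCCURRENCE_THRESHOLD_PCT,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    connectivity: int = 8,
    river_threshold: float = DEFAULT_RIVER_THRESHOLD,
    pixel_area_km2: float = 0.0009,
    lines=None,
) -> list[LakeRecord]:
    """Full phase-1 run: threshold, label, size-filter, score, flag.

    Lake ids are assigned by raster-scan order of each component's first
    pixel, so identical inputs always yield identical ids.
    """
    mask = binarize_occurrence(occ, threshold_pct)
    comps = filter_by_size(label_components(mask, connectivity), min_pixels)
    records = []
    for i, comp in enumerate(comps):
        rows, cols = np.nonzero(comp)
        bbox = (int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)
        n = int(comp.sum())
        e = erosion_count(comp)
        records.append(
            LakeRecord(
                lake_id=i,
                mask=comp,
                bbox=bbox,
                n_pixels=n,
                area_km2=n * pixel_area_km2,
                erosion_count=e,
                morph_score=morphological_score(e, n),
                georef=occ.georef,
            )
        )
    flag_rivers(records, river_threshold)
    if lines is not None:
        flag_line_overlap(records, lines)
    return records
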