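"""Accuracy evaluation of water extent maps against annotated references.

A reference map labels each pixel WATER(1), LAND(0) or MASKED (annotator
excluded: clouds, ambiguous shorelines).  A predicted map may additionally
be MISSING, which is scored as 0.5 to reflect total uncertainty between
land and water.  Accuracy is 1 minus the mean absolute difference of these
encodings over valid (non-masked) reference cells, so a prediction that is
all MISSING scores exactly 0.5 against any reference.

Because most scenes are dominated by dry land that every map labels
correctly, a *restricted* variant drops pixels labelled land by the
reference and by both compared predictions, giving a stricter, less
inflated comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LAND, MISSING, WATER

#: Reference-map code for annotator-excluded pixels.
REF_MASKED = 3


def _encode(predicted: np.ndarray) -> np.ndarray:
    """WATER -> 1, LAND -> 0, MISSING -> 0.5."""
    out = np.full(predicted.shape, np.nan)
    out[predicted == WATER] = 1.0
    out[predicted == LAND] = 0.0
    out[predicted == MISSING] = 0.5
    if np.isnan(out).any():
        raise ValueError("predicted map contains codes outside {LAND, WATER, MISSING}")
    return out


def accuracy(reference: np.ndarray, predicted: np.ndarray) -> float:
    """Mean-absolute-agreement accuracy over non-masked reference cells."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted maps differ in shape")
    valid = reference != REF_MASKED
    if not valid.any():
        raise ValueError("no valid (non-masked) reference cells")
    ref = reference[valid].astype(float)
    if not np.isin(ref, (0.0, 1.0)).all():
        raise ValueError("reference cells must be LAND, WATER or MASKED")
    pred = _encode(predicted[valid])
    return float(1.0 - np.abs(ref - pred).mean())


@dataclass
class RestrictedAccuracy:
    accuracy_a: float
    accuracy_b: float
    n_pixels: int
    defined: bool


def restricted_accuracy(
    reference: np.ndarray, predicted_a: np.ndarray, predicted_b: np.ndarray
) -> RestrictedAccuracy:
    """Accuracy of both predictions after dropping triple-land pixels.

    Cells where the reference and both predictions all say LAND (plus
    masked cells) are removed; accuracies are recomputed on the survivors.
    If nothing survives the result is flagged undefined (NaN accuracies),
    not an exception.
    """
    reference = np.asarray(reference)
    if reference.shape != np.asarray(predicted_a).shape or reference.shape != np.asarray(predicted_b).shape:
        raise ValueError("maps differ in shape")
    triple_land = (reference == LAND) & (predicted_a == LAND) & (predicted_b == LAND)
    keep = (reference != REF_MASKED) & ~triple_land
    n = int(keep.sum())
    if n == 0:
        return RestrictedAccuracy(np.nan, np.nan, 0, defined=False)
    masked_ref = np.where(keep, reference, REF_MASKED)
    return RestrictedAccuracy(
        accuracy_a=accuracy(masked_ref, predicted_a),
        accuracy_b=accuracy(masked_ref, predicted_b),
        n_pixels=n,
        defined=True,
    )


def select_evaluation_maps(
    metadata: pd.DataFrame,
    max_missing_pct: float = 90.0,
    min_year: int = 2000,
    n_sample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Apply the map-selection filters used before accuracy evaluation.

    ``metadata`` needs columns year, pct_corrected, pct_imputed.  Frames
    are kept when the correction step actually changed something
    (pct_corrected + pct_imputed > 0), missing labels are not overwhelming
    (pct_imputed <= max_missing_pct, strict > excluded), and year >=
    min_year.  Optionally draws ``n_sample`` frames weighted toward
    heavily-updated maps: weights are inverse frequencies of 10-point
    update-percentage bins, so rarely-seen heavy updates are favoured.
    """
    df = metadata.copy()
    updates = df["pct_corrected"] + df["pct_imputed"]
    keep = (updates > 0) & (df["pct_imputed"] <= max_missing_pct) & (df["year"] >= min_year)
    df = df[keep]
    if n_sample is not None and len(df) > n_sample:
        upd = (df["pct_corrected"] + df["pct_imputed"]).to_numpy()
        bins = np.clip((upd // 10).astype(int), 0, 9)
        counts = np.bincount(bins, minlength=10).astype(float)
        weights = 1.0 / counts[bins]
        weights /= weights.sum()
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(df), size=n_sample, replace=False, p=weights)
        df = df.iloc[np.sort(idx)]
    return df


def accuracy_delta_histogram(
    accuracy_a: np.ndarray, accuracy_b: np.ndarray, n_bins: int = 20
) -> tuple[pd.DataFrame, float]:
    """Histogram of paired accuracy differences, excluding exact ties.

    Returns (binned counts over [-1, 1], share of positive deltas).  The
    share is NaN when every pair ties.
    """
    deltas = np.asarray(accuracy_a, dtype=float) - np.asarray(accuracy_b, dtype=float)
    deltas = deltas[deltas != 0]
    edges = np.linspace(-1, 1, n_bins + 1)
    counts, _ = np.histogram(deltas, bins=edges)
    table = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    share_positive = float((deltas > 0).mean()) if deltas.size else float("nan")
    return table, share_positive
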