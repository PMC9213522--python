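"""Per-lake quality scores and the reliability gate.

Two scores flag lakes where the single-basin ordering assumption is shaky:

* Connected Component Score (CS): time-aggregated fraction of water pixels
  outside each frame's largest connected water component,
  CS = sum_t P[t] / sum_t W[t].  An ideal single-basin lake scores 0; a
  persistently split lake approaches 1.
* Ephemeral Score (ES): number of months the lake's water count falls
  strictly below a fraction (default 10%) of its reference size.  Highly
  transient lakes carry too little signal to learn an ordering.

The published reliability gate keeps lakes with ES <= 156 and CS < 0.2
(the ES bound was tuned on 384-month series; a fractional mode rescales it
for shorter records).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .extraction import _STRUCT

logger = logging.getLogger(__name__)

DEFAULT_ES_MAX = 156
DEFAULT_CS_MAX = 0.2
DEFAULT_EPHEMERAL_FRAC = 0.10
REFERENCE_SERIES_LENGTH = 384  # months in the 1984-2015 record the ES bound was tuned on


@dataclass
class QualityScores:
    cs: float
    es: int
    reliable: bool
    n_frames: int
    penalties: np.ndarray  # P[t]
    water_counts: np.ndarray  # W[t]


def connected_component_score(
    binary_stack: np.ndarray, connectivity: int = 8
) -> tuple[float, np.ndarray, np.ndarray]:
    """Eq.-style fragmentation score: (CS, P, W).

    P[t] = water pixels outside the frame's largest component (0 for dry
    frames); CS = sum(P)/sum(W), defined as 0 for an always-dry stack (such
    a record should fail on ES, not on CS).
    """
    binary_stack = np.asarray(binary_stack, dtype=bool)
    struct = _STRUCT[connectivity]
    T = binary_stack.shape[0]
    P = np.zeros(T, dtype=np.int64)
    W = np.zeros(T, dtype=np.int64)
    for t in range(T):
        W[t] = int(binary_stack[t].sum())
        if W[t] == 0:
            continue
        lab, n = ndimage.label(binary_stack[t], structure=struct)
        largest = int(np.bincount(lab.ravel())[1:].max())
        P[t] = W[t] - largest
    total_w = int(W.sum())
    if total_w == 0:
        logger.warning("stack has no water in any frame; CS defined as 0")
        return 0.0, P, W
    return float(P.sum() / total_w), P, W


def ephemeral_score(
    water_counts: np.ndarray, reference_size: int, frac: float = DEFAULT_EPHEMERAL_FRAC
) -> int:
    """Number of timesteps with water count strictly below frac * N."""
    if reference_size < 1:
        raise ValueError("reference_size must be >= 1")
    water_counts = np.asarray(water_counts)
    return int((water_counts < frac * reference_size).sum())


def reliability_flag(
    cs: float,
    es: int,
    es_max: float = DEFAULT_ES_MAX,
    cs_max: float = DEFAULT_CS_MAX,
    fractional: bool = False,
    n_frames: int | None = None,
) -> bool:
    """Reliable iff ES <= es_max and CS < cs_max (note the mixed bounds).

    With ``fractional=True`` the ES bound is rescaled by n_frames/384 so the
    gate keeps the same *proportion* of ephemeral months on shorter series.
    """
    bound = es_max
    if fractional:
        if n_frames is None:
            raise ValueError("fractional mode needs n_frames")
        bound = es_max * n_frames / REFERENCE_SERIES_LENGTH
    return bool(es <= bound and cs < cs_max)


def score_stack(
    binary_stack: np.ndarray,
    reference_size: int,
    connectivity: int = 8,
    frac: float = DEFAULT_EPHEMERAL_FRAC,
    es_max: float = DEFAULT_ES_MAX,
    cs_max: float = DEFAULT_CS_MAX,
    fractional: bool = False,
) -> QualityScores:
    """Compute CS, ES and the reliability flag for one lake's binary stack."""
    cs, P, W = connected_component_score(binary_stack, connectivity)
    es = ephemeral_score(W, reference_size, frac)
    reliable = reliability_flag(
        cs, es, es_max=es_max, cs_max=cs_max,
        fractional=fractional, n_frames=binary_stack.shape[0],
    )
    return QualityScores(
        cs=cs, es=es, reliable=reliable,
        n_frames=binary_stack.shape[0], penalties=P, water_counts=W,
    )
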