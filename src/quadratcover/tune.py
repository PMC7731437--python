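"""Parameter-selection workflows.

The classifier is deliberately semi-automated: the thresholds g1, g2 and
the brightness multiplier d are chosen by a person, informed by two kinds
of evidence this module computes.

* :func:`explore_gv_thresholds` summarizes the normalized (G - R) and
  (G - B) differences over a user-supplied reference region known to be
  green vegetation. The *minimum* of each difference is the natural
  candidate threshold: the largest value that still admits every reference
  pixel.
* :func:`sweep_d` and :func:`sweep_g` run the classifier over a grid of
  parameter values and report the resulting covers, so the sensitivity of
  the estimate to each constant can be inspected before committing to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassificationParams, classify_image
from .imaging import NormalizedImage

__all__ = ["DiffStats", "ThresholdStats", "explore_gv_thresholds", "sweep_d", "sweep_g"]


@dataclass(frozen=True)
class DiffStats:
    """Summary statistics of one normalized band difference."""

    min: float
    max: float
    mean: float
    std: float


@dataclass(frozen=True)
class ThresholdStats:
    """Reference-region statistics guiding the choice of g1 and g2.

    ``g1`` summarizes (G - R), ``g2`` summarizes (G - B); ``min`` of each
    is the candidate threshold.
    """

    g1: DiffStats
    g2: DiffStats
    n_pixels: int


def _stats(values: np.ndarray) -> DiffStats:
    return DiffStats(
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        std=float(values.std()),
    )


def explore_gv_thresholds(
    img: NormalizedImage, reference_mask: np.ndarray
) -> ThresholdStats:
    """Band-difference statistics over known-GV reference pixels.

    The mask is user-supplied (hand-drawn, or ground truth from the
    synthetic generator); condition labels such as "high exposure" or
    "bluish leaves" are metadata the caller keeps, not something inferred
    here.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != img.shape:
        raise ValueError(
            f"reference mask shape {reference_mask.shape} does not match "
            f"image {img.shape}"
        )
    n = int(reference_mask.sum())
    if n == 0:
        raise ValueError("reference mask selects no pixels")
    gr = (img.green - img.red)[reference_mask]
    gb = (img.green - img.blue)[reference_mask]
    return ThresholdStats(g1=_stats(gr), g2=_stats(gb), n_pixels=n)


def sweep_d(
    img: NormalizedImage,
    g1: float,
    g2: float,
    d_values,
) -> pd.DataFrame:
    """SDM cover as a function of d at fixed g1, g2.

    ``d_values`` must be a non-empty, strictly monotonic sequence of
    positive values (ascending or descending); the output preserves its
    order. Columns: ``d``, ``sdm_cover_pct``.
    """
    d_values = [float(d) for d in d_values]
    if not d_values:
        raise ValueError("d_values must be non-empty")
    if any(d <= 0 for d in d_values):
        raise ValueError("all d values must be > 0")
    if len(d_values) > 1:
        diffs = np.diff(d_values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("d_values must be strictly monotonic")
    rows = []
    for d in d_values:
        _, cover = classify_image(img, ClassificationParams(g1=g1, g2=g2, d=d))
        rows.append({"d": d, "sdm_cover_pct": cover.sdm_cover})
    return pd.DataFrame(rows)


def sweep_g(
    img: NormalizedImage,
    g_pairs,
    d: float = 1.0,
) -> pd.DataFrame:
    """GV cover for each (g1, g2) pair at fixed d.

    Columns: ``g1``, ``g2``, ``gv_cover_pct``; row order follows the input.
    """
    g_pairs = list(g_pairs)
    if not g_pairs:
        raise ValueError("g_pairs must be non-empty")
    rows = []
    for g1, g2 in g_pairs:
        _, cover = classify_image(
            img, ClassificationParams(g1=float(g1), g2=float(g2), d=d)
        )
        rows.append({"g1": float(g1), "g2": float(g2), "gv_cover_pct": cover.gv_cover})
    return pd.DataFrame(rows)
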