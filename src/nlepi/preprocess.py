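"""Preprocessing: per-sample rescaling and detection-based probe filtering.

Mirrors the two (and only two) preprocessing steps applied to the condensed
chip data: every sample column is rescaled so its mean intensity is 200, and
probe sets detectable in fewer than 20% of samples are removed. No background
correction or quantile/loess normalisation is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

DEFAULT_TARGET_MEAN = 200.0
DEFAULT_MIN_DETECT_FRAC = 0.20


def rescale_samples(
    matrix: ExpressionMatrix, target_mean: float = DEFAULT_TARGET_MEAN
) -> ExpressionMatrix:
    """Multiply each sample column by a scalar so its mean equals ``target_mean``.

    Detection calls are untouched. Idempotent. Raises on an all-zero sample
    (no finite scalar exists), naming the sample.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    col_means = matrix.intensities.mean(axis=0)
    zero = col_means[col_means == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero intensities")
    scaled = matrix.intensities * (target_mean / col_means)
    return ExpressionMatrix(scaled, matrix.detection, matrix.groups, matrix.sample_meta)


def filter_detection(
    matrix: ExpressionMatrix,
    min_detect_frac: float = DEFAULT_MIN_DETECT_FRAC,
    marginal_counts_as_detected: bool = False,
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove probes detectable in < ``min_detect_frac`` of samples.

    'Detectable' means a Present call; the removal rule is a strict '<', so a
    probe at exactly the threshold fraction is retained. Marginal calls count
    as not detected unless ``marginal_counts_as_detected``. The fraction is
    computed jointly over all samples in the matrix. Returns the filtered
    matrix and the removed probe ids (kept + removed partition the input).
    """
    if not 0 <= min_detect_frac <= 1:
        raise ValueError("min_detect_frac must lie in [0, 1]")
    det = matrix.detection.to_numpy()
    detected = det == "P"
    if marginal_counts_as_detected:
        detected |= det == "M"
    frac = detected.mean(axis=1)
    keep_mask = frac >= min_detect_frac
    keep = [p for p, k in zip(matrix.probe_ids, keep_mask) if k]
    removed = [p for p, k in zip(matrix.probe_ids, keep_mask) if not k]
    return matrix.select_probes(keep), removed


def preprocess(
    matrix: ExpressionMatrix,
    target_mean: float = DEFAULT_TARGET_MEAN,
    min_detect_frac: float = DEFAULT_MIN_DETECT_FRAC,
    marginal_counts_as_detected: bool = False,
) -> tuple[ExpressionMatrix, list[str]]:
    """Rescale then filter, the order used on the condensed chip data.

    The two steps commute up to the rescaling factor: the filter ignores
    intensity values, so the removed probe set is order-independent.
    """
    scaled = rescale_samples(matrix, target_mean)
    return filter_detection(scaled, min_detect_frac, marginal_counts_as_detected)
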