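"""Structural (visibility-graph) branch.

An utterance is turned into a short positive-valued series in four steps:

1. min-max normalization to [0, 1] (see :mod:`graphser.audio_io`);
2. variable-length segmentation at gradient edges found by a 1-D adaptation
   of the Canny / Sobel / Prewitt detectors — segments stand in for
   syllable/word-scale prosodic units;
3. the mean of each segment, giving a much shorter series;
4. the standard deviation over fixed overlapping windows of that mean
   series, which is nonnegative by construction and keeps the variability.

The resulting series feeds the natural visibility graph: two samples are
connected iff the straight line between them passes strictly above every
intermediate sample.  The binary adjacency matrix of that graph is the
structural representation of the utterance.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DegenerateSignalError, ParameterError

logger = logging.getLogger(__name__)

DETECTORS = ("canny", "sobel", "prewitt")


def _central_gradient(x: np.ndarray) -> np.ndarray:
    """Response of the horizontal derivative kernel [-1, 0, 1] with reflect
    padding; both Sobel and Prewitt collapse to this kernel on a 1-row image."""
    padded = np.pad(x, 1, mode="edge")
    return padded[2:] - padded[:-2]


def _nms_1d(mag: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a nonnegative magnitude profile.

    Plateaus keep their first sample so ties break toward earlier positions.
    """
    left = np.r_[-np.inf, mag[:-1]]
    right = np.r_[mag[1:], -np.inf]
    return np.flatnonzero((mag > left) & (mag >= right))


def _merge_boundaries(candidates, n: int, min_segment_samples: int) -> np.ndarray:
    """Assemble the partition 0 < b_1 < ... < N, dropping interior boundaries
    closer than ``min_segment_samples`` to the previously kept one (the
    earlier boundary wins)."""
    kept = [0]
    for b in sorted(int(b) for b in candidates):
        if b <= 0 or b >= n:
            continue
        if b - kept[-1] >= min_segment_samples and n - b >= 1:
            kept.append(b)
    kept.append(n)
    return np.asarray(kept, dtype=np.intp)


def detect_boundaries(
    norm_series: np.ndarray,
    detector: str = "canny",
    *,
    threshold: float = 0.5,
    canny_sigma: float = 1.0,
    canny_low_pct: float = 70.0,
    canny_high_pct: float = 90.0,
    min_segment_samples: int = 2,
) -> np.ndarray:
    """Segment a unit-range series at its gradient edges.

    Returns the boundary index array ``[0, b_1, ..., N]`` defining half-open
    segments ``[b_i, b_{i+1})``.  ``sobel`` and ``prewitt`` threshold the
    absolute response of the [-1, 0, 1] derivative kernel at ``threshold``;
    ``canny`` smooths with a Gaussian of ``canny_sigma`` samples, applies
    1-D non-maximum suppression, and keeps maxima by hysteresis between the
    ``canny_low_pct`` / ``canny_high_pct`` percentiles of the gradient
    magnitude.
    """
    x = np.asarray(norm_series, dtype=np.float64)
    n = x.size
    if detector not in DETECTORS:
        raise ParameterError(f"unknown detector {detector!r}; expected one of {DETECTORS}")
    if min_segment_samples < 1:
        raise ParameterError("min_segment_samples must be >= 1")
    kernel_len = 3 if detector != "canny" else max(3, int(2 * round(4.0 * canny_sigma) + 1))
    if n < kernel_len:
        raise DegenerateSignalError(
            f"series of length {n} is shorter than the {detector} kernel ({kernel_len})"
        )

    if detector in ("sobel", "prewitt"):
        mag = np.abs(_central_gradient(x))
        candidates = np.flatnonzero(mag > threshold)
    else:
        smooth = gaussian_filter1d(x, sigma=canny_sigma, mode="nearest")
        mag = np.abs(_central_gradient(smooth))
        low = np.percentile(mag, canny_low_pct)
        high = np.percentile(mag, canny_high_pct)
        maxima = _nms_1d(mag)
        strong = mag >= high
        weak = mag >= low
        # hysteresis on the 1-D topology: a weak maximum survives iff its
        # contiguous run of weak samples contains at least one strong sample
        run_id = np.cumsum(np.r_[weak[0], np.diff(weak.astype(np.int8)) != 0])
        strong_runs = set(run_id[strong & weak].tolist())
        candidates = [i for i in maxima if weak[i] and run_id[i] in strong_runs]

    return _merge_boundaries(candidates, n, min_segment_samples)


def segment_means(series: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Mean of each segment ``[b_i, b_{i+1})`` of the partition."""
    x = np.asarray(series, dtype=np.float64)
    b = np.asarray(boundaries, dtype=np.intp)
    if b.size < 2 or b[0] != 0 or b[-1] != x.size or np.any(np.diff(b) <= 0):
        raise ParameterError(f"invalid partition {b!r} for series of length {x.size}")
    sums = np.add.reduceat(x, b[:-1])
    return sums / np.diff(b)


def sliding_sd(
    series: np.ndarray, window: int, overlap: int, *, pooling: str = "sd"
) -> np.ndarray:
    """Pool a series into one value per overlapping window.

    Windows start at 0, hop, 2*hop ... with hop = window - overlap; a
    trailing partial window is discarded.  The pooled value is the
    population standard deviation (``pooling="sd"``, the default) or the
    root-mean-square (``pooling="rms"``, kept selectable although it
    performs worse as an emotion cue).  A series shorter than one window
    collapses to a single pooled value over the whole series.
    """
    if window < 1 or overlap < 0 or overlap >= window:
        raise ParameterError(f"need 0 <= overlap < window, got window={window} overlap={overlap}")
    if pooling not in ("sd", "rms"):
        raise ParameterError(f"unknown pooling {pooling!r}")
    x = np.asarray(series, dtype=np.float64)
    if x.size == 0:
        raise ParameterError("empty series")
    pool = (lambda w: float(np.std(w))) if pooling == "sd" else (lambda w: float(np.sqrt(np.mean(w**2))))
    if x.size < window:
        return np.array([pool(x)])
    hop = window - overlap
    starts = range(0, x.size - window + 1, hop)
    return np.array([pool(x[s : s + window]) for s in starts])


def visibility_adjacency(series: np.ndarray) -> np.ndarray:
    """Binary adjacency of the natural visibility graph of a nonnegative series.

    Nodes are the samples ``(x_i, i)``; nodes i < j are connected iff every
    intermediate sample k satisfies ``x_k < x_i + (x_j - x_i) * (k - i) / (j - i)``,
    i.e. lies strictly below the chord.  Immediate neighbors are always
    visible and the diagonal is zero.  Runs in O(n^2) by sweeping j for each
    i while tracking the maximum intermediate chord slope.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ParameterError("series must be a 1-D array of length >= 1")
    if np.any(x < 0):
        raise ParameterError("visibility graph requires a nonnegative series")
    n = x.size
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
        max_slope = -np.inf
        for j in range(i + 1, n):
            slope = (x[j] - x[i]) / (j - i)
            if slope > max_slope:
                # chord from i to j clears every intermediate point
                a[i, j] = a[j, i] = 1
            max_slope = max(max_slope, slope)
    return a


def structural_adjacency(
    norm_samples: np.ndarray,
    *,
    detector: str = "canny",
    threshold: float = 0.5,
    canny_sigma: float = 1.0,
    canny_low_pct: float = 70.0,
    canny_high_pct: float = 90.0,
    min_segment_samples: int = 2,
    window: int = 50,
    overlap: int = 25,
    pooling: str = "sd",
    utterance_id: str = "",
) -> np.ndarray:
    """Full structural chain: boundaries -> segment means -> sliding SD -> VG.

    ``norm_samples`` must already be min-max normalized to [0, 1].  If the
    pooled series would have fewer than 3 points, the whole mean series is
    pooled as a single window (logged) so a tiny graph is still produced.
    """
    boundaries = detect_boundaries(
        norm_samples,
        detector,
        threshold=threshold,
        canny_sigma=canny_sigma,
        canny_low_pct=canny_low_pct,
        canny_high_pct=canny_high_pct,
        min_segment_samples=min_segment_samples,
    )
    means = segment_means(norm_samples, boundaries)
    pooled = sliding_sd(means, window, overlap, pooling=pooling)
    if pooled.size < 3:
        logger.warning(
            "utterance %s: pooled series has %d point(s); using one window over "
            "the whole mean series (%d segments)",
            utterance_id or "<unnamed>",
            pooled.size,
            means.size,
        )
        pooled = sliding_sd(means, max(means.size, 1), 0, pooling=pooling)
    return visibility_adjacency(pooled)
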