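"""Statistical (correlation-graph) branch.

The raw utterance is split into overlapping fixed-length windows and every
pair of windows is compared with Pearson's correlation; the absolute
correlations form a weighted adjacency matrix in [0, 1].  Fixed-length
windows are required because Pearson correlation compares vectors of equal
length.  The branch operates on raw (unnormalized) samples: correlation is
invariant to affine amplitude transforms, so per-utterance normalization
would be a no-op.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import DegenerateSignalError, ParameterError

logger = logging.getLogger(__name__)


def fixed_windows(samples: np.ndarray, window: int, overlap: int) -> np.ndarray:
    """Split a signal into overlapping windows of exactly ``window`` samples.

    Windows start at 0, hop, 2*hop ... (hop = window - overlap); the trailing
    partial window is discarded.  Returns an (L, window) array.
    """
    if window < 1 or overlap < 0 or overlap >= window:
        raise ParameterError(f"need 0 <= overlap < window, got window={window} overlap={overlap}")
    x = np.asarray(samples, dtype=np.float64)
    if x.size < window:
        raise DegenerateSignalError(
            f"signal of {x.size} samples is shorter than one window ({window})"
        )
    hop = window - overlap
    starts = np.arange(0, x.size - window + 1, hop)
    return np.stack([x[s : s + window] for s in starts])


def correlation_adjacency(windows: np.ndarray) -> np.ndarray:
    """Weighted adjacency |Pearson r| between all window pairs, diagonal zeroed.

    A window with zero variance has no defined correlation; it contributes 0
    to all its pairs (logged) so a long stretch of silence does not abort the
    utterance.
    """
    w = np.asarray(windows, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] < 2:
        raise DegenerateSignalError(
            f"need at least 2 equal-length windows, got shape {getattr(w, 'shape', None)}"
        )
    sd = w.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning("%d zero-variance window(s) set to zero correlation", flat.size)
    centered = w - w.mean(axis=1, keepdims=True)
    denom = sd.copy()
    denom[flat] = 1.0  # avoid 0/0; the rows are zeroed below
    r = (centered @ centered.T) / w.shape[1] / np.outer(denom, denom)
    a = np.abs(r)
    a[flat, :] = 0.0
    a[:, flat] = 0.0
    np.fill_diagonal(a, 0.0)
    # |r| can exceed 1 by float round-off only
    return np.clip(a, 0.0, 1.0)


def statistical_adjacency(
    samples: np.ndarray, *, window: int = 8000, overlap: int = 6000
) -> np.ndarray:
    """Full statistical chain: fixed windows -> absolute Pearson adjacency."""
    return correlation_adjacency(fixed_windows(samples, window, overlap))
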