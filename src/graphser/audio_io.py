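"""Audio and label-table I/O.

Reads PCM WAV utterances (mono or stereo; stereo is mixed down by channel
averaging), resamples with a band-limited polyphase filter, and provides the
per-utterance min-max normalization to [0, 1] required by the structural
(visibility-graph) branch of the pipeline.  The statistical branch operates
on raw samples because Pearson correlation is affine-invariant.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AudioFormatError, DegenerateSignalError, ParameterError, SchemaError

LABEL_COLUMNS = ["utterance_id", "path", "speaker_id", "emotion"]


@dataclass
class Utterance:
    """One recorded speech segment with a single speaker and emotion label.

    ``samples`` are dimensionless amplitudes (floats, typically in [-1, 1]
    after 16-bit PCM decoding); ``sample_rate_hz`` is the sampling frequency.
    """

    utterance_id: str
    samples: np.ndarray
    sample_rate_hz: int
    speaker_id: str = ""
    emotion: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError(
                f"utterance {self.utterance_id!r}: samples must be a 1-D array "
                f"of length >= 2, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError(
                f"utterance {self.utterance_id!r}: samples contain non-finite values"
            )
        if not (isinstance(self.sample_rate_hz, (int, np.integer)) and self.sample_rate_hz > 0):
            raise ParameterError(
                f"utterance {self.utterance_id!r}: sample_rate_hz must be a "
                f"positive integer, got {self.sample_rate_hz!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


# peak value per PCM sample width used to scale integers to [-1, 1)
_PCM_SCALE = {np.dtype(np.int16): 2.0**15, np.dtype(np.int32): 2.0**31, np.dtype(np.uint8): 2.0**7}


def read_wave(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file, returning (mono float samples, sample rate).

    Stereo input is mixed down by averaging the channels.  Integer PCM
    (8/16/24/32-bit) is scaled to [-1, 1); float WAV is passed through.
    """
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError, EOFError, struct.error) as exc:
        raise AudioFormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"cannot read {path}: file contains no samples")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64)
        if data.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
            samples -= 128.0
        samples /= _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    elif samples.ndim != 1:
        raise AudioFormatError(f"cannot read {path}: unsupported shape {data.shape}")
    return samples, int(rate)


def write_wave(path, samples: np.ndarray, rate_hz: int) -> None:
    """Write mono float samples as 16-bit PCM WAV, clipping to [-1, 1]."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(rate_hz), pcm)


def load_utterance(utterance_id, path, speaker_id="", emotion="") -> Utterance:
    samples, rate = read_wave(path)
    return Utterance(str(utterance_id), samples, rate, str(speaker_id), str(emotion))


def resample(utt: Utterance, target_hz: int) -> Utterance:
    """Band-limited resampling to ``target_hz``.

    The output length is ``round(n * target_hz / source_hz)``; a pure tone
    below the Nyquist frequency keeps its frequency.
    """
    if not target_hz > 0:
        raise ParameterError(f"target_hz must be positive, got {target_hz}")
    target_hz = int(target_hz)
    if target_hz == utt.sample_rate_hz:
        return utt
    g = math.gcd(target_hz, utt.sample_rate_hz)
    up, down = target_hz // g, utt.sample_rate_hz // g
    y = resample_poly(utt.samples, up, down)
    n_out = round(utt.samples.size * target_hz / utt.sample_rate_hz)
    if y.size > n_out:
        y = y[:n_out]
    elif y.size < n_out:
        y = np.pad(y, (0, n_out - y.size))
    return Utterance(utt.utterance_id, y, target_hz, utt.speaker_id, utt.emotion)


def to_unit_range(samples: np.ndarray) -> np.ndarray:
    """Min-max normalize a signal to [0, 1].

    This is the per-utterance normalization feeding the edge detectors of
    the structural branch (they expect grayscale-like input).  A constant
    signal has no defined normalization and raises
    :class:`DegenerateSignalError`.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ParameterError(f"need at least 2 samples, got {x.size}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError("constant signal cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def read_labels(path) -> pd.DataFrame:
    """Read the corpus label table (CSV: utterance_id,path,speaker_id,emotion)."""
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"label table {path} is missing columns: {missing}")
    if table.empty:
        raise SchemaError(f"label table {path} has no rows")
    if table["utterance_id"].duplicated().any():
        dup = table.loc[table["utterance_id"].duplicated(), "utterance_id"].iloc[0]
        raise SchemaError(f"duplicate utterance_id {dup!r} in {path}")
    return table[LABEL_COLUMNS]
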