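"""Speaker-based emotional motif.

Rather than classifying single utterances, all utterances one speaker
produced under one emotion are collapsed into a single 44-value signature:
the first four probabilistic moments (mean, standard deviation, skewness,
kurtosis) of each of the 11 graph features over that group's m utterances.
This sidesteps both per-class utterance imbalance and unequal utterance
lengths, and gives each speaker-emotion pair a unique identity the
classifier operates on.

Conventions: sigma uses the population (1/m) divisor; kurtosis is plain
(E[z^4], no -3 excess correction); a zero-variance group gets skewness and
kurtosis 0 so single-utterance groups stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError, SchemaError
from .features import FEATURE_NAMES

MOMENT_NAMES = ["mean", "sd", "skew", "kurt"]
MOTIF_COLUMNS = [f"{feat}_{mom}" for feat in FEATURE_NAMES for mom in MOMENT_NAMES]
GROUP_COLUMNS = ["speaker_id", "emotion"]


def four_moments(values) -> tuple[float, float, float, float]:
    """(mean, population SD, skewness, plain kurtosis) of a 1-D sample."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("four_moments needs a non-empty 1-D array")
    mu = x.mean()
    sigma = np.sqrt(np.mean((x - mu) ** 2))
    if sigma == 0:
        return float(mu), 0.0, 0.0, 0.0
    z = (x - mu) / sigma
    return float(mu), float(sigma), float(np.mean(z**3)), float(np.mean(z**4))


def moment_columns(feature: str) -> list[str]:
    """The four motif columns a single graph feature contributes."""
    if feature not in FEATURE_NAMES:
        raise ParameterError(f"unknown feature {feature!r}")
    return [f"{feature}_{mom}" for mom in MOMENT_NAMES]


def build_motifs(features: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an utterance feature table into one motif row per
    (speaker_id, emotion) group.

    Output columns: speaker_id, emotion, m (utterances aggregated) and the
    44 feature-moment values.
    """
    required = GROUP_COLUMNS + FEATURE_NAMES
    missing = [c for c in required if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    if features.empty:
        raise SchemaError("feature table has no rows")
    rows = []
    for (speaker, emotion), group in features.groupby(GROUP_COLUMNS, sort=True):
        row: dict = {"speaker_id": speaker, "emotion": emotion, "m": len(group)}
        for feat in FEATURE_NAMES:
            mu, sd, skew, kurt = four_moments(group[feat].to_numpy())
            row.update({f"{feat}_mean": mu, f"{feat}_sd": sd,
                        f"{feat}_skew": skew, f"{feat}_kurt": kurt})
        rows.append(row)
    return pd.DataFrame(rows, columns=GROUP_COLUMNS + ["m"] + MOTIF_COLUMNS)


class MotifAggregator(BaseEstimator, TransformerMixin):
    """scikit-learn transformer wrapping :func:`build_motifs`."""

    def fit(self, X=None, y=None):
        self.n_features_out_ = len(MOTIF_COLUMNS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return build_motifs(X)
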