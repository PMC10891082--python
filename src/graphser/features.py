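"""Graph features and the 11-element utterance feature vector.

Six scalar descriptors are read off an adjacency matrix A (structural binary
or statistical weighted):

- degree of connectivity DoC = sum_ij A_ij (a global scalar; for a binary
  graph this is 2|E|);
- global clustering coefficient CC = mean_i CC_i with
  CC_i = (A^3)_ii / (k_i (k_i - 1)), k_i the (weighted) degree, CC_i = 0
  when k_i <= 1;
- density D = 2|E| / (N (N - 1)) with an edge counted for every strictly
  positive entry;
- averaged value M = mean over all N^2 entries (zero diagonal included);
- modularity Q maximized by deterministic greedy agglomeration, evaluated
  as Q = sum_c (e_cc - a_c^2);
- energy E = sum_i lambda_i^2 of the adjacency spectrum.  Note this is the
  sum of *squared* eigenvalues (equal to trace(A^2)), not the classical
  graph energy sum_i |lambda_i|.

An utterance contributes all six from its structural (visibility) graph and
the first five from its statistical (correlation) graph; energy from the
correlation graph carries no extra class information and is omitted, giving
the 11 named features below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from sklearn.base import BaseEstimator, TransformerMixin

from .audio_io import Utterance, load_utterance, resample, to_unit_range
from .config import PipelineConfig
from .errors import DegenerateSignalError, ParameterError
from .statistical import statistical_adjacency
from .structural import structural_adjacency

logger = logging.getLogger(__name__)

STRUCTURAL_FEATURES = ["struct_DoC", "struct_CC", "struct_D", "struct_M", "struct_Q", "struct_E"]
STATISTICAL_FEATURES = ["stat_DoC", "stat_CC", "stat_D", "stat_M", "stat_Q"]
FEATURE_NAMES = STRUCTURAL_FEATURES + STATISTICAL_FEATURES
ID_COLUMNS = ["utterance_id", "speaker_id", "emotion"]


def _check_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError(f"adjacency must be square, got shape {a.shape}")
    if np.any(a < 0) or not np.allclose(a, a.T) or np.any(np.diag(a) != 0):
        raise ParameterError("adjacency must be symmetric, nonnegative, zero-diagonal")
    return a


def total_degree(a: np.ndarray) -> float:
    """Degree of connectivity: the grand sum of adjacency entries."""
    return float(_check_adjacency(a).sum())


def global_clustering(a: np.ndarray) -> float:
    """Mean local clustering coefficient, weights used verbatim."""
    a = _check_adjacency(a)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a)
    cc = np.zeros(a.shape[0])
    ok = k > 1
    cc[ok] = triangles[ok] / (k[ok] * (k[ok] - 1.0))
    return float(cc.mean())


def density(a: np.ndarray, *, edge_threshold: float = 0.0) -> float:
    """2|E| / (N(N-1)); any entry strictly above ``edge_threshold`` is an edge."""
    a = _check_adjacency(a)
    n = a.shape[0]
    if n < 2:
        logger.warning("density undefined for %d-node graph; returning 0", n)
        return 0.0
    n_edges = int(np.count_nonzero(np.triu(a, 1) > edge_threshold))
    return 2.0 * n_edges / (n * (n - 1))


def averaged_value(a: np.ndarray) -> float:
    """Mean over all N^2 adjacency entries (zero diagonal included)."""
    return float(_check_adjacency(a).mean())


def modularity_of_partition(a: np.ndarray, communities) -> float:
    """Q = sum_c (e_cc - a_c^2), with e and a as edge-mass fractions.

    ``communities`` is an iterable of node-index collections covering all
    nodes.  Edge mass is the adjacency weight; 2m is the grand sum.
    """
    a = _check_adjacency(a)
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        idx = np.fromiter(comm, dtype=np.intp)
        e_cc = a[np.ix_(idx, idx)].sum() / two_m
        a_c = a[idx, :].sum() / two_m
        q += e_cc - a_c**2
    return float(q)


def best_modularity(a: np.ndarray) -> tuple[float, list[set]]:
    """Maximized modularity and its partition.

    Community detection is deterministic greedy agglomeration (CNM);
    a graph with zero total weight gets Q = 0 on the singleton partition.
    """
    a = _check_adjacency(a)
    n = a.shape[0]
    if a.sum() == 0:
        logger.warning("zero-weight graph: modularity defined as 0 on singletons")
        return 0.0, [{i} for i in range(n)]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    rows, cols = np.nonzero(np.triu(a, 1))
    graph.add_weighted_edges_from((int(i), int(j), float(a[i, j])) for i, j in zip(rows, cols))
    if n == 1:
        return 0.0, [{0}]
    communities = [set(c) for c in greedy_modularity_communities(graph, weight="weight")]
    return modularity_of_partition(a, communities), communities


def graph_energy(a: np.ndarray) -> float:
    """Sum of squared adjacency eigenvalues (= trace(A^2))."""
    a = _check_adjacency(a)
    eigenvalues = np.linalg.eigvalsh(a)
    return float(np.sum(eigenvalues**2))


@dataclass
class UtteranceFeatures:
    """The 11 graph features of one utterance, plus its identity fields."""

    utterance_id: str
    speaker_id: str
    emotion: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if sorted(self.values) != sorted(FEATURE_NAMES):
            raise ParameterError(f"expected the 11 features {FEATURE_NAMES}, got {sorted(self.values)}")

    def as_row(self) -> dict:
        row = {"utterance_id": self.utterance_id, "speaker_id": self.speaker_id,
               "emotion": self.emotion}
        row.update({name: self.values[name] for name in FEATURE_NAMES})
        return row


def features_from_adjacency(a: np.ndarray, *, with_energy: bool) -> list[float]:
    feats = [
        total_degree(a),
        global_clustering(a),
        density(a),
        averaged_value(a),
        best_modularity(a)[0],
    ]
    if with_energy:
        feats.append(graph_energy(a))
    return feats


def utterance_features(utt: Utterance, config: PipelineConfig | None = None) -> UtteranceFeatures:
    """Run both branches on one utterance and assemble the 11-value vector."""
    cfg = config or PipelineConfig()
    if cfg.target_rate_hz is not None:
        utt = resample(utt, cfg.target_rate_hz)
    try:
        a1 = structural_adjacency(
            to_unit_range(utt.samples),
            detector=cfg.detector,
            threshold=cfg.threshold,
            canny_sigma=cfg.canny_sigma,
            canny_low_pct=cfg.canny_low_pct,
            canny_high_pct=cfg.canny_high_pct,
            min_segment_samples=cfg.min_segment_samples,
            window=cfg.struct_window,
            overlap=cfg.struct_overlap,
            pooling=cfg.pooling,
            utterance_id=utt.utterance_id,
        )
        a2 = statistical_adjacency(
            utt.samples, window=cfg.stat_window, overlap=cfg.stat_overlap
        )
    except DegenerateSignalError as exc:
        raise DegenerateSignalError(f"utterance {utt.utterance_id!r}: {exc}") from exc
    struct_vals = features_from_adjacency(a1, with_energy=True)
    stat_vals = features_from_adjacency(a2, with_energy=False)
    values = dict(zip(STRUCTURAL_FEATURES, struct_vals)) | dict(zip(STATISTICAL_FEATURES, stat_vals))
    return UtteranceFeatures(utt.utterance_id, utt.speaker_id, utt.emotion, values)


class GraphFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transform utterances into the 11-column graph-feature table.

    A stateless scikit-learn transformer: ``fit`` only validates parameters,
    ``transform`` maps a list of :class:`Utterance` (or a label DataFrame
    with paths) to a feature DataFrame, skipping and logging utterances the
    branches reject as degenerate.

    Parameters mirror :class:`graphser.config.PipelineConfig`.
    """

    def __init__(self, detector="canny", threshold=0.5, canny_sigma=1.0,
                 canny_low_pct=70.0, canny_high_pct=90.0, min_segment_samples=2,
                 struct_window=50, struct_overlap=25, pooling="sd",
                 stat_window=8000, stat_overlap=6000, target_rate_hz=None):
        self.detector = detector
        self.threshold = threshold
        self.canny_sigma = canny_sigma
        self.canny_low_pct = canny_low_pct
        self.canny_high_pct = canny_high_pct
        self.min_segment_samples = min_segment_samples
        self.struct_window = struct_window
        self.struct_overlap = struct_overlap
        self.pooling = pooling
        self.stat_window = stat_window
        self.stat_overlap = stat_overlap
        self.target_rate_hz = target_rate_hz

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            detector=self.detector, threshold=self.threshold,
            canny_sigma=self.canny_sigma, canny_low_pct=self.canny_low_pct,
            canny_high_pct=self.canny_high_pct,
            min_segment_samples=self.min_segment_samples,
            struct_window=self.struct_window, struct_overlap=self.struct_overlap,
            pooling=self.pooling, stat_window=self.stat_window,
            stat_overlap=self.stat_overlap, target_rate_hz=self.target_rate_hz,
        )

    def fit(self, X=None, y=None):
        self._config()  # raises ParameterError on inconsistent settings
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of Utterance, or a label DataFrame with a ``path`` column."""
        self.fit()
        cfg = self._config()
        rows, skipped = [], []
        for utt in self._iter_utterances(X):
            try:
                rows.append(utterance_features(utt, cfg).as_row())
            except DegenerateSignalError as exc:
                skipped.append(utt.utterance_id)
                logger.warning("skipping: %s", exc)
        self.skipped_ = skipped
        return pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)

    @staticmethod
    def _iter_utterances(X):
        if isinstance(X, pd.DataFrame):
            for row in X.itertuples(index=False):
                yield load_utterance(row.utterance_id, row.path, row.speaker_id, row.emotion)
        else:
            yield from X


def extract_features(utterances, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`GraphFeatureExtractor`."""
    cfg = (config or PipelineConfig()).to_dict()
    cfg = {k: v for k, v in cfg.items() if k not in ("n_trees", "seed")}
    return GraphFeatureExtractor(**cfg).fit().transform(utterances)
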