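import numpy as np
import pandas as pd
import pytest

import graphser as g
from graphser.features import FEATURE_NAMES
from graphser.motif import MOTIF_COLUMNS


def synthetic_motifs(rng, n_speakers=6, emotions=("ang", "neu", "sad"),
                     noise=0.1, informative=None):
    """Motif table with class-coded means; ``informative`` restricts which of
    the 11 features carry signal (others are constant)."""
    informative = set(informative if informative is not None else FEATURE_NAMES)
    rows = []
    for s in range(n_speakers):
        for e_idx, emo in enumerate(emotions):
            row = {"speaker_id": f"s{s}", "emotion": emo, "m": 5}
            for col in MOTIF_COLUMNS:
                feat = col.rsplit("_", 1)[0]
                center = float(e_idx) if feat in informative else 0.0
                row[col] = center + noise * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestUar:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            ([[10, 0], [0, 10]], 1.0),
            ([[8, 2], [5, 5]], 0.65),
            ([[0, 0], [0, 10]], 1.0),  # class without true instances excluded
        ],
    )
    def test_examples(self, cm, expected):
        assert g.uar(np.array(cm)) == pytest.approx(expected)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(g.ParameterError):
            g.uar(np.zeros((3, 3)))

    def test_random_predictor_scores_near_chance(self, rng):
        n_classes, n_per = 4, 500
        true = np.repeat(np.arange(n_classes), n_per)
        pred = rng.integers(0, n_classes, true.size)
        cm = np.zeros((n_classes, n_classes), int)
        np.add.at(cm, (true, pred), 1)
        se = np.sqrt((1 / n_classes) * (1 - 1 / n_classes) / n_per)
        assert g.uar(cm) == pytest.approx(1 / n_classes, abs=3 * se)


class TestLosocv:
    def test_fold_structure_and_no_speaker_leakage(self, rng):
        motifs = synthetic_motifs(rng, n_speakers=8)
        result = g.losocv(motifs, n_trees=50, seed=0)
        assert len(result.folds) == 8
        speakers = [f["speaker"] for f in result.folds]
        assert sorted(speakers) == sorted(motifs["speaker_id"].unique())
        assert sum(len(f["true"]) for f in result.folds) == len(motifs)
        assert result.confusion.sum() == len(motifs)

    def test_separable_classes_reach_perfect_uar(self, rng):
        motifs = synthetic_motifs(rng, noise=0.01)
        assert g.losocv(motifs, n_trees=50, seed=0).uar == 1.0

    def test_same_seed_is_bit_reproducible(self, rng):
        motifs = synthetic_motifs(rng, noise=1.0)
        r1 = g.losocv(motifs, n_trees=50, seed=9)
        r2 = g.losocv(motifs, n_trees=50, seed=9)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.folds == r2.folds
        assert r1.uar == r2.uar

    def test_single_speaker_rejected(self, rng):
        motifs = synthetic_motifs(rng, n_speakers=1)
        with pytest.raises(g.ConfigurationError):
            g.losocv(motifs)

    def test_fold_with_single_training_class_rejected(self, rng):
        motifs = synthetic_motifs(rng, n_speakers=2)
        # leave speaker s0 with both classes, but s1 with only one:
        motifs = motifs[~((motifs.speaker_id == "s1") & (motifs.emotion != "ang"))]
        with pytest.raises(g.ConfigurationError, match="class"):
            g.losocv(motifs)

    def test_result_serializes_to_json_types(self, rng):
        import json

        motifs = synthetic_motifs(rng)
        payload = g.losocv(motifs, n_trees=20, seed=0).to_dict()
        json.dumps(payload)  # must not raise
        assert set(payload) >= {"labels", "folds", "confusion", "uar",
                                "f1_macro", "specificity_macro"}


class TestAblation:
    def test_all_group_equals_plain_losocv(self, rng):
        motifs = synthetic_motifs(rng, noise=0.5)
        plain = g.losocv(motifs, n_trees=40, seed=2).uar
        assert g.ablation(motifs, {"all": list(FEATURE_NAMES)},
                          n_trees=40, seed=2)["all"] == pytest.approx(plain)

    def test_builtin_groups_cover_branches_and_leave_one_out(self):
        groups = g.builtin_groups()
        assert len(groups) == 3 + 11
        assert len(groups["structural"]) == 6
        assert len(groups["statistical"]) == 5
        assert all(len(v) == 10 for k, v in groups.items() if k.startswith("minus_"))

    def test_unknown_feature_rejected(self, rng):
        motifs = synthetic_motifs(rng)
        with pytest.raises(g.ParameterError):
            g.ablation(motifs, {"bad": ["struct_XX"]})

    def test_uninformative_feature_scores_near_chance(self, rng):
        # struct_Q carries no class signal; the other features do
        motifs = synthetic_motifs(rng, n_speakers=8, noise=0.05,
                                  informative=set(FEATURE_NAMES) - {"struct_Q"})
        scores = g.ablation(motifs, {"only_q": ["struct_Q"]}, n_trees=100, seed=0)
        assert scores["only_q"] == pytest.approx(1 / 3, abs=0.15)
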