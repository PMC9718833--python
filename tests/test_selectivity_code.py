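"""Discriminant model, composite scores, code extraction, projections."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gpcrcontacts.errors import (
    AlignmentError,
    DataError,
    DegenerateModelError,
    ParameterError,
)
from gpcrcontacts.fingerprints import (
    CLASSES,
    FingerprintMatrix,
    classify_persistence,
    frequencies,
)
from gpcrcontacts.selectivity_code import (
    LDAModel,
    class_mean_frequencies,
    compare_position_subsets,
    composite_scores,
    extract_code,
    fit_lda,
    holdout_accuracy,
    project_and_classify,
)
from gpcrcontacts.synthetic import PlantedSpec, generate_fingerprints

from conftest import SEPARABLE_SPEC


def matrix_from_probs(probs_by_class, n_frames=300, seed=0, pairs=None):
    """Bernoulli fingerprint matrix with one system per class."""
    rng = np.random.default_rng(seed)
    n_pairs = len(next(iter(probs_by_class.values())))
    pairs = pairs or [f"p{i:02d}" for i in range(n_pairs)]
    blocks, sys_ids, labels = [], [], []
    for cls in CLASSES:
        p = np.asarray(probs_by_class[cls], float)
        blocks.append((rng.random((n_frames, n_pairs)) < p).astype(np.uint8))
        sys_ids += [f"{cls}_1"] * n_frames
        labels += [cls] * n_frames
    return FingerprintMatrix(
        pairs=pairs,
        data=np.vstack(blocks),
        system_ids=np.asarray(sys_ids, dtype=object),
        class_labels=np.asarray(labels, dtype=object),
        frame_ids=np.arange(3 * n_frames),
    )


class TestFit:
    def test_separating_feature_gets_largest_class_weight(self):
        """One near-diagnostic feature per class dominates that class's weights."""
        probs = {
            "Gs": [0.9, 0.05, 0.05, 0.3],
            "Gi": [0.05, 0.9, 0.05, 0.3],
            "Gq": [0.05, 0.05, 0.9, 0.3],
        }
        m = fit_lda(matrix_from_probs(probs, seed=1))
        for j, cls in enumerate(CLASSES):
            w = np.abs(m.weights(cls))
            assert int(np.argmax(w)) == j  # exhaustive comparison over features

    def test_identical_classes_collapse_one_axis(self):
        """Gs and Gi drawn from one distribution: the second discriminant
        carries far less variance than under a genuine 3-class structure."""
        same = [0.6, 0.1, 0.5, 0.2, 0.3]
        merged = fit_lda(
            matrix_from_probs({"Gs": same, "Gi": same, "Gq": [0.1, 0.7, 0.1, 0.6, 0.3]}, seed=2)
        )
        distinct = fit_lda(
            matrix_from_probs(
                {"Gs": same, "Gi": [0.9, 0.5, 0.1, 0.7, 0.1], "Gq": [0.1, 0.7, 0.1, 0.6, 0.3]},
                seed=2,
            )
        )
        assert merged.explained_variance_ratio[1] < 0.05
        assert merged.explained_variance_ratio[1] < distinct.explained_variance_ratio[1]

    def test_single_class_is_degenerate(self, planted_default):
        m = planted_default.matrix
        with pytest.raises(DegenerateModelError):
            fit_lda(m, labels=np.asarray(["Gs"] * m.n_rows, dtype=object))

    def test_all_constant_features_are_a_rank_error(self):
        m = matrix_from_probs({"Gs": [1.0], "Gi": [1.0], "Gq": [1.0]}, n_frames=5)
        with pytest.raises(DegenerateModelError):
            fit_lda(m)

    def test_explained_variance_ratios_sum_to_one(self, planted_default):
        m = fit_lda(planted_default.matrix)
        assert m.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert (m.explained_variance_ratio >= 0).all()
        assert m.scalings.shape[1] == 2

    def test_components_orthogonal_in_within_class_metric(self, planted_default):
        X = planted_default.matrix.data.astype(float)
        y = planted_default.matrix.class_labels
        m = fit_lda(planted_default.matrix)
        Sw = np.zeros((X.shape[1], X.shape[1]))
        for cls in CLASSES:
            Xc = X[y == cls]
            d = Xc - Xc.mean(axis=0)
            Sw += d.T @ d
        Sw /= len(y) - len(CLASSES)
        M = m.scalings.T @ Sw @ m.scalings
        assert abs(M[0, 1]) < 1e-8 and abs(M[1, 0]) < 1e-8

    def test_refit_is_deterministic(self, planted_default):
        m1 = fit_lda(planted_default.matrix)
        m2 = fit_lda(planted_default.matrix)
        np.testing.assert_array_equal(m1.scalings, m2.scalings)
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_duplicating_every_frame_keeps_the_discriminant_directions(
        self, planted_default
    ):
        m1 = fit_lda(planted_default.matrix)
        src = planted_default.matrix
        dup = FingerprintMatrix(
            pairs=src.pairs,
            data=np.vstack([src.data, src.data]),
            system_ids=np.concatenate([src.system_ids] * 2),
            class_labels=np.concatenate([src.class_labels] * 2),
            frame_ids=np.arange(2 * src.n_rows),
        )
        m2 = fit_lda(dup)
        # identical directions and signs; normalization is n-dependent
        for j in range(2):
            a, b = m1.scalings[:, j], m2.scalings[:, j]
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(m1.scalings, m2.scalings, rtol=1e-2)

    def test_json_round_trip_preserves_predictions(self, tmp_path, planted_default):
        m = fit_lda(planted_default.matrix)
        p = tmp_path / "model.json"
        m.to_json(p)
        again = LDAModel.from_json(p)
        X = planted_default.matrix.data[:50].astype(float)
        np.testing.assert_array_equal(m.predict(X), again.predict(X))
        np.testing.assert_allclose(m.transform(X), again.transform(X))


class TestHoldout:
    def test_separable_data_classifies_perfectly(self):
        planted = generate_fingerprints(PlantedSpec(seed=11, **SEPARABLE_SPEC))
        acc = holdout_accuracy(planted.matrix, seed=11)
        # oracle: nearest class mean on the raw binary features
        X = planted.matrix.data.astype(float)
        y = planted.matrix.class_labels
        means = {c: X[y == c].mean(axis=0) for c in CLASSES}
        pred = np.asarray(
            [min(CLASSES, key=lambda c: np.linalg.norm(x - means[c])) for x in X],
            dtype=object,
        )
        assert (pred == y).mean() > 0.99
        assert acc == 1.0

    def test_permuted_labels_fall_to_chance(self, planted_default):
        """3000 frames, labels shuffled: holdout accuracy ≈ 1/3."""
        m = planted_default.matrix
        assert m.n_rows >= 3000
        rng = np.random.default_rng(99)
        acc = holdout_accuracy(m, labels=rng.permutation(m.class_labels), seed=7)
        assert acc == pytest.approx(1 / 3, abs=0.05)


class TestCompositeScores:
    def _toy_model_and_freq(self, seed=3):
        planted = generate_fingerprints(
            PlantedSpec(n_background_pairs=11, seed=seed)  # 11+9+5 = 25 pairs
        )
        model = fit_lda(planted.matrix)
        freq = frequencies(planted.matrix)
        fbc = class_mean_frequencies(freq, planted.system_to_class)
        return planted, model, fbc

    def test_wgx_is_the_weight_frequency_product(self):
        _, model, fbc = self._toy_model_and_freq()
        scores = composite_scores(model, fbc)
        for _, row in scores.sample(25, random_state=0).iterrows():
            assert row["wGx"] == pytest.approx(row["weight"] * row["cGx"])

    def test_zero_frequency_zeroes_the_composite(self):
        _, model, fbc = self._toy_model_and_freq()
        fbc.iloc[:, 0] = 0.0
        scores = composite_scores(model, fbc)
        target = scores[scores["pair_key"] == fbc.columns[0]]
        assert (target["wGx"] == 0.0).all()

    def test_ranking_matches_oracle_sort(self):
        _, model, fbc = self._toy_model_and_freq()
        scores = composite_scores(model, fbc)
        for cls in CLASSES:
            sub = scores[scores["class"] == cls]
            # recompute ordering independently: descending wGx, |w|, then key
            oracle_keys = sorted(
                sub.itertuples(),
                key=lambda r: (-r.wGx, -abs(r.weight), r.pair_key),
            )
            assert [r.pair_key for r in oracle_keys] == list(
                sub.sort_values("rank")["pair_key"]
            )

    def test_universe_mismatch_is_an_alignment_error(self):
        _, model, fbc = self._toy_model_and_freq()
        with pytest.raises(AlignmentError):
            composite_scores(model, fbc.rename(columns={fbc.columns[0]: "zz"}))

    def test_cgx_lies_in_unit_interval_and_ranks_are_permutations(self):
        _, model, fbc = self._toy_model_and_freq()
        scores = composite_scores(model, fbc)
        assert scores["cGx"].between(0, 1).all()
        n = scores["pair_key"].nunique()
        for cls in CLASSES:
            ranks = sorted(scores.loc[scores["class"] == cls, "rank"])
            assert ranks == list(range(1, n + 1))


class TestExtractCode:
    def test_planted_specific_pairs_reach_their_class_top10(self, planted_separable):
        model = fit_lda(planted_separable.matrix)
        freq = frequencies(planted_separable.matrix)
        fbc = class_mean_frequencies(freq, planted_separable.system_to_class)
        labels = classify_persistence(freq, planted_separable.system_to_class)
        code = extract_code(composite_scores(model, fbc), k=10, persistence=labels)
        for cls in CLASSES:
            top = set(code.loc[code["class"] == cls, "pair_key"])
            planted_pairs = set(planted_separable.pairs_with_role(f"specific-{cls}"))
            assert planted_pairs <= top
        assert len(code) == 30

    def test_k_of_one_on_single_pair_universe(self):
        scores = pd.DataFrame(
            [
                {"class": c, "pair_key": "3x50:G.H5.10", "weight": 1.0, "cGx": 0.5, "wGx": 0.5, "rank": 1}
                for c in CLASSES
            ]
        )
        code = extract_code(scores, k=1)
        assert list(code["pair_key"].unique()) == ["3x50:G.H5.10"]

    def test_k_beyond_universe_is_a_parameter_error(self):
        scores = pd.DataFrame(
            [
                {"class": c, "pair_key": "a:b", "weight": 1.0, "cGx": 0.5, "wGx": 0.5, "rank": 1}
                for c in CLASSES
            ]
        )
        with pytest.raises(ParameterError):
            extract_code(scores, k=2)


class TestProjection:
    def test_training_frames_project_to_their_own_class(self, planted_separable):
        model = fit_lda(planted_separable.matrix)
        m = planted_separable.matrix
        mask = m.class_labels == "Gs"
        sub = FingerprintMatrix(
            pairs=m.pairs,
            data=m.data[mask],
            system_ids=m.system_ids[mask],
            class_labels=m.class_labels[mask],
            frame_ids=np.arange(mask.sum()),
        )
        result = project_and_classify(model, sub, target_class="Gs")
        assert result.accuracy == 1.0
        assert result.n_missing_pairs == 0 and result.n_dropped_pairs == 0

    def test_all_zero_fingerprints_project_to_a_single_point(self, planted_default):
        model = fit_lda(planted_default.matrix)
        zeros = FingerprintMatrix(
            pairs=planted_default.matrix.pairs,
            data=np.zeros((5, len(model.pairs)), dtype=np.uint8),
            system_ids=np.asarray(["z"] * 5, dtype=object),
            class_labels=np.asarray(["other"] * 5, dtype=object),
            frame_ids=np.arange(5),
        )
        coords = project_and_classify(model, zeros).coordinates
        assert np.ptp(coords["component1"]) < 1e-9
        assert np.ptp(coords["component2"]) < 1e-9

    def test_universe_alignment_tallies_missing_and_dropped(self, planted_default):
        model = fit_lda(planted_default.matrix)
        m = planted_default.matrix
        renamed = ["novel:pair" if i < 3 else p for i, p in enumerate(m.pairs)]
        ext = FingerprintMatrix(
            pairs=[p if i >= 3 else f"novel{i}:x" for i, p in enumerate(m.pairs)],
            data=m.data[:10],
            system_ids=m.system_ids[:10],
            class_labels=m.class_labels[:10],
            frame_ids=np.arange(10),
        )
        result = project_and_classify(model, ext)
        assert result.n_missing_pairs == 3
        assert result.n_dropped_pairs == 3

    def test_empty_matrix_is_a_data_error(self, planted_default):
        model = fit_lda(planted_default.matrix)
        empty = FingerprintMatrix(
            pairs=planted_default.matrix.pairs,
            data=np.zeros((0, len(model.pairs)), dtype=np.uint8),
            system_ids=np.asarray([], dtype=object),
            class_labels=np.asarray([], dtype=object),
            frame_ids=np.asarray([], dtype=int),
        )
        with pytest.raises(DataError):
            project_and_classify(model, empty)


class TestPositionSubsets:
    def test_two_position_example(self):
        assert compare_position_subsets({"a": 1.0, "b": 3.0}, {"a"}) == (1.0, 3.0)

    def test_full_subset_has_no_complement_mean(self):
        mean_in, mean_out = compare_position_subsets({"a": 1.0, "b": 3.0}, {"a", "b"})
        assert mean_in == pytest.approx(2.0)
        assert mean_out is None

    def test_empty_subset_is_a_parameter_error(self):
        with pytest.raises(ParameterError):
            compare_position_subsets({"a": 1.0}, set())

    def test_synthetic_table_matches_oracle_means(self):
        rng = np.random.default_rng(17)
        values = {f"p{i}": float(rng.random()) for i in range(100)}
        subset = {f"p{i}" for i in range(0, 100, 7)}
        mean_in, mean_out = compare_position_subsets(values, subset)
        assert mean_in == pytest.approx(np.mean([values[p] for p in subset]))
        assert mean_out == pytest.approx(
            np.mean([v for p, v in values.items() if p not in subset])
        )
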