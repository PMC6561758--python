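from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
import hypothesis.strategies as st

import helpers
from taxodist import (
    FoldAssignment,
    LabeledSequence,
    PredictionRecord,
    RankedLabel,
    evaluate,
    macro_aggregate,
    parse_label,
    plateau_best,
    plateau_best_closed_form,
    plateau_evaluate,
    stratified_folds,
    taxonomy_distance,
    trim,
)


TRUTH = parse_label("orderA;familyB;genusE")
TRAINING = [parse_label("orderA;familyB;genusC;speciesD")]


class TestPlateauBest:
    def test_trimmed_label_worked_example(self):
        result = plateau_best(TRUTH, TRAINING)
        assert result.best_td == Fraction(1, 3)
        assert parse_label("orderA;familyB") in result.best_labels
        assert parse_label("orderA;familyB;genusC") in result.best_labels
        # deterministic representative: deepest minimizer
        assert result.best_label == parse_label("orderA;familyB;genusC")

    def test_untrimmed_training_label_is_strictly_worse(self):
        assert taxonomy_distance(TRUTH, TRAINING[0]) == Fraction(2, 4)
        assert Fraction(2, 4) > plateau_best(TRUTH, TRAINING).best_td

    def test_truth_in_training_gives_zero_and_truth_only(self):
        result = plateau_best(TRUTH, [TRUTH, TRAINING[0]])
        assert result.best_td == 0
        assert result.best_labels == (TRUTH,)

    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            plateau_best(TRUTH, [])
        with pytest.raises(ValueError):
            plateau_best_closed_form(TRUTH, [])

    def test_root_truth_is_trivially_attainable(self):
        result = plateau_best(RankedLabel(()), TRAINING)
        assert result.best_td == 0

    @given(
        truth=helpers.ranked_labels(max_depth=5),
        training=st.lists(helpers.ranked_labels(max_depth=5), min_size=1, max_size=8),
    )
    def test_every_minimizer_attains_best_td(self, truth, training):
        result = plateau_best(truth, training)
        for label in result.best_labels:
            assert taxonomy_distance(truth, label) == result.best_td

    @given(
        truth=helpers.ranked_labels(max_depth=5),
        training=st.lists(helpers.ranked_labels(max_depth=5), min_size=1, max_size=8),
    )
    def test_zero_iff_truth_is_training_label_or_prefix(self, truth, training):
        result = plateau_best(truth, training)
        is_prefix = any(
            l.ranks[: truth.depth] == truth.ranks for l in training
        )
        assert (result.best_td == 0) == is_prefix

    @given(
        truth=helpers.ranked_labels(max_depth=5),
        training=st.lists(helpers.ranked_labels(max_depth=5), min_size=1, max_size=8),
    )
    def test_dominates_every_prefix_candidate(self, truth, training):
        best = plateau_best(truth, training).best_td
        for label in training:
            for k in range(label.depth + 1):
                assert taxonomy_distance(truth, trim(label, k)) >= best


class TestClosedFormEquivalence:
    def test_matches_bruteforce_on_randomized_prefix_consistent_instances(self):
        """On taxonomies whose node names never recur at a position, the
        closed form (m - c*)/m equals brute-force prefix minimization."""
        from taxodist import random_taxonomy

        rng = np.random.default_rng(7)
        checked = 0
        for rep in range(40):
            labels = random_taxonomy(
                12, max_depth=6, branching=1.5, seed=1000 + rep
            )
            for truth in labels:
                training = [l for l in labels if l != truth]
                exact = plateau_best(truth, training)
                closed = plateau_best_closed_form(truth, training)
                assert exact.best_td == closed.best_td
                assert helpers.brute_plateau_best_td(truth, training) == closed.best_td
                if exact.best_td < 1:
                    assert set(exact.best_labels) == set(closed.best_labels)
                else:
                    # at TD 1 every zero-match prefix minimizes, including
                    # prefixes deeper than the truth that the canonical
                    # closed-form set leaves out
                    assert set(closed.best_labels) <= set(exact.best_labels)
                checked += 1
        assert checked >= 400

    def test_closed_form_diverges_when_names_recur_after_mismatch(self):
        # positional TD rewards the late match; the closed form cannot see it
        truth = parse_label("A;X")
        training = [parse_label("B;X")]
        assert plateau_best(truth, training).best_td == Fraction(1, 2)
        assert plateau_best_closed_form(truth, training).best_td == Fraction(1)


def _dataset(spec):
    """spec: list of (lineage, n_sequences)."""
    out = []
    serial = 0
    for lineage, n in spec:
        label = parse_label(lineage)
        for _ in range(n):
            serial += 1
            out.append(LabeledSequence("s%04d" % serial, label))
    return out


class TestPlateauEvaluate:
    def test_no_singletons_means_perfect_plateau(self):
        dataset = _dataset([("a;b;c", 4), ("a;b;d", 4), ("a;e;f", 4)])
        folds = stratified_folds(dataset, k=4, seed=0)
        report = macro_aggregate(plateau_evaluate(dataset, folds))
        assert report.atd_by_taxa == 0
        assert report.err_by_seq == 0

    def test_singleton_with_shared_depth2_prefix_scores_one_third(self):
        dataset = _dataset([("a;b;c", 1), ("a;b;d", 6)])
        folds = stratified_folds(dataset, k=2, seed=0)
        records = plateau_evaluate(dataset, folds)
        singleton = [r for r in records if r.truth == parse_label("a;b;c")]
        assert len(singleton) == 1
        assert taxonomy_distance(
            singleton[0].truth, singleton[0].prediction
        ) == Fraction(1, 3)

    def test_binary_plateau_error_is_fraction_of_unseen_taxa(self):
        """On a prefix-free label set, the Plateau errs (binary) exactly on
        the sequences whose taxon is absent from training."""
        from taxodist import random_taxonomy, imbalanced_dataset

        labels = random_taxonomy(20, max_depth=5, seed=5)
        dataset = imbalanced_dataset(
            labels, 60, 1.5, seed=6, with_sequences=False
        )
        folds = stratified_folds(dataset, k=5, seed=7)
        records = plateau_evaluate(dataset, folds)
        label_folds = {}
        for s in dataset:
            label_folds.setdefault(s.label, set()).add(folds.fold_of(s.id))
        expected_errors = sum(
            1 for s in dataset if label_folds[s.label] == {folds.fold_of(s.id)}
        )
        report = evaluate(records)
        assert report.err_by_seq == Fraction(expected_errors, len(dataset))

    def test_plateau_per_taxon_atd_lower_bounds_any_training_label_guesser(self):
        """Per taxon, the Plateau ATD is a lower bound for any classifier
        whose predictions come from the training label space."""
        dataset = _dataset([("a;b;c", 3), ("a;b;d", 3), ("a;e;f", 3), ("g;h;i", 1)])
        folds = stratified_folds(dataset, k=3, seed=1)
        plateau_report = evaluate(plateau_evaluate(dataset, folds))

        rng = np.random.default_rng(2)
        fold_labels = {f: set() for f in range(folds.k)}
        for s in dataset:
            fold_labels[folds.fold_of(s.id)].add(s.label)
        guesses = []
        for s in dataset:
            f = folds.fold_of(s.id)
            pool = sorted(
                {l for g, ls in fold_labels.items() if g != f for l in ls},
                key=lambda l: l.ranks,
            )
            guesses.append(
                PredictionRecord(
                    s.id, s.label, pool[int(rng.integers(len(pool)))], fold=f
                )
            )
        guess_report = evaluate(guesses)
        plateau_atds = plateau_report.taxon_atds()
        for taxon, guessed_atd in guess_report.taxon_atds().items():
            assert plateau_atds[taxon] <= guessed_atd

    def test_fold_covering_whole_dataset_raises(self):
        dataset = _dataset([("a;b", 3)])
        folds = FoldAssignment({s.id: 0 for s in dataset}, k=2, seed=0)
        with pytest.raises(ValueError, match="training is empty"):
            plateau_evaluate(dataset, folds)
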