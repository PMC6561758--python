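from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given

import helpers
from taxodist import (
    ROOT,
    PredictionRecord,
    RankedLabel,
    atd,
    binary_error,
    dataset_summary,
    edge_distance,
    evaluate,
    parse_label,
    taxonomy_distance,
)


class TestTaxonomyDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("orderA;familyB;generaD", "orderA;familyB;generaE", Fraction(1, 3)),
            ("orderA;familyC;generaF", "orderA;familyC;generaF;speciesG", Fraction(1, 4)),
            ("orderA;familyB", "orderA;familyC", Fraction(1, 2)),
            ("orderA;familyB", "orderA;familyC;generaF;speciesG", Fraction(3, 4)),
            ("a;b;c", "", Fraction(3, 3)),
            ("", "", Fraction(0)),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert taxonomy_distance(parse_label(a), parse_label(b)) == expected

    @given(a=helpers.ranked_labels(), b=helpers.ranked_labels())
    def test_symmetry_range_identity(self, a, b):
        td = taxonomy_distance(a, b)
        assert td == taxonomy_distance(b, a)
        assert Fraction(0) <= td <= Fraction(1)
        assert (td == 0) == (a == b)
        assert taxonomy_distance(a, a) == 0

    @given(a=helpers.ranked_labels(), b=helpers.ranked_labels())
    def test_matches_independent_padding_oracle(self, a, b):
        assert taxonomy_distance(a, b) == helpers.brute_td(a, b)

    def test_binary_error_dominates_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a = helpers.random_label(rng)
            b = helpers.random_label(rng)
            assert binary_error(a, b) >= taxonomy_distance(a, b)
            assert binary_error(a, b) in (0, 1)

    @pytest.mark.parametrize("depth", [1, 2, 3, 6, 8])
    def test_one_rank_error_at_lowest_rank_gives_1_over_d(self, depth):
        ranks = tuple("n%d" % i for i in range(depth))
        truth = RankedLabel(ranks)
        pred = RankedLabel(ranks[:-1] + ("other",))
        assert taxonomy_distance(truth, pred) == Fraction(1, depth)

    def test_unclassified_prediction_scores_1(self):
        truth = parse_label("a;b;c;d;e;f")
        assert taxonomy_distance(truth, ROOT) == 1


class TestEdgeDistance:
    def test_discussion_contrast_pairs(self, fig2):
        t4, t5, t6 = fig2.labels["T4"], fig2.labels["T5"], fig2.labels["T6"]
        assert edge_distance(fig2.tree, t4, t5) == 2
        assert edge_distance(fig2.tree, t4, t6) == 4
        assert edge_distance(fig2.tree, t4, t4) == 0

    def test_absent_label_raises(self, fig2):
        with pytest.raises(KeyError):
            edge_distance(fig2.tree, fig2.labels["T1"], RankedLabel(("nowhere",)))


class TestAtd:
    def test_mean_of_two_tds(self):
        truth = parse_label("a;b;c")
        records = [
            PredictionRecord("s1", truth, truth),
            PredictionRecord("s2", truth, parse_label("a;b;x")),
        ]
        assert atd(records) == Fraction(1, 6)

    def test_all_correct_taxon_is_zero(self):
        truth = parse_label("a;b")
        records = [PredictionRecord("s%d" % i, truth, truth) for i in range(5)]
        assert atd(records) == 0

    @given(table=helpers.prediction_tables(min_records=1, max_records=15))
    def test_matches_resummation_oracle(self, table):
        truth = table[0].truth
        group = [
            PredictionRecord("g%d" % i, truth, r.prediction)
            for i, r in enumerate(table)
        ]
        expected = sum(
            (helpers.brute_td(truth, r.prediction) for r in group), Fraction(0)
        ) / len(group)
        assert atd(group) == expected

    def test_empty_and_mixed_inputs_raise(self):
        with pytest.raises(ValueError):
            atd([])
        with pytest.raises(ValueError):
            atd(
                [
                    PredictionRecord("a", parse_label("x"), parse_label("x")),
                    PredictionRecord("b", parse_label("y"), parse_label("y")),
                ]
            )


def _nine_one_table():
    a = parse_label("p;q;r")
    b = parse_label("p;s")
    records = [PredictionRecord("a%d" % i, a, a) for i in range(9)]
    records.append(PredictionRecord("b0", b, parse_label("p;t")))
    return records


class TestEvaluate:
    def test_two_taxon_worked_arithmetic(self):
        report = evaluate(_nine_one_table())
        assert report.atd_by_seq == Fraction(1, 20)
        assert report.atd_by_taxa == Fraction(1, 4)
        assert report.err_by_seq == Fraction(1, 10)
        assert report.err_by_taxa == Fraction(1, 2)
        assert report.n_taxa == 2

    def test_within_taxon_duplication_leaves_atd_by_taxa_unchanged(self):
        records = _nine_one_table()
        base = evaluate(records)
        a = records[0]
        doubled = records + [
            PredictionRecord("dup%d" % i, a.truth, a.prediction) for i in range(9)
        ]
        dup = evaluate(doubled)
        assert dup.atd_by_taxa == base.atd_by_taxa
        assert dup.err_by_taxa == base.err_by_taxa
        # ...but the sequence-weighted view shifts toward the duplicated taxon
        assert dup.atd_by_seq != base.atd_by_seq

    @given(table=helpers.prediction_tables())
    def test_taxon_metrics_bounded_by_binary(self, table):
        report = evaluate(table)
        assert report.atd_by_seq <= report.err_by_seq
        assert report.atd_by_taxa <= report.err_by_taxa
        for t in report.taxon_reports:
            assert t.atd <= t.binary_error_rate
            assert (t.atd == 0) == all(
                r.prediction == t.taxon for r in table if r.truth == t.taxon
            )

    @given(table=helpers.prediction_tables())
    def test_matches_double_loop_oracle(self, table):
        report = evaluate(table)
        expected = helpers.brute_evaluate(table)
        assert report.atd_by_taxa == expected["atd_by_taxa"]
        assert report.atd_by_seq == expected["atd_by_seq"]
        assert report.err_by_taxa == expected["err_by_taxa"]
        assert report.err_by_seq == expected["err_by_seq"]
        assert report.sd_by_taxa == pytest.approx(expected["sd_by_taxa"])
        assert report.sd_by_seq == pytest.approx(expected["sd_by_seq"])
        assert report.sd_err_by_taxa == pytest.approx(expected["sd_err_by_taxa"])

    def test_empty_and_duplicate_tables_raise(self):
        with pytest.raises(ValueError):
            evaluate([])
        rec = PredictionRecord("same", parse_label("a"), parse_label("a"))
        with pytest.raises(ValueError, match="duplicate"):
            evaluate([rec, rec])


class TestDatasetSummary:
    def test_six_distinct_labels(self, fig2):
        assert dataset_summary(fig2.labels.values()) == (6, 6, 6)

    def test_adding_a_duplicate_removes_a_singleton(self, fig2):
        labels = list(fig2.labels.values()) + [fig2.labels["T1"]]
        assert dataset_summary(labels) == (7, 6, 5)

    @given(table=helpers.prediction_tables())
    def test_matches_histogram_recount(self, table):
        labels = [r.truth for r in table]
        counts = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        summary = dataset_summary(labels)
        assert summary.n_sequences == len(labels)
        assert summary.n_taxa == len(counts)
        assert summary.n_singletons == sum(1 for v in counts.values() if v == 1)
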