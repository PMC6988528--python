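import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taxback import (
    class_metrics,
    confusion_counts,
    confusion_matrix,
    per_class_metrics,
    rank_summaries,
    recall_distribution,
    weighted_mean_summary,
)
from taxback.metrics import RankSummary, round_half_up
from taxback.taxonomy import TaxonomyTable


def flat_taxonomy(names):
    """Each species its own genus; single family — ranks collapse to species."""
    return TaxonomyTable(
        pd.DataFrame({"species": list(names), "genus": list(names), "family": ["F"] * len(names)})
    )


def species_preds(pairs):
    """Prediction frame from (truth, predicted) species pairs."""
    return pd.DataFrame(
        {
            "image_id": [f"i{k}" for k in range(len(pairs))],
            "predicted_taxon": [p for _, p in pairs],
            "predicted_rank": "species",
            "confidence": 1.0,
            "truth_species": [t for t, _ in pairs],
            "correct": [t == p for t, p in pairs],
        }
    )


class TestClassMetrics:
    def test_perfect_class(self):
        m = class_metrics((10, 0, 90, 0))
        assert (m.precision, m.recall, m.accuracy, m.balanced_accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_class_undefined_not_zero(self):
        m = class_metrics((0, 0, 100, 0))
        assert m.precision is None and m.recall is None and m.balanced_accuracy is None
        assert m.tnr == 1.0

    def test_arithmetic(self):
        m = class_metrics((3, 1, 90, 6))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(1 / 3)
        assert m.accuracy == pytest.approx(0.93)
        assert m.balanced_accuracy == pytest.approx((1 / 3 + 90 / 91) / 2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            class_metrics((-1, 0, 0, 0))


class TestConfusionCounts:
    def test_all_correct(self):
        taxonomy = flat_taxonomy(["A", "B"])
        preds = species_preds([("A", "A")] * 10)
        assert confusion_counts(preds, "A", "species", taxonomy) == (10, 0, 0, 0)

    def test_three_image_enumeration(self):
        taxonomy = flat_taxonomy(["A", "B", "C"])
        preds = species_preds([("A", "B"), ("B", "B"), ("C", "C")])
        # for A: its one image predicted elsewhere -> fn; nothing predicted A
        assert confusion_counts(preds, "A", "species", taxonomy) == (0, 0, 2, 1)
        # for B: own image correct (tp), plus A's image wrongly predicted B (fp)
        assert confusion_counts(preds, "B", "species", taxonomy) == (1, 1, 1, 0)

    def test_absent_class_all_true_negatives(self):
        taxonomy = flat_taxonomy(["A", "B", "C"])
        preds = species_preds([("A", "A"), ("B", "B")])
        assert confusion_counts(preds, "C", "species", taxonomy) == (0, 0, 2, 0)

    def test_unknown_class_rejected(self):
        taxonomy = flat_taxonomy(["A"])
        with pytest.raises(KeyError):
            confusion_counts(species_preds([("A", "A")]), "Z", "species", taxonomy)


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        taxonomy = flat_taxonomy(["A", "B"])
        cm = confusion_matrix(species_preds([("A", "A"), ("B", "B"), ("B", "B")]),
                              "species", taxonomy)
        assert cm.at["A", "A"] == 1 and cm.at["B", "B"] == 2
        assert cm.to_numpy().sum() == 3

    def test_known_swaps_match_hand_tally(self):
        taxonomy = flat_taxonomy(["A", "B", "C"])
        preds = species_preds(
            [("A", "B"), ("B", "A"), ("A", "A"), ("C", "C"), ("C", "C")]
        )
        cm = confusion_matrix(preds, "species", taxonomy)
        assert cm.at["A", "B"] == 1 and cm.at["B", "A"] == 1
        assert cm.at["A", "A"] == 1 and cm.at["C", "C"] == 2
        # row sums equal per-taxon truth counts
        assert cm.sum(axis=1).to_dict() == {"A": 2, "B": 1, "C": 2}

    def test_rollup_to_coarser_rank(self):
        taxonomy = TaxonomyTable(
            pd.DataFrame(
                {"species": ["s1", "s2", "s3"], "genus": ["A", "A", "B"],
                 "family": ["F"] * 3}
            )
        )
        preds = species_preds([("s1", "s2"), ("s3", "s1")])
        cm = confusion_matrix(preds, "genus", taxonomy)
        assert cm.at["A", "A"] == 1 and cm.at["B", "A"] == 1


class TestRankSummaries:
    def test_all_species_rank_single_row(self, small_dataset):
        from taxback import predict_backoff_batch

        preds = predict_backoff_batch(
            small_dataset["matrix"], small_dataset["taxonomy"], 0.0, small_dataset["truths"]
        )
        summaries = rank_summaries(preds, small_dataset["taxonomy"])
        assert len(summaries) == 1
        assert summaries[0].rank == "species"
        assert summaries[0].n_specimens == small_dataset["matrix"].n_images

    def test_single_family_specimen_yields_undefined_balanced_accuracy(self):
        """One image emitted at family: no negatives exist, so TNR and hence
        balanced accuracy are undefined while precision and recall are 100."""
        taxonomy = flat_taxonomy(["A"])
        preds = pd.DataFrame(
            {
                "image_id": ["i0"],
                "predicted_taxon": ["F"],
                "predicted_rank": "family",
                "confidence": 1.0,
                "truth_species": ["A"],
                "correct": [True],
            }
        )
        (summary,) = rank_summaries(preds, taxonomy)
        assert summary.n_specimens == 1
        assert summary.mean_balanced_accuracy is None
        assert summary.mean_precision == pytest.approx(100.0)
        assert summary.mean_recall == pytest.approx(100.0)

    def test_two_rank_partition_counts_match_construction(self):
        taxonomy = TaxonomyTable(
            pd.DataFrame(
                {"species": ["s1", "s2", "s3"], "genus": ["A", "A", "B"],
                 "family": ["F"] * 3}
            )
        )
        preds = species_preds([("s1", "s1"), ("s2", "s2")])
        genus_rows = pd.DataFrame(
            {
                "image_id": ["g0", "g1", "g2"],
                "predicted_taxon": ["A", "A", "B"],
                "predicted_rank": "genus",
                "confidence": 0.8,
                "truth_species": ["s1", "s3", "s3"],
                "correct": [True, False, True],
            }
        )
        summaries = rank_summaries(pd.concat([preds, genus_rows]), taxonomy)
        by_rank = {s.rank: s for s in summaries}
        assert by_rank["species"].n_specimens == 2
        assert by_rank["genus"].n_specimens == 3


class TestWeightedMeans:
    def test_single_rank_identity(self):
        s = RankSummary("species", 100, 82.4, 70.0, 64.9)
        assert weighted_mean_summary([s]) == pytest.approx((82.4, 70.0, 64.9))

    def test_equal_weights_average(self):
        a = RankSummary("species", 50, 40.0, 40.0, 40.0)
        b = RankSummary("genus", 50, 60.0, 60.0, 60.0)
        assert weighted_mean_summary([a, b]) == pytest.approx((50.0, 50.0, 50.0))

    def test_undefined_rows_excluded_per_column(self):
        a = RankSummary("species", 99, 80.0, 70.0, 60.0)
        b = RankSummary("family", 1, None, 100.0, 100.0)
        wb, wp, wr = weighted_mean_summary([a, b])
        assert wb == pytest.approx(80.0)  # NA row carries no weight here
        assert wp == pytest.approx((99 * 70.0 + 100.0) / 100)
        assert wr == pytest.approx((99 * 60.0 + 100.0) / 100)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_summary([])


class TestRecallDistribution:
    def test_constant_values(self):
        d = recall_distribution([50, 50, 50])
        assert (d.mean, d.sd, d.se) == (50.0, 0.0, 0.0)

    def test_two_point_closed_form(self):
        d = recall_distribution([0, 100])
        assert d.mean == 50.0
        assert d.sd == pytest.approx(100 / np.sqrt(2))
        assert d.se == pytest.approx(50.0)

    def test_se_is_sd_over_sqrt_n(self, rng):
        values = rng.uniform(0, 100, size=291)
        d = recall_distribution(values)
        assert d.se == pytest.approx(d.sd / np.sqrt(291))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            recall_distribution([])


class TestAgainstNaiveOracle:
    def naive_tally(self, truth, pred, taxon):
        tp = sum(1 for t, p in zip(truth, pred) if t == taxon and p == taxon)
        fp = sum(1 for t, p in zip(truth, pred) if t != taxon and p == taxon)
        fn = sum(1 for t, p in zip(truth, pred) if t == taxon and p != taxon)
        tn = len(truth) - tp - fp - fn
        return tp, fp, tn, fn

    def test_random_prediction_sets(self, rng):
        names = list("ABCDE")
        taxonomy = flat_taxonomy(names)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            truth = rng.choice(names, n)
            pred = rng.choice(names, n)
            preds = species_preds(list(zip(truth, pred)))
            for taxon in names:
                expected = self.naive_tally(truth, pred, taxon)
                assert confusion_counts(preds, taxon, "species", taxonomy) == expected

    def test_sum_of_tp_equals_total_correct(self, rng):
        names = list("ABCD")
        taxonomy = flat_taxonomy(names)
        truth = rng.choice(names, 200)
        pred = rng.choice(names, 200)
        preds = species_preds(list(zip(truth, pred)))
        metrics = per_class_metrics(preds, "species", taxonomy)
        assert sum(m.tp for m in metrics) == int((truth == pred).sum())

    def test_matches_sklearn_per_class(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        names = list("ABC")
        taxonomy = flat_taxonomy(names)
        truth = rng.choice(names, 150)
        pred = rng.choice(names, 150)
        preds = species_preds(list(zip(truth, pred)))
        ours = {m.class_name: m for m in per_class_metrics(preds, "species", taxonomy)}
        for taxon in names:
            y_true = truth == taxon
            y_pred = pred == taxon
            assert ours[taxon].recall == pytest.approx(
                sk.recall_score(y_true, y_pred, zero_division=np.nan), nan_ok=True
            )
            assert ours[taxon].precision == pytest.approx(
                sk.precision_score(y_true, y_pred, zero_division=np.nan), nan_ok=True
            )
            assert ours[taxon].balanced_accuracy == pytest.approx(
                sk.balanced_accuracy_score(y_true, y_pred)
            )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 500)] * 4))
def test_class_metric_invariants(counts):
    tp, fp, tn, fn = counts
    m = class_metrics(counts)
    total = tp + fp + tn + fn
    if total == 0:
        assert m.accuracy is None
        return
    # one-vs-rest error budget: all errors touch the class as truth or as
    # prediction, so accuracy >= (n - 2 * n_involved) / n
    n_involved = max(tp + fn, tp + fp)
    assert m.accuracy >= (total - 2 * n_involved) / total - 1e-12
    for v in (m.precision, m.recall, m.accuracy, m.balanced_accuracy, m.tpr, m.tnr):
        assert v is None or 0.0 <= v <= 1.0
    if m.tpr is not None and m.tnr is not None:
        assert m.balanced_accuracy == pytest.approx((m.tpr + m.tnr) / 2)


def test_round_half_up():
    assert round_half_up(75.75) == 75.8
    assert round_half_up(70.64999) == 70.6
    assert round_half_up(217.74, 0) == 218.0
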