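import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from subtypebench.corpus import LABEL_ORDER, SubtypeLabel
from subtypebench.evaluation import (
    ConfusionMatrix,
    as_percent,
    compare_best,
    confusion_matrix,
    load_published_fixtures,
    macro_metrics,
    misclassification_rate,
    per_class_metrics,
)

_L = SubtypeLabel


def random_label_pairs(rng, n):
    labels = list(SubtypeLabel)
    true = [labels[i] for i in rng.integers(6, size=n)]
    pred = [labels[i] for i in rng.integers(6, size=n)]
    return true, pred


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        true = [label for label in LABEL_ORDER for _ in range(10)]
        cm = confusion_matrix(true, true)
        assert np.array_equal(cm.counts, np.eye(6, dtype=int) * 10)

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [])
        assert cm.total == 0 and np.all(cm.counts == 0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        true, pred = random_label_pairs(rng, 500)
        cm = confusion_matrix(true, pred)
        for i, row_label in enumerate(LABEL_ORDER):
            for j, col_label in enumerate(LABEL_ORDER):
                tally = sum(
                    1 for t, p in zip(true, pred) if t is row_label and p is col_label
                )
                assert cm.counts[i, j] == tally
        assert cm.total == 500

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([_L.MAJOR], [])


class TestMetrics:
    def test_perfect_predictions_score_one_everywhere(self):
        true = [label for label in LABEL_ORDER for _ in range(5)]
        report = macro_metrics(confusion_matrix(true, true))
        assert report.macro_f1 == report.accuracy == 1.0
        assert report.macro_precision == report.macro_recall == 1.0

    def test_single_class_corpus_uses_zero_denominator_convention(self):
        true = [_L.MAJOR] * 8
        report = macro_metrics(confusion_matrix(true, true))
        assert report.accuracy == 1.0
        # five classes have empty rows and columns: flagged, counted as 0
        assert report.macro_f1 == pytest.approx(1 / 6)
        flagged = [m for m in report.per_class if m.undefined]
        assert len(flagged) == 5

    def test_never_predicted_class_has_zero_precision_with_flag(self):
        true = [_L.MAJOR, _L.BIPOLAR]
        pred = [_L.MAJOR, _L.MAJOR]
        metrics = {m.label: m for m in per_class_metrics(confusion_matrix(true, pred))}
        assert metrics[_L.BIPOLAR].precision == 0.0
        assert metrics[_L.BIPOLAR].undefined

    def test_oracle_equivalence_on_random_predictions(self):
        """1,000 random prediction sets against the sklearn textbook
        implementation, to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            true, pred = random_label_pairs(rng, rng.integers(6, 60))
            report = macro_metrics(confusion_matrix(true, pred))
            p, r, f1, _ = precision_recall_fscore_support(
                [t.index for t in true],
                [q.index for q in pred],
                labels=range(6),
                average="macro",
                zero_division=0,
            )
            assert report.macro_precision == pytest.approx(p, abs=1e-12)
            assert report.macro_recall == pytest.approx(r, abs=1e-12)
            assert report.macro_f1 == pytest.approx(f1, abs=1e-12)
            accuracy = np.mean([t is q for t, q in zip(true, pred)])
            assert report.accuracy == pytest.approx(accuracy, abs=1e-12)

    def test_row_weighted_recall_reproduces_accuracy(self):
        rng = np.random.default_rng(2)
        true, pred = random_label_pairs(rng, 400)
        cm = confusion_matrix(true, pred)
        report = macro_metrics(cm)
        weighted = sum(
            m.recall * cm.row_sum(m.label) for m in report.per_class
        ) / cm.total
        assert weighted == pytest.approx(report.accuracy, abs=1e-12)

    def test_f1_between_min_and_max_of_precision_recall(self):
        rng = np.random.default_rng(3)
        true, pred = random_label_pairs(rng, 300)
        for m in per_class_metrics(confusion_matrix(true, pred)):
            if not m.undefined:
                assert min(m.precision, m.recall) <= m.f1 <= max(m.precision, m.recall)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            macro_metrics(ConfusionMatrix(np.zeros((6, 6), dtype=int)))


class TestMisclassificationRate:
    def test_diagonal_only_matrix_has_unit_self_rate(self):
        cm = ConfusionMatrix(np.eye(6, dtype=int) * 7)
        assert misclassification_rate(cm, _L.MAJOR, _L.MAJOR) == 1.0

    def test_zero_row_rejected(self):
        counts = np.eye(6, dtype=int) * 7
        counts[_L.ATYPICAL.index] = 0
        with pytest.raises(ValueError, match="atypical"):
            misclassification_rate(ConfusionMatrix(counts), _L.ATYPICAL, _L.MAJOR)


@pytest.fixture(scope="module")
def fixtures():
    return load_published_fixtures()


@pytest.fixture(scope="module")
def benchmark(fixtures):
    return fixtures.benchmark


class TestPublishedCountArithmetic:
    """Every percentage printed in the published error analysis must be
    reproduced at one decimal from its printed numerator/denominator."""

    @pytest.mark.parametrize(
        "accessor, expected",
        [
            (lambda fx: fx.prompt_only.recall(_L.BIPOLAR), 95.8),
            (lambda fx: fx.prompt_only.precision(_L.BIPOLAR), 43.6),
            (
                lambda fx: fx.prompt_only.misclassification_rate(
                    _L.NO_DEPRESSION, _L.BIPOLAR
                ),
                26.5,
            ),
            (
                lambda fx: fx.prompt_only.misclassification_rate(
                    _L.ATYPICAL, _L.BIPOLAR
                ),
                49.0,
            ),
            (lambda fx: fx.prompt_only.recall(_L.MAJOR), 53.1),
            (lambda fx: fx.prompt_only.recall(_L.NO_DEPRESSION), 68.0),
            (lambda fx: fx.fine_tuned.precision(_L.BIPOLAR), 92.9),
            (lambda fx: fx.fine_tuned.recall(_L.BIPOLAR), 86.0),
            (
                lambda fx: fx.fine_tuned.misclassification_rate(
                    _L.NO_DEPRESSION, _L.BIPOLAR
                ),
                1.4,
            ),
            (
                lambda fx: fx.fine_tuned.misclassification_rate(
                    _L.BIPOLAR, _L.NO_DEPRESSION
                ),
                7.4,
            ),
            (
                lambda fx: fx.fine_tuned.misclassification_rate(
                    _L.BIPOLAR, _L.ATYPICAL
                ),
                5.8,
            ),
            (lambda fx: fx.fine_tuned.recall(_L.MAJOR), 96.7),
        ],
    )
    def test_printed_percentages_reproduce_at_one_decimal(
        self, fixtures, accessor, expected
    ):
        assert as_percent(accessor(fixtures)) == expected

    def test_sparse_ratios_agree_with_full_matrix_path(self, fixtures):
        """Embedding a known cell in a full matrix with the same row total
        yields the same rate through misclassification_rate."""
        counts = np.zeros((6, 6), dtype=int)
        i, j = _L.NO_DEPRESSION.index, _L.BIPOLAR.index
        counts[i, j] = 149
        counts[i, i] = 562 - 149
        rate = misclassification_rate(ConfusionMatrix(counts), _L.NO_DEPRESSION, _L.BIPOLAR)
        assert rate == pytest.approx(
            fixtures.prompt_only.misclassification_rate(_L.NO_DEPRESSION, _L.BIPOLAR)
        )


class TestCompareBest:
    def test_macro_f1_delta_is_19_2_points(self, benchmark):
        best_ft, best_fs, delta = compare_best(benchmark, "macro_f1", "test")
        assert best_ft["model"] == "RoBERTa-large"
        assert best_fs["model"] == "Meta-Llama-3-8B-Instruct"
        assert round(delta, 1) == 19.2

    def test_accuracy_delta_is_20_4_points(self, benchmark):
        _, _, delta = compare_best(benchmark, "accuracy", "test")
        assert round(delta, 1) == 20.4

    def test_identical_tracks_give_zero_delta(self):
        rows = []
        for track in ("few-shot", "fine-tune"):
            rows.append([f"m-{track}", track, "test", 0.8, 0.8, 0.8, 0.8])
        table = pd.DataFrame(
            rows,
            columns=["model", "track", "split", "macro_f1", "accuracy", "precision", "recall"],
        )
        assert compare_best(table, "macro_f1", "test")[2] == 0.0

    def test_missing_track_rejected(self, benchmark):
        only_fs = benchmark[benchmark["track"] == "few-shot"]
        with pytest.raises(ValueError, match="fine-tune"):
            compare_best(only_fs, "macro_f1", "test")

    def test_best_few_shot_tie_resolves_to_first_listed(self, benchmark):
        # two few-shot models share test macro-F1 0.765; first listed wins
        rows = benchmark[
            (benchmark["split"] == "test") & (benchmark["track"] == "few-shot")
        ]
        tied = rows[rows["macro_f1"] == rows["macro_f1"].max()]
        assert len(tied) == 2
        _, best_fs, _ = compare_best(benchmark, "macro_f1", "test")
        assert best_fs["model"] == tied.iloc[0]["model"]


class TestFixtureTranscription:
    def test_in_text_counts_are_transcribed(self):
        fx = load_published_fixtures()
        assert fx.prompt_only.row_totals[_L.BIPOLAR] == 378
        assert fx.prompt_only.cells[(_L.BIPOLAR, _L.BIPOLAR)] == 362
        assert fx.prompt_only.col_totals[_L.BIPOLAR] == 831
        assert fx.fine_tuned.cells[(_L.MAJOR, _L.MAJOR)] == 355
        assert fx.fine_tuned.row_totals[_L.MAJOR] == 367

    def test_benchmark_table_shape_and_bounds(self):
        table = load_published_fixtures().benchmark
        assert len(table) == 28  # 14 models x 2 splits
        assert table.groupby(["track", "split"])["model"].nunique().min() >= 5
        metric_cols = ["macro_f1", "accuracy", "precision", "recall"]
        assert ((table[metric_cols] >= 0) & (table[metric_cols] <= 1)).all().all()

    def test_best_few_shot_test_macro_f1_value(self):
        table = load_published_fixtures().benchmark
        row = table[
            (table["model"] == "Meta-Llama-3-8B-Instruct") & (table["split"] == "test")
        ].iloc[0]
        assert row["macro_f1"] == 0.765
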