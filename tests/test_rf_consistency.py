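"""Random-forest consistency protocol: determinism, calibration, queries."""

import numpy as np
import pandas as pd
import pytest

from crosscontrast.rf_consistency import (ForestProtocol, classify_queries,
                                          run_cv_forests)
from crosscontrast.simdata import SimConfig, generate_dataset


@pytest.fixture(scope="module")
def strong_signal():
    """Two classes separated by a large effect on many genes."""
    config = SimConfig(group_sizes={"HD_BA9": 20, "C_BA9": 30},
                       n_genes=400, frac_de=0.3, frac_region=0,
                       frac_interaction=0, l2fc_loc=4.0, seed=21)
    counts, meta, truth = generate_dataset(config)
    normalized = counts / counts.sum(axis=0).mean() * 1e3
    labels = meta["group"]
    de_ranking = pd.DataFrame({
        "padj": np.where(truth.table["is_de"], 1e-6, 0.9),
        "log2FoldChange": truth.table["l2fc_disease"],
    }, index=truth.table.index)
    return normalized, labels, de_ranking


def quick(mode, **kw):
    return ForestProtocol(n_trees=200, panel_size=100, panel_mode=mode,
                          n_repetitions=4, **kw)


class TestProtocolValidation:
    def test_bad_settings_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            ForestProtocol(train_fraction=1.0)
        with pytest.raises(ValueError, match="panel_mode"):
            ForestProtocol(panel_mode="best")
        with pytest.raises(ValueError, match="null_label_mode"):
            ForestProtocol(null_label_mode="flip")

    def test_top_de_requires_ranking(self, strong_signal):
        normalized, labels, _ = strong_signal
        with pytest.raises(ValueError, match="de_ranking"):
            run_cv_forests(normalized, labels, quick("top_de"))

    def test_two_classes_required(self, strong_signal):
        normalized, labels, _ = strong_signal
        labels3 = labels.copy()
        labels3.iloc[0] = "X"
        with pytest.raises(ValueError, match="two classes"):
            run_cv_forests(normalized, labels3, quick("random"))

    def test_panel_cannot_exceed_genes(self, strong_signal):
        normalized, labels, _ = strong_signal
        proto = ForestProtocol(n_trees=50, panel_size=10_000,
                               panel_mode="random", n_repetitions=1)
        with pytest.raises(ValueError, match="panel_size"):
            run_cv_forests(normalized, labels, proto)

    def test_query_missing_genes_rejected(self, strong_signal):
        normalized, labels, _ = strong_signal
        queries = normalized.iloc[:10, :2]
        with pytest.raises(ValueError, match="missing"):
            run_cv_forests(normalized, labels, quick("random"), queries=queries)


class TestRuns:
    def test_seeded_determinism(self, strong_signal):
        normalized, labels, de = strong_signal
        proto = quick("top_de", seed=3)
        r1 = run_cv_forests(normalized, labels, proto, de_ranking=de)
        r2 = run_cv_forests(normalized, labels, proto, de_ranking=de)
        pd.testing.assert_frame_equal(r1.per_repetition, r2.per_repetition)

    def test_strong_signal_memorized_and_generalized(self, strong_signal):
        normalized, labels, de = strong_signal
        run = run_cv_forests(normalized, labels, quick("top_de", seed=5),
                             de_ranking=de)
        assert run.per_repetition["train_accuracy"].eq(1.0).all()  # 1 +- 0
        assert run.mean_test_accuracy > 0.9

    def test_swapping_positive_class_swaps_sensitivity_specificity(
            self, strong_signal):
        normalized, labels, de = strong_signal
        runs = {pos: run_cv_forests(normalized, labels, quick("top_de", seed=7),
                                    de_ranking=de, pos_label=pos)
                for pos in ("HD", "C")}
        pd.testing.assert_series_equal(
            runs["HD"].per_repetition["sensitivity"],
            runs["C"].per_repetition["specificity"], check_names=False)
        pd.testing.assert_series_equal(
            runs["HD"].per_repetition["specificity"],
            runs["C"].per_repetition["sensitivity"], check_names=False)

    def test_null_mode_near_chance(self, strong_signal):
        normalized, labels, _ = strong_signal
        proto = ForestProtocol(n_trees=300, panel_size=100, panel_mode="null",
                               n_repetitions=15, seed=9)
        run = run_cv_forests(normalized, labels, proto)
        assert abs(run.mean_test_accuracy - 0.5) < 0.1
        # memorization still perfect on the training side
        assert run.per_repetition["train_accuracy"].eq(1.0).all()

    def test_vote_fractions_sum_to_one(self, strong_signal):
        normalized, labels, de = strong_signal
        queries = normalized.iloc[:, :4].copy()
        queries.columns = [f"q{i}" for i in range(4)]
        run = run_cv_forests(normalized, labels, quick("top_de", seed=11),
                             de_ranking=de, queries=queries)
        assert np.allclose(run.query_votes.sum(axis=1), 1.0)

    def test_gene_order_invariance(self, strong_signal):
        normalized, labels, de = strong_signal
        shuffled = normalized.sample(frac=1.0, random_state=0)
        proto = quick("top_de", seed=13)
        r1 = run_cv_forests(normalized, labels, proto, de_ranking=de)
        r2 = run_cv_forests(shuffled, labels, proto, de_ranking=de)
        pd.testing.assert_frame_equal(r1.per_repetition, r2.per_repetition)


class TestQueries:
    def test_training_duplicate_recovers_its_label(self, strong_signal):
        normalized, labels, de = strong_signal
        hd_sample = labels.index[labels == "HD"][0]
        queries = normalized[[hd_sample]].copy()
        queries.columns = ["dup"]
        run = run_cv_forests(normalized, labels, quick("top_de", seed=15),
                             de_ranking=de, queries=queries)
        assert run.query_votes.loc["dup", "HD"] > 0.5

    def test_same_class_query_strongly_voted(self, strong_signal):
        normalized, labels, de = strong_signal
        # a fresh draw from the HD generative regime: average two HD samples
        hd = labels.index[labels == "HD"]
        queries = pd.DataFrame({"synthetic_hd":
                                normalized[hd[:2]].mean(axis=1)})
        run = run_cv_forests(normalized, labels, quick("top_de", seed=17),
                             de_ranking=de, queries=queries)
        assert run.query_votes.loc["synthetic_hd", "HD"] > 0.8

    def test_classify_queries_matches_online_votes(self, strong_signal):
        normalized, labels, de = strong_signal
        queries = normalized.iloc[:, :3].copy()
        queries.columns = ["q0", "q1", "q2"]
        run = run_cv_forests(normalized, labels, quick("top_de", seed=19),
                             de_ranking=de, queries=queries, store_forests=True)
        offline = classify_queries(run, queries)
        pd.testing.assert_frame_equal(offline, run.query_votes)

    def test_classify_queries_needs_stored_forests(self, strong_signal):
        normalized, labels, de = strong_signal
        run = run_cv_forests(normalized, labels, quick("top_de", seed=19),
                             de_ranking=de)
        with pytest.raises(ValueError, match="store_forests"):
            classify_queries(run, normalized.iloc[:, :2])
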