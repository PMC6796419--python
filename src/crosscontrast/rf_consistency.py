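"""Random-forest classification consistency with a permutation null.

Protocol: many repetitions of (stratified 75/25 train/test split, gene-panel
selection, forest training, held-out scoring), in three panel modes --
``top_de`` (the most significant genes of a reference DE analysis),
``random`` (a uniform gene panel), and ``null`` (random panel AND shuffled
training labels, which destroys any real signal and calibrates the
protocol: test accuracy must hover at 0.5).  Held-out "query" samples (e.g.
samples of a third group never seen in training) are pushed through every
repetition's forest and their per-class vote fractions averaged: the
classification consistency of a query is the fraction of trees voting each
class.

Accuracy here is vote-weighted: the mean, over test samples, of the
fraction of trees voting the sample's true label, matching how consistency
is reported for queries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = ["ForestProtocol", "ForestRunResult", "run_cv_forests", "classify_queries"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class ForestProtocol:
    """Tunables of the repetition protocol.

    Defaults follow the study protocol (20000 trees, 250-gene panels, 75%
    stratified training fraction, 1000 repetitions); tests and small runs
    scale ``n_trees``/``n_repetitions`` down since vote fractions converge
    far earlier.
    """

    n_trees: int = 20000
    panel_size: int = 250
    panel_mode: str = "top_de"  # 'top_de' | 'random' | 'null'
    train_fraction: float = 0.75
    n_repetitions: int = 1000
    null_label_mode: str = "uniform"  # 'uniform' | 'permute'
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.panel_mode not in ("top_de", "random", "null"):
            raise ValueError(f"unknown panel_mode {self.panel_mode!r}")
        if self.null_label_mode not in ("uniform", "permute"):
            raise ValueError(f"unknown null_label_mode {self.null_label_mode!r}")
        if self.panel_size < 1 or self.n_trees < 1 or self.n_repetitions < 1:
            raise ValueError("panel_size, n_trees, n_repetitions must be >= 1")


@dataclass
class ForestRunResult:
    """Per-repetition metrics, their aggregate, and query vote fractions."""

    per_repetition: pd.DataFrame       # one row per repetition
    summary: pd.DataFrame              # mean/sd per metric (Table-style)
    query_votes: pd.DataFrame | None   # query x class mean vote fractions
    classes: tuple[str, str]
    pos_label: str
    forests: list | None = None        # (forest, panel) pairs if stored

    @property
    def mean_test_accuracy(self) -> float:
        return float(self.per_repetition["test_accuracy"].mean())


def _top_de_panel(de_ranking: pd.DataFrame, available: pd.Index, size: int) -> list[str]:
    """Most significant genes: smallest padj, ties by |L2FC| desc then gene id."""
    de = de_ranking.loc[de_ranking.index.isin(available)].copy()
    de["_abs_lfc"] = -de["log2FoldChange"].abs()
    # stable mergesort over a gene-id-presorted frame: gene id is the final tiebreak
    de = de.sort_index().sort_values(["padj", "_abs_lfc"], kind="mergesort",
                                     na_position="last")
    return de.index[:size].tolist()


def run_cv_forests(normalized: pd.DataFrame, labels: pd.Series,
                   protocol: ForestProtocol,
                   de_ranking: pd.DataFrame | None = None,
                   queries: pd.DataFrame | None = None,
                   pos_label: str | None = None,
                   store_forests: bool = False) -> ForestRunResult:
    """Run the repetition protocol on a normalized genes x samples matrix.

    ``labels`` (indexed by sample id) must have exactly two classes with at
    least two samples each.  ``queries`` is an optional genes x samples
    matrix of held-out samples scored by every repetition's forest.
    Sensitivity is the vote-weighted true-positive rate for ``pos_label``
    (default: the lexicographically larger class, so disease labels like
    ``HD`` beat ``C``); specificity is the same for the other class.
    """
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs >= 2 samples")
    if protocol.panel_mode == "top_de" and de_ranking is None:
        raise ValueError("panel_mode='top_de' requires de_ranking")
    if protocol.panel_size > normalized.shape[0]:
        raise ValueError("panel_size exceeds the number of available genes")
    if queries is not None:
        missing = normalized.index.difference(queries.index)
        if len(missing):
            raise ValueError(f"query samples missing panel genes: "
                             f"{missing[:5].tolist()}")

    neg, pos = classes
    if pos_label is not None:
        if pos_label not in classes:
            raise ValueError(f"pos_label {pos_label!r} not in {classes}")
        pos = pos_label
        neg = classes[0] if classes[1] == pos else classes[1]
    else:
        pos = classes[-1]
        neg = classes[0]

    X_all = normalized.T  # samples x genes
    labels = labels.loc[X_all.index]
    y = labels.to_numpy()
    sample_idx = {c: np.where(y == c)[0] for c in classes}

    master = np.random.default_rng(protocol.seed)
    rep_rows = []
    vote_sum = None
    forests = [] if store_forests else None

    top_panel = None
    if protocol.panel_mode == "top_de":
        top_panel = _top_de_panel(de_ranking, normalized.index, protocol.panel_size)

    for rep in range(protocol.n_repetitions):
        rng = np.random.default_rng(master.integers(_MAX_SEED))
        # stratified split mirroring the class ratio
        while True:
            train_idx, test_idx = [], []
            for c in classes:
                idx = sample_idx[c].copy()
                rng.shuffle(idx)
                n_train = int(round(protocol.train_fraction * len(idx)))
                n_train = min(max(n_train, 1), len(idx) - 1)
                train_idx.extend(idx[:n_train])
                test_idx.extend(idx[n_train:])
            train_idx, test_idx = np.array(train_idx), np.array(test_idx)
            if (len(set(y[train_idx])) == 2 and len(set(y[test_idx])) == 2):
                break

        if protocol.panel_mode == "top_de":
            panel = top_panel
        else:
            panel = list(rng.choice(normalized.index.to_numpy(),
                                    size=protocol.panel_size, replace=False))
        panel = sorted(panel)  # canonical order: votes invariant to gene order
        y_train = y[train_idx].copy()
        if protocol.panel_mode == "null":
            # training labels only; test keeps truth.  'uniform' severs the
            # class prior as well as the signal, so a calibrated protocol
            # gives vote fractions near 1/2 regardless of class imbalance
            if protocol.null_label_mode == "uniform":
                while True:
                    y_train = np.array(classes)[rng.integers(2, size=len(train_idx))]
                    if len(set(y_train)) == 2:
                        break
            else:
                rng.shuffle(y_train)

        X_train = X_all.iloc[train_idx][panel].to_numpy()
        X_test = X_all.iloc[test_idx][panel].to_numpy()
        forest = RandomForestClassifier(
            n_estimators=protocol.n_trees, max_features="sqrt",
            random_state=int(rng.integers(_MAX_SEED)), n_jobs=1)
        forest.fit(X_train, y_train)

        def _vote_metrics(X, y_true):
            proba = forest.predict_proba(X)
            class_order = list(forest.classes_)
            p_pos = (proba[:, class_order.index(pos)] if pos in class_order
                     else np.zeros(len(X)))
            true_pos = y_true == pos
            acc = np.where(true_pos, p_pos, 1.0 - p_pos).mean()
            sens = p_pos[true_pos].mean() if true_pos.any() else np.nan
            spec = (1.0 - p_pos[~true_pos]).mean() if (~true_pos).any() else np.nan
            return acc, sens, spec

        # train accuracy is hard majority-vote (fully grown trees memorize the
        # training set, so this is 1 even under the null); test metrics are
        # vote-weighted, the "fraction of trees" semantics used for queries
        train_acc = float((forest.predict(X_train) == y_train).mean())
        test_acc, sens, spec = _vote_metrics(X_test, y[test_idx])
        rep_rows.append({
            "train_accuracy": train_acc, "test_accuracy": test_acc,
            "sensitivity": sens, "specificity": spec,
            "false_positive": 1.0 - spec if np.isfinite(spec) else np.nan,
            "false_negative": 1.0 - sens if np.isfinite(sens) else np.nan,
        })

        if queries is not None:
            Q = queries.loc[panel].T.to_numpy()
            proba = forest.predict_proba(Q)
            cols = {c: (proba[:, list(forest.classes_).index(c)]
                        if c in forest.classes_ else np.zeros(len(Q)))
                    for c in classes}
            votes = pd.DataFrame(cols, index=queries.columns)
            vote_sum = votes if vote_sum is None else vote_sum + votes
        if store_forests:
            forests.append((forest, panel))

    per_rep = pd.DataFrame(rep_rows)
    summary = pd.DataFrame({"mean": per_rep.mean(), "sd": per_rep.std(ddof=1)})
    query_votes = vote_sum / protocol.n_repetitions if vote_sum is not None else None
    return ForestRunResult(per_repetition=per_rep, summary=summary,
                           query_votes=query_votes, classes=(neg, pos),
                           pos_label=pos, forests=forests)


def classify_queries(run: ForestRunResult, queries: pd.DataFrame) -> pd.DataFrame:
    """Average vote fractions for query samples over a run's stored forests.

    Requires ``run_cv_forests(..., store_forests=True)``.  ``queries`` is a
    genes x samples matrix covering every panel gene.
    """
    if not run.forests:
        raise ValueError("run has no stored forests; rerun with store_forests=True")
    classes = list(run.classes)
    total = None
    for forest, panel in run.forests:
        missing = [g for g in panel if g not in queries.index]
        if missing:
            raise ValueError(f"query samples missing panel genes: {missing[:5]}")
        proba = forest.predict_proba(queries.loc[panel].T.to_numpy())
        cols = {c: (proba[:, list(forest.classes_).index(c)]
                    if c in forest.classes_ else np.zeros(queries.shape[1]))
                for c in classes}
        votes = pd.DataFrame(cols, index=queries.columns)
        total = votes if total is None else total + votes
    return total / len(run.forests)
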