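"""Scoring inferred networks against gold standards.

Accuracy is computed over all m(m-1) ordered gene pairs excluding
self-loops: every ordered pair is labelled predicted present/absent (Step-3
semantics) and gold present/absent, and accuracy = (TP + TN) / m(m-1).  A
directed edge predicted in the wrong orientation therefore counts as one
false positive plus one false negative.  An unordered variant (pair linked
in either direction) is reported alongside for transparency.

Two significance tests support the threshold choices: a two-sample
Student's t test (equal variances by default) separating induced from
repressed expression values (justifying tau) and present from absent
influence values (justifying epsilon), and a Wilcoxon signed-rank test for
paired accuracy comparisons across parameter settings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import EdgeSet, Network
from .exceptions import ValidationError


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts over ordered pairs and the derived accuracies."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    universe_size: int
    accuracy_unordered: float

    def __post_init__(self):
        m = self.universe_size
        if self.tp + self.fp + self.tn + self.fn != m * (m - 1):
            raise ValidationError("confusion counts must cover all ordered pairs")


def score_network(predicted: Network, gold: EdgeSet, universe=None) -> EvalReport:
    """Confusion counts and accuracy of a predicted network vs a gold standard."""
    shared = frozenset(universe) if universe is not None else gold.universe
    if not predicted.universe <= shared:
        extra = sorted(predicted.universe - shared)
        raise ValidationError(
            f"predicted universe has genes outside the evaluation universe: {extra[:5]}"
        )
    pred = predicted.edge_pairs()
    gold_present = {e for e in gold.present if e[0] in shared and e[1] in shared}
    m = len(shared)
    total = m * (m - 1)
    tp = len(pred & gold_present)
    fp = len(pred - gold_present)
    fn = len(gold_present - pred)
    tn = total - tp - fp - fn
    accuracy = (tp + tn) / total if total else 1.0

    pred_u = {frozenset(e) for e in pred}
    gold_u = {frozenset(e) for e in gold_present}
    total_u = total // 2
    tp_u = len(pred_u & gold_u)
    wrong_u = len(pred_u ^ gold_u)
    acc_u = (total_u - wrong_u) / total_u if total_u else 1.0
    return EvalReport(tp, fp, tn, fn, accuracy, m, acc_u)


def all_absent_accuracy(gold: EdgeSet, universe=None) -> float:
    """Accuracy of the trivial predictor that declares every edge absent."""
    shared = frozenset(universe) if universe is not None else gold.universe
    m = len(shared)
    total = m * (m - 1)
    present = len({e for e in gold.present if e[0] in shared and e[1] in shared})
    return (total - present) / total if total else 1.0


def average_accuracy(reports) -> float:
    """Unweighted mean accuracy over per-dataset reports (or bare floats)."""
    values = [getattr(r, "accuracy", r) for r in reports]
    if not values:
        raise ValidationError("average_accuracy needs at least one report")
    return float(np.mean(values))


def separation_test(group_a, group_b, equal_var: bool = True):
    """Two-sample Student's t test for a difference of means.

    Returns (t statistic, two-sided p).  Degenerate zero-variance inputs:
    equal means give (0, 1) by convention; unequal means give p = 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def paired_rank_test(differences) -> float:
    """Two-sided Wilcoxon signed-rank p for paired score differences.

    Zero differences are dropped; all-zero input returns p = 1.
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    return float(stats.wilcoxon(d, alternative="two-sided", method="auto").pvalue)


def run_benchmark(dataset_gold_pairs, config=None, algorithm: str = "M2",
                  n_workers: int = 1, n_reducers: int | None = None) -> dict:
    """Score one inference configuration over several benchmark datasets.

    ``dataset_gold_pairs`` is an iterable of (TimeSeriesDataset, EdgeSet).
    Runs the chosen algorithm with the given configuration on each dataset,
    scores it against its gold standard over the dataset's gene universe,
    and returns per-dataset accuracies, their unweighted mean, and the full
    configuration used (the achieved value is only meaningful alongside the
    MI estimator settings).
    """
    from . import engine

    cfg = config or engine.InferenceConfig()
    reducers = n_reducers if n_reducers is not None else engine.DEFAULT_N_REDUCERS
    reports = []
    for dataset, gold in dataset_gold_pairs:
        result = engine.run(dataset, algorithm, cfg, n_workers, reducers)
        universe = frozenset(dataset.gene_ids) | gold.universe
        reports.append(score_network(result.network, gold, universe))
    if not reports:
        raise ValidationError("benchmark needs at least one dataset")
    return {
        "reports": reports,
        "accuracies": [r.accuracy for r in reports],
        "mean_accuracy": average_accuracy(reports),
        "algorithm": algorithm.upper(),
        "config": cfg.as_params(),
    }


def ordered_pairs(universe):
    """All ordered gene pairs (x, y), x != y, over a universe."""
    genes = sorted(universe)
    return itertools.permutations(genes, 2)
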