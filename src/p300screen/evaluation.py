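"""Selection performance as a function of accumulated trials.

Each evaluation repetition yields one selected marker; the selection labels
that marker target and the remaining n_markers - 1 nontarget, so a wrong
selection costs exactly one target (missed) and one nontarget (falsely
selected).  Sensitivity, specificity, and accuracy follow from the counts
j (correct targets) and k (correct nontargets); curves report them per
number of accumulated trials l, aggregated across subjects by median and
interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from p300screen.classifier import ScoreMatrix, select_target
from p300screen.errors import ConfigurationError

DEFAULT_L_VALUES = tuple(range(1, 11))


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of one evaluation set: j correct targets, k correct nontargets."""

    j: int
    k: int
    n_reps: int = 9
    n_markers: int = 12

    def __post_init__(self) -> None:
        if not 0 <= self.j <= self.n_reps:
            raise ConfigurationError("j must lie in [0, n_reps]")
        if not 0 <= self.k <= self.n_reps * (self.n_markers - 1):
            raise ConfigurationError("k out of range")


def confusion_from_selections(
    selections: list[int], truths: list[int], n_markers: int = 12
) -> ConfusionCounts:
    """Count correct targets and nontargets under one-selection-per-repetition.

    A correct repetition credits the target and all n_markers - 1 nontargets;
    a wrong one misses the target and mislabels one nontarget, so
    k = n_reps * (n_markers - 1) - (n_reps - j).
    """
    if len(selections) != len(truths):
        raise ConfigurationError("selections and truths must have equal length")
    n_reps = len(truths)
    j = int(sum(s == t for s, t in zip(selections, truths)))
    k = n_reps * (n_markers - 1) - (n_reps - j)
    return ConfusionCounts(j=j, k=k, n_reps=n_reps, n_markers=n_markers)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at full precision."""
    if counts.n_reps < 1:
        raise ConfigurationError("need at least one evaluation repetition")
    n_nontargets = counts.n_reps * (counts.n_markers - 1)
    if n_nontargets < 1:
        raise ConfigurationError("need at least one nontarget per repetition")
    sensitivity = counts.j / counts.n_reps
    specificity = counts.k / n_nontargets
    accuracy = (counts.j + counts.k) / (counts.n_reps * counts.n_markers)
    return sensitivity, specificity, accuracy


def curve_by_l(
    score_matrices: list[ScoreMatrix],
    l_values: tuple[int, ...] = DEFAULT_L_VALUES,
    n_markers: int | None = None,
) -> pd.DataFrame:
    """Metrics per accumulated-trial count l for one subject.

    Every score matrix must carry its true target and at least max(l) trials.
    """
    if not score_matrices:
        raise ConfigurationError("no evaluation repetitions")
    if any(sm.true_target is None for sm in score_matrices):
        raise ConfigurationError("score matrices must carry true_target")
    max_l = max(l_values)
    if any(sm.n_trials < max_l for sm in score_matrices):
        raise ConfigurationError(f"every repetition needs >= {max_l} trials")
    if n_markers is None:
        n_markers = score_matrices[0].n_markers
    truths = [int(sm.true_target) for sm in score_matrices]
    rows = []
    for l in l_values:
        selections = [select_target(sm, l).selected for sm in score_matrices]
        counts = confusion_from_selections(selections, truths, n_markers)
        sens, spec, acc = metrics(counts)
        rows.append(
            {
                "l": l,
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
                "j": counts.j,
                "k": counts.k,
            }
        )
    return pd.DataFrame(rows)


def aggregate_curves(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject median and IQR (linear-interpolation quartiles) per l."""
    if not curves:
        raise ConfigurationError("no subject curves to aggregate")
    stacked = pd.concat(curves, ignore_index=True)
    rows = []
    for l, grp in stacked.groupby("l"):
        row = {"l": int(l)}
        for metric in ("sensitivity", "specificity", "accuracy"):
            q1, med, q3 = grp[metric].quantile([0.25, 0.5, 0.75], interpolation="linear")
            row[f"{metric}_median"] = med
            row[f"{metric}_q1"] = q1
            row[f"{metric}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows).sort_values("l", ignore_index=True)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based area under the ROC curve of labeled scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ConfigurationError("AUROC needs both classes present")
    return float(roc_auc_score(labels == labels.max(), scores))


def auroc_by_l(
    score_matrices: list[ScoreMatrix],
    l_values: tuple[int, ...] = DEFAULT_L_VALUES,
) -> np.ndarray:
    """AUROC per l on accumulated marker scores pooled over repetitions.

    At each l, every (repetition, marker) contributes its accumulated score,
    labeled target when the marker is the repetition's true target.
    """
    values = []
    for l in l_values:
        pooled_scores, pooled_labels = [], []
        for sm in score_matrices:
            acc = sm.scores[:, :l].sum(axis=1)
            pooled_scores.append(acc)
            labels = np.zeros(sm.n_markers, dtype=int)
            labels[int(sm.true_target)] = 1
            pooled_labels.append(labels)
        values.append(auroc(np.concatenate(pooled_scores), np.concatenate(pooled_labels)))
    return np.asarray(values)


def subject_summary(
    score_matrices: list[ScoreMatrix],
    l_report: int = 10,
    l_values: tuple[int, ...] = DEFAULT_L_VALUES,
) -> dict:
    """Per-subject report row at l = l_report: j, k, AUROC mean (SD) over l,
    and the three metrics, mirroring a per-subject results table."""
    curve = curve_by_l(score_matrices, l_values)
    row = curve[curve["l"] == l_report].iloc[0]
    aucs = auroc_by_l(score_matrices, l_values)
    return {
        "j": int(row["j"]),
        "k": int(row["k"]),
        "sensitivity": float(row["sensitivity"]),
        "specificity": float(row["specificity"]),
        "accuracy": float(row["accuracy"]),
        "auroc_mean": float(aucs.mean()),
        "auroc_sd": float(aucs.std(ddof=1)),
        "m_correct": int(row["j"] + row["k"]),
    }
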