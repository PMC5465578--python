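"""Evaluation protocol: cross-validation, robustness designs, PPV calibration.

Model quality is assessed by rank-based AUC and by confusion metrics at a
DDI-score threshold (default 0, the lowest threshold consistent with the
synergy definition).  Because positives are rare among all drug pairs,
the positive predictive value PPV = TP / (TP + FP) is the operationally
relevant metric; thresholds on the 0-100 normalized DDI score are
calibrated to reach target PPV levels by cross-validation.

The robustness designs probe sensitivity to training-set composition:

* **Type I** trains on a fraction of the positives plus half of the
  baseline pairs and tests on the remainder.
* **Type II** additionally moves half of the test-set positives into the
  training baseline class (planted false negatives).
* **Type III** moves test-set baseline pairs — as many as there are true
  training positives — into the training positive class (planted false
  positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ddisyn.profiles import PairUniverse
from ddisyn.scoring import laplace_corrected_weights, pair_ddi_scores

DEFAULT_MIN_POSITIVES = 50
DEFAULT_PPV_TARGETS = (0.10, 0.20, 0.30, 0.40, 0.50)
DEFAULT_THRESHOLD_GRID = tuple(range(0, 100, 10))


@dataclass
class MetricsReport:
    """Confusion metrics (and optionally AUC) at one score threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float | None = None
    auc: float | None = None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def ppv(self) -> float | None:
        """Precision; None (undefined, not 0) when nothing is called positive."""
        d = self.tp + self.fp
        return self.tp / d if d else None

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class RobustnessDesign:
    """One cell of the robustness experiment grid."""

    model_type: str                   # "I", "II", or "III"
    positive_fraction: float
    repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in ("I", "II", "III"):
            raise ValueError(f"unknown model type: {self.model_type!r}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def confusion_metrics(
    predictions: Sequence[bool],
    labels: Sequence[bool],
    threshold: float | None = None,
) -> MetricsReport:
    """Exact confusion counts and the derived ratios."""
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty input")
    tp = int((predictions & labels).sum())
    fp = int((predictions & ~labels).sum())
    tn = int((~predictions & ~labels).sum())
    fn = int((~predictions & labels).sum())
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold)


def fold_enrichment(ppv: float, baseline_rate: float) -> float:
    """How many times better than random a positive call is."""
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    return ppv / baseline_rate


def min_positives_gate(positives_count: int, minimum: int = DEFAULT_MIN_POSITIVES) -> bool:
    """Models need at least ``minimum`` positive pairs to be trainable."""
    return positives_count >= minimum


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Pooled held-out scores and metrics from one k-fold run."""

    pooled: MetricsReport
    folds: list[MetricsReport]
    scores: np.ndarray           # held-out raw DDI scores (row order of universe)
    norm_scores: np.ndarray      # held-out scores on each fold model's 0-100 scale
    labels: np.ndarray
    fold_model_max: list[float]


def _positive_mask(universe: PairUniverse, positives: Iterable[str]) -> np.ndarray:
    positives = set(positives)
    return np.fromiter(
        (pid in positives for pid in universe.pair_ids),
        dtype=bool,
        count=len(universe),
    )


def _fit_fold(universe: PairUniverse, train_rows: np.ndarray, pos_rows: np.ndarray):
    """Weights and training-universe max DDI for one training split."""
    bits = universe.pair_bits
    n_total = len(train_rows)
    n_b = bits[train_rows].sum(axis=0, dtype=np.int64)
    n_a = bits[pos_rows].sum(axis=0, dtype=np.int64)
    w = laplace_corrected_weights(n_b, n_a, n_total, len(pos_rows))
    train_ddi = pair_ddi_scores(
        universe.drugs.matrix,
        universe.i_idx[train_rows],
        universe.j_idx[train_rows],
        w,
    )
    return w, float(train_ddi.max()) if len(train_ddi) else 0.0


def kfold_cv(
    universe: PairUniverse,
    positives: Iterable[str],
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.0,
) -> CVResult:
    """Stratified k-fold cross-validation of one ADR model.

    Positive and baseline pairs are segregated into k groups
    independently; each group is held out exactly once.  Metrics are
    reported per fold and pooled over all held-out predictions (pooling
    is primary: per-fold PPV is unstable when positives are rare).
    """
    pos_mask = _positive_mask(universe, positives)
    pos_idx = np.nonzero(pos_mask)[0]
    base_idx = np.nonzero(~pos_mask)[0]
    if len(pos_idx) < k or len(base_idx) < k:
        raise ValueError(
            f"need at least k={k} pairs in each class, "
            f"got {len(pos_idx)} positive / {len(base_idx)} baseline"
        )
    rng = np.random.default_rng(seed)
    pos_folds = np.array_split(rng.permutation(pos_idx), k)
    base_folds = np.array_split(rng.permutation(base_idx), k)

    n = len(universe)
    scores = np.full(n, np.nan)
    norm_scores = np.full(n, np.nan)
    folds: list[MetricsReport] = []
    fold_max: list[float] = []
    for f in range(k):
        test_rows = np.concatenate([pos_folds[f], base_folds[f]])
        train_pos = np.concatenate([pos_folds[g] for g in range(k) if g != f])
        train_base = np.concatenate([base_folds[g] for g in range(k) if g != f])
        train_rows = np.concatenate([train_pos, train_base])
        w, m_max = _fit_fold(universe, train_rows, train_pos)
        fold_max.append(m_max)
        test_scores = pair_ddi_scores(
            universe.drugs.matrix,
            universe.i_idx[test_rows],
            universe.j_idx[test_rows],
            w,
        )
        scores[test_rows] = test_scores
        if m_max > 0:
            norm_scores[test_rows] = 100.0 * test_scores / m_max
        test_labels = pos_mask[test_rows]
        report = confusion_metrics(test_scores > threshold, test_labels, threshold)
        if test_labels.any() and not test_labels.all():
            report.auc = auc(test_scores, test_labels)
        folds.append(report)

    pooled = confusion_metrics(scores > threshold, pos_mask, threshold)
    pooled.auc = auc(scores, pos_mask)
    return CVResult(
        pooled=pooled,
        folds=folds,
        scores=scores,
        norm_scores=norm_scores,
        labels=pos_mask,
        fold_model_max=fold_max,
    )


# ---------------------------------------------------------------------------
# Robustness experiments


def robustness_experiment(
    universe: PairUniverse,
    positives: Iterable[str],
    design: RobustnessDesign,
) -> list[float]:
    """Per-repeat test-set AUC under one robustness design.

    Each repeat redraws the training/test split from a deterministic
    sub-seed.  With zero planted noise (e.g. fewer than two test
    positives for type II) the type II/III paths reduce exactly to
    type I under the same seed.
    """
    pos_mask = _positive_mask(universe, positives)
    pos_idx = np.nonzero(pos_mask)[0]
    base_idx = np.nonzero(~pos_mask)[0]
    if len(pos_idx) < 1:
        raise ValueError("no positive pairs")
    aucs: list[float] = []
    for r in range(design.repeats):
        rng = np.random.default_rng([design.seed, r])
        p = rng.permutation(pos_idx)
        b = rng.permutation(base_idx)
        n_tp = max(1, int(round(design.positive_fraction * len(p))))
        if n_tp >= len(p):
            raise ValueError("positive fraction leaves no test positives")
        train_pos, test_pos = p[:n_tp], p[n_tp:]
        n_tb = len(b) // 2  # half of the baseline (rounded down) trains
        train_base, test_base = b[:n_tb], b[n_tb:]

        if design.model_type == "II":
            n_move = len(test_pos) // 2
            moved, test_pos = test_pos[:n_move], test_pos[n_move:]
            train_base = np.concatenate([train_base, moved])
        elif design.model_type == "III":
            n_fp = len(train_pos)  # as many false positives as true ones
            if n_fp > len(test_base):
                raise ValueError("not enough baseline pairs for type III design")
            moved, test_base = test_base[:n_fp], test_base[n_fp:]
            train_pos = np.concatenate([train_pos, moved])

        train_rows = np.concatenate([train_pos, train_base])
        w, _ = _fit_fold(universe, train_rows, train_pos)
        test_rows = np.concatenate([test_pos, test_base])
        test_scores = pair_ddi_scores(
            universe.drugs.matrix,
            universe.i_idx[test_rows],
            universe.j_idx[test_rows],
            w,
        )
        test_labels = np.zeros(len(test_rows), dtype=bool)
        test_labels[: len(test_pos)] = True
        aucs.append(auc(test_scores, test_labels))
    return aucs


def robustness_grid(
    universe: PairUniverse,
    positives: Iterable[str],
    fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    model_types: Sequence[str] = ("I", "II", "III"),
    repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Full experiment grid as tidy rows (model_type, fraction, repeat, auc)."""
    positives = set(positives)
    rows = []
    for model_type in model_types:
        for fraction in fractions:
            design = RobustnessDesign(model_type, fraction, repeats=repeats, seed=seed)
            for r, value in enumerate(robustness_experiment(universe, positives, design)):
                rows.append((model_type, fraction, r, value))
    return pd.DataFrame(rows, columns=["model_type", "fraction", "repeat", "auc"])


# ---------------------------------------------------------------------------
# PPV threshold calibration


def cv_threshold_metrics(
    cv: CVResult,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> pd.DataFrame:
    """Pooled metrics at each normalized-score threshold of the grid."""
    rows = []
    for t in grid:
        report = confusion_metrics(cv.norm_scores > t, cv.labels, threshold=t)
        d = report.as_dict()
        d["auc"] = cv.pooled.auc
        rows.append(d)
    return pd.DataFrame(rows)


def calibrate_ppv_thresholds(
    universe: PairUniverse,
    positives: Iterable[str],
    targets: Sequence[float] = DEFAULT_PPV_TARGETS,
    k: int = 10,
    seed: int = 0,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> dict[float, float | None]:
    """Smallest normalized threshold reaching each PPV target under k-fold CV.

    A target no grid threshold reaches — including thresholds where no
    pair is called positive (PPV undefined) — maps to None (unreachable).
    """
    cv = kfold_cv(universe, positives, k=k, seed=seed)
    table = cv_threshold_metrics(cv, grid=grid)
    out: dict[float, float | None] = {}
    for target in targets:
        reached = table[(table["ppv"].notna()) & (table["ppv"] >= target)]
        out[target] = float(reached["threshold"].iloc[0]) if len(reached) else None
    return out
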