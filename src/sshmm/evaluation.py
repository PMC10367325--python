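"""Validation of semi-supervised behavioural classification.

The validation design mirrors a k-fold analysis built from repeated
random hold-outs: 10 independent random samples of 10% of the fixes
with a sensor-derived known state are set aside as test sets, the rest
form the training pool from which supervision subsets are drawn. For a
grid of supervision fractions (measured against *all* modelled fixes,
not only known ones), a model is refitted per fraction x fold with the
sampled known states enforced, decoded by Viterbi, and scored on the
fold's test fixes with a 3x3 confusion matrix (rows = reference labels,
columns = predictions) and its global accuracy plus class-wise
sensitivity, specificity and precision. Optionally, fixes whose maximum
smoothed state probability falls below a threshold (0.9 by default) are
removed before scoring, trading coverage for confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hmm
from .sensor_fusion import FORAGE, REST, TRAVEL, LABEL_NAMES

__all__ = [
    "FoldPlan",
    "confusion_matrix",
    "MetricSet",
    "metric_set",
    "make_folds",
    "subsample_supervision",
    "evaluate_fold",
    "threshold_filter",
    "supervision_sweep",
    "max_feasible_fraction",
]

CLASSES = (REST, FORAGE, TRAVEL)


@dataclass
class FoldPlan:
    """Independent random test samples of the known-state fixes."""

    test_idx: list[np.ndarray]
    train_pool_idx: list[np.ndarray]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.test_idx)


def make_folds(
    known_idx: np.ndarray,
    n_folds: int = 10,
    test_frac: float = 0.10,
    seed: int = 0,
) -> FoldPlan:
    """Draw ``n_folds`` independent test samples of known-state fixes.

    Each fold samples ``test_frac`` of the known fixes without
    replacement (independently across folds, so folds may overlap —
    repeated random sub-sampling, not a partition); the complement is
    that fold's training pool.
    """
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    known_idx = np.asarray(known_idx)
    n = len(known_idx)
    if n < n_folds:
        raise ValueError(f"{n} known fixes < {n_folds} folds")
    n_test = max(int(round(test_frac * n)), 1)
    rng = np.random.default_rng(seed)
    tests, pools = [], []
    for _ in range(n_folds):
        t = rng.choice(known_idx, size=n_test, replace=False)
        tests.append(np.sort(t))
        pools.append(np.setdiff1d(known_idx, t))
    return FoldPlan(tests, pools, seed)


def subsample_supervision(
    train_pool: np.ndarray, dataset_size: int, fraction: float, seed: int = 0
) -> np.ndarray:
    """Sample the supervised fix set for one model.

    ``fraction`` is measured against all ``dataset_size`` fixes in the
    modelled dataset — so a dataset where only a small share of fixes is
    known has a correspondingly low feasible ceiling.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_sup = int(round(fraction * dataset_size))
    pool = np.asarray(train_pool)
    if n_sup > len(pool):
        raise ValueError(
            f"fraction {fraction} needs {n_sup} supervised fixes but the "
            f"training pool has only {len(pool)} "
            f"(feasible maximum {len(pool) / dataset_size:.3f})"
        )
    if n_sup == 0:
        return np.empty(0, dtype=pool.dtype)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=n_sup, replace=False))


def max_feasible_fraction(
    pool_size: int, dataset_size: int, step: float = 0.05
) -> float:
    """Largest multiple of ``step`` whose supervised-set size fits the pool."""
    return np.floor((pool_size / dataset_size) / step) * step


def confusion_matrix(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """3x3 counts, rows = reference (known) labels, columns = predictions."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("length mismatch")
    cm = np.zeros((3, 3), dtype=int)
    for r in CLASSES:
        for p in CLASSES:
            cm[r, p] = int(np.sum((reference == r) & (predicted == p)))
    return cm


@dataclass
class MetricSet:
    """Global accuracy plus class-wise sensitivity/specificity/precision.

    Class metrics with a zero denominator are NaN (undefined) and are
    excluded from aggregation.
    """

    accuracy: float
    sensitivity: dict[int, float] = field(default_factory=dict)
    specificity: dict[int, float] = field(default_factory=dict)
    precision: dict[int, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {"accuracy": self.accuracy}
        for c in CLASSES:
            name = LABEL_NAMES[c].lower()
            row[f"sensitivity_{name}"] = self.sensitivity[c]
            row[f"specificity_{name}"] = self.specificity[c]
            row[f"precision_{name}"] = self.precision[c]
        return row


def metric_set(cm: np.ndarray) -> MetricSet:
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    acc = np.trace(cm) / total if total > 0 else np.nan
    sens, spec, prec = {}, {}, {}
    for c in CLASSES:
        tp = cm[c, c]
        fn = cm[c, :].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec[c] = tn / (tn + fp) if tn + fp > 0 else np.nan
        prec[c] = tp / (tp + fp) if tp + fp > 0 else np.nan
    return MetricSet(acc, sens, spec, prec)


def threshold_filter(state_probs: np.ndarray, threshold: float = 0.90) -> np.ndarray:
    """Boolean mask of fixes whose maximum state probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return np.asarray(state_probs).max(axis=1) >= threshold


def evaluate_fold(
    predicted_labels: np.ndarray,
    known_labels: np.ndarray,
    test_idx: np.ndarray,
    supervised_idx: np.ndarray | None = None,
    retain_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, MetricSet]:
    """Score decoded labels against known labels on the test fixes only.

    ``supervised_idx`` is checked for leakage (test fixes must not have
    been supervised during fitting). ``retain_mask`` optionally restricts
    scoring to threshold-retained fixes.
    """
    test_idx = np.asarray(test_idx)
    if len(test_idx) == 0:
        raise ValueError("empty test set")
    if supervised_idx is not None and np.intersect1d(test_idx, supervised_idx).size:
        raise ValueError("supervision leaked into the test set")
    if retain_mask is not None:
        test_idx = test_idx[retain_mask[test_idx]]
    cm = confusion_matrix(known_labels[test_idx], predicted_labels[test_idx])
    return cm, metric_set(cm)


def _fit_and_decode(obs, supervised_known, n_restarts, seed, maxiter):
    fit_res = hmm.fit(
        obs.with_known(supervised_known),
        n_restarts=n_restarts,
        seed=seed,
        maxiter=maxiter,
    )
    sup_obs = obs.with_known(supervised_known)
    mapping = hmm.label_states(fit_res)
    states = hmm.map_states(
        hmm.viterbi(fit_res.emissions, fit_res.gamma_mat, sup_obs), mapping
    )
    probs_raw = hmm.state_probabilities(fit_res.emissions, fit_res.gamma_mat, sup_obs)
    # reorder posterior columns into biological-label order
    col = np.empty(3, dtype=int)
    for state_idx, label in mapping.items():
        col[label] = state_idx
    return fit_res, states, probs_raw[:, col], mapping


def supervision_sweep(
    obs: hmm.Observations,
    known_labels: np.ndarray,
    fractions: list[float],
    fold_plan: FoldPlan,
    thresholds: list[float] = (0.90,),
    n_restarts: int = 10,
    seed: int = 0,
    maxiter: int = 300,
) -> pd.DataFrame:
    """Fit, decode and score one model per supervision fraction x fold.

    ``known_labels`` is the flat per-fix label vector (-1 where unknown).
    Returns a tidy frame with one row per fraction x fold x threshold
    setting (threshold NaN = unfiltered), confusion counts and metrics;
    aggregated mean +/- sd per fraction under ``df.attrs['summary']``.
    Fit failures are flagged rows, not aborts.
    """
    fractions = list(fractions)
    if len(set(fractions)) < len(fractions):
        warnings.warn("duplicate fractions merged in aggregation")
    n = obs.n_fixes
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        for fold in range(fold_plan.n_folds):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pool = fold_plan.train_pool_idx[fold]
            try:
                sup_idx = subsample_supervision(pool, n, frac, seed=sub_seed)
                sup_known = np.full(n, -1, dtype=int)
                sup_known[sup_idx] = known_labels[sup_idx]
                _, states, probs, mapping = _fit_and_decode(
                    obs, sup_known, n_restarts, sub_seed, maxiter
                )
            except (hmm.FitError, ValueError) as exc:
                rows.append(
                    {"fraction": frac, "fold": fold, "threshold": np.nan,
                     "failed": True, "error": str(exc)}
                )
                continue
            test_idx = fold_plan.test_idx[fold]
            settings = [None] + list(thresholds)
            for thr in settings:
                retain = None if thr is None else threshold_filter(probs, thr)
                try:
                    cm, ms = evaluate_fold(
                        states, known_labels, test_idx, sup_idx, retain
                    )
                except ValueError:
                    # threshold removed every test fix
                    rows.append(
                        {"fraction": frac, "fold": fold,
                         "threshold": np.nan if thr is None else thr,
                         "failed": True, "error": "no test fixes retained"}
                    )
                    continue
                row = {
                    "fraction": frac,
                    "fold": fold,
                    "threshold": np.nan if thr is None else thr,
                    "failed": False,
                    "error": "",
                    "n_supervised": len(sup_idx),
                    "n_test": int(cm.sum()),
                    "mapping": "".join(
                        LABEL_NAMES[mapping[i]][0] for i in range(3)
                    ),
                }
                for r in CLASSES:
                    for p in CLASSES:
                        row[f"cm_{LABEL_NAMES[r].lower()}_{LABEL_NAMES[p].lower()}"] = cm[r, p]
                row.update(ms.as_row())
                rows.append(row)
    df = pd.DataFrame(rows)
    ok = df[~df["failed"]]
    metric_cols = [c for c in df.columns if c.startswith(("accuracy", "sensitivity", "specificity", "precision"))]
    summary = (
        ok.groupby(["fraction", "threshold"], dropna=False)[metric_cols]
        .agg(["mean", "std", "count"])
        if len(ok)
        else pd.DataFrame()
    )
    df.attrs["summary"] = summary
    return df
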