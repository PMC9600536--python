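"""Cross-validation and hold-out evaluation: F1, AUC, and DeLong's test.

The harness is subject-level throughout: folds and hold-out splits
partition subjects (never individual samples), stratified by class so
that every fold sees both labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .data import MicrobiomeDataset

__all__ = [
    "EvalResult",
    "f1_score",
    "auc_score",
    "delong_test",
    "cross_validate",
    "holdout_split",
    "recovery_scores",
    "rule_model_fitter",
]


def f1_score(labels, predictions) -> float:
    """Harmonic mean of precision and recall; 0 when both are undefined."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    return float(_sk_f1(labels, predictions, zero_division=0))


def auc_score(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney pair statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def _midrank(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based) with ties averaged."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """AUC and its structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = _midrank(combined)
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return auc, v10, v01


def delong_test(labels, scores_a, scores_b):
    """Paired comparison of two AUCs on the same subjects.

    Uses the structural-component covariance estimate of the AUC
    difference; returns (auc_a, auc_b, two-sided p). Identical score
    vectors (zero variance of the difference) give p = 1.
    """
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (len(labels) == len(scores_a) == len(scores_b)):
        raise ValueError("paired test needs equal-length inputs")
    if len(np.unique(labels)) < 2:
        raise ValueError("DeLong test undefined: only one class present")
    auc_a, v10_a, v01_a = _delong_components(labels, scores_a)
    auc_b, v10_b, v01_b = _delong_components(labels, scores_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-16:
        return float(auc_a), float(auc_b), 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(p)


@dataclass
class EvalResult:
    """Fold-level and aggregated cross-validation scores."""

    fold_scores: pd.DataFrame   # seed, repeat, fold, f1, auc, n_test
    aggregate: pd.DataFrame     # one row per (seed, repeat): mean over folds

    def summary(self) -> dict:
        agg = self.aggregate
        return {
            "n_scores": len(agg),
            "f1_mean": float(agg["f1"].mean()),
            "f1_q25": float(agg["f1"].quantile(0.25)),
            "f1_median": float(agg["f1"].median()),
            "f1_q75": float(agg["f1"].quantile(0.75)),
            "auc_mean": float(agg["auc"].mean()),
            "auc_median": float(agg["auc"].median()),
        }


def cross_validate(dataset: MicrobiomeDataset, fitter, k: int = 5,
                   repeats: int = 5, seeds=(0,), stratify: bool = True) -> EvalResult:
    """Stratified repeated k-fold cross-validation.

    `fitter(train_dataset, seed)` must return a callable mapping a dataset
    to per-subject scores in [0, 1]. Folds are re-partitioned for every
    repeat; each (seed, repeat) contributes one aggregate score (the mean
    over its folds), so the result has len(seeds) * repeats aggregates.
    With `stratify=False` plain k-fold is used (enables leave-one-out).
    """
    y = dataset.labels
    if stratify and k > np.bincount(y, minlength=2).min():
        raise ValueError(
            f"k={k} exceeds the smaller class count; lower k, rebalance, "
            "or disable stratification"
        )
    rows = []
    for seed in seeds:
        for rep in range(repeats):
            cls = StratifiedKFold if stratify else KFold
            skf = cls(n_splits=k, shuffle=True,
                      random_state=1_000_000 * (seed + 1) + rep)
            for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
                train = dataset.subset_subjects(tr)
                test = dataset.subset_subjects(te)
                predict = fitter(train, seed)
                scores = np.asarray(predict(test), dtype=float)
                preds = (scores > 0.5).astype(int)
                row = {
                    "seed": seed, "repeat": rep, "fold": fold,
                    "n_test": len(te),
                    "f1": f1_score(test.labels, preds),
                    "auc": auc_score(test.labels, scores)
                    if len(np.unique(test.labels)) > 1 else np.nan,
                }
                rows.append(row)
    fold_scores = pd.DataFrame(rows)
    aggregate = (
        fold_scores.groupby(["seed", "repeat"], as_index=False)[["f1", "auc"]]
        .mean()
    )
    return EvalResult(fold_scores=fold_scores, aggregate=aggregate)


def holdout_split(dataset: MicrobiomeDataset, test_fraction: float,
                  rng: np.random.Generator):
    """Stratified subject-level split into (train, test)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = dataset.labels
    # largest-remainder allocation so the test set has round(frac * n) subjects
    total = int(round(test_fraction * len(y)))
    quotas = {}
    remainders = []
    for cls in (0, 1):
        exact = test_fraction * np.sum(y == cls)
        quotas[cls] = int(np.floor(exact))
        remainders.append((exact - quotas[cls], cls))
    for _, cls in sorted(remainders, reverse=True):
        if sum(quotas.values()) >= total:
            break
        quotas[cls] += 1
    test_idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        n_test = quotas[cls]
        if n_test == 0 or n_test == len(members):
            raise ValueError(
                f"test fraction {test_fraction} leaves class {cls} empty "
                "on one side of the split"
            )
        test_idx.extend(rng.permutation(members)[:n_test])
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return dataset.subset_subjects(train_idx), dataset.subset_subjects(test_idx)


def rule_model_fitter(embedding, config):
    """Adapter: fit the rule model inside the CV harness.

    The phylogenetic embedding is computed from the distance matrix alone
    (it involves no labels), so it is shared across folds.
    """
    from dataclasses import replace as _replace

    from .inference import fit_map
    from .model import predict_proba

    def fitter(train: MicrobiomeDataset, seed: int):
        cfg = _replace(config, seed=seed)
        fitted = fit_map(train, embedding, cfg)

        def predict(ds: MicrobiomeDataset):
            return predict_proba(fitted.params, fitted.temps, ds, embedding)

        return predict

    return fitter


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def recovery_scores(ruleset, truth) -> tuple:
    """How well the binarised model recovered the simulated perturbation.

    Returns (jaccard, window_overlap): the best Jaccard index between any
    active detector's taxon set and a true clade, and the best fraction of
    a true window's length covered by any active detector's window. The
    two maxima may come from different detectors — they score the model's
    taxon attribution and temporal localisation separately. Returns (0, 0)
    for an empty rule set.
    """
    best_jac = 0.0
    best_overlap = 0.0
    for rule in ruleset.rules:
        for det in rule.detectors:
            det_taxa = set(det.taxa)
            for clade, window in zip(truth.clades, truth.windows):
                best_jac = max(best_jac, _jaccard(det_taxa, set(clade)))
                lo = max(det.window[0], window[0])
                hi = min(det.window[1], window[1])
                overlap = max(0.0, hi - lo) / (window[1] - window[0])
                best_overlap = max(best_overlap, overlap)
    return best_jac, best_overlap
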