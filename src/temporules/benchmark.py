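"""Desk-scale benchmark pipelines over the semi-synthetic generator.

These runners tie the whole method together — simulate a cohort, embed
the tree, fit the rule model, binarise, and score — with one frozen set
of desk-scale conditions (64 subjects, 18 time points, 32 taxa, one
clade perturbed fourfold in the central 30% of the study; 3 rules x 8
detector slots). They back both the acceptance test suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np

from .data import MicrobiomeDataset
from .embedding import build_embedding
from .evaluate import (
    auc_score,
    cross_validate,
    f1_score,
    holdout_split,
    recovery_scores,
    rule_model_fitter,
)
from .inference import FitConfig, fit_map
from .model import predict_proba
from .report import binarize
from .simulate import SimulationConfig, generate_reference_tree, noise_series, simulate_cohort

__all__ = [
    "desk_fit_config",
    "make_separable_cohort",
    "run_separable_benchmark",
    "run_cohort_benchmark",
    "run_null_benchmark",
    "run_noise_benchmark",
]


def desk_fit_config(seed: int, **overrides) -> FitConfig:
    """Model capacity and optimiser settings used for the synthetic benchmarks."""
    kwargs = dict(n_rules=3, n_detectors=8, seed=seed)
    kwargs.update(overrides)
    return FitConfig(**kwargs)


def make_separable_cohort(seed: int, n_subjects: int = 20, n_taxa: int = 8,
                          n_timepoints: int = 10, duration: float = 60.0):
    """A cohort whose label is exactly one taxon's windowed mean vs a threshold.

    Subject labels are *defined* by whether the driving taxon's mean
    relative abundance between days 20 and 40 exceeds the midpoint
    between the two simulated abundance regimes, so a single abundance
    detector separates the classes with a wide margin.

    Returns (dataset, driver_taxon, window_days, threshold).
    """
    rng = np.random.default_rng(seed)
    tree, taxa, D = generate_reference_tree(n_taxa, rng)
    times = np.linspace(0.0, duration, n_timepoints)
    window = (20.0, 40.0)
    in_window = (times >= window[0]) & (times <= window[1])

    low, high = -3.0, -0.5   # driver log-levels for the two regimes
    X = np.empty((n_subjects, n_timepoints, n_taxa))
    for s in range(n_subjects):
        log_ab = rng.normal(0.0, 0.25, size=(1, n_taxa)) \
            + rng.normal(0.0, 0.05, size=(n_timepoints, n_taxa))
        level = high if s % 2 else low
        log_ab[:, 0] = rng.normal(-3.0, 0.05, size=n_timepoints)
        log_ab[in_window, 0] = rng.normal(level, 0.05, size=in_window.sum())
        ab = np.exp(log_ab)
        X[s] = ab / ab.sum(axis=1, keepdims=True)

    feature = X[:, in_window, 0].mean(axis=1)
    # label from the realised feature (geometric midpoint of the two regimes)
    mid = float(np.exp(0.5 * (np.log(feature[::2]).mean()
                              + np.log(feature[1::2]).mean())))
    labels = (feature > mid).astype(int)
    ds = MicrobiomeDataset(
        subjects=[f"P{i:03d}" for i in range(n_subjects)],
        labels=labels, taxa=taxa, times=times, abundances=X,
        mask=np.ones((n_subjects, n_timepoints), dtype=bool), distances=D,
    )
    ds.validate()
    return ds, taxa[0], window, mid


def run_separable_benchmark(seed: int) -> dict:
    """Fit the separable toy; report training F1, driver recovery, agreement."""
    ds, driver, window, thr = make_separable_cohort(seed)
    embedding = build_embedding(ds.distances)
    fitted = fit_map(ds, embedding, desk_fit_config(seed, n_rules=3, n_detectors=3))
    p = predict_proba(fitted.params, fitted.temps, ds, embedding)
    soft_pred = (p > 0.5).astype(int)
    ruleset = binarize(fitted, ds, embedding)
    driver_found = any(driver in det.taxa
                       for rule in ruleset.rules for det in rule.detectors)
    return {
        "train_f1": f1_score(ds.labels, soft_pred),
        "driver_found": bool(driver_found),
        "agreement": float(np.mean(ruleset.predictions == soft_pred)),
    }


def run_cohort_benchmark(seed: int, cv_folds: int = 5) -> dict:
    """Full benchmark on one simulated cohort.

    5-fold cross-validated held-out F1, perturbed-clade recovery (best
    detector Jaccard and window overlap of the full-data fit), and
    hard/soft prediction agreement.
    """
    config = SimulationConfig(seed=seed)
    ds, truth = simulate_cohort(config)
    embedding = build_embedding(ds.distances)

    result = cross_validate(ds, rule_model_fitter(embedding, desk_fit_config(seed)),
                            k=cv_folds, repeats=1, seeds=(seed,))
    fitted = fit_map(ds, embedding, desk_fit_config(seed))
    p = predict_proba(fitted.params, fitted.temps, ds, embedding)
    soft_pred = (p > 0.5).astype(int)
    ruleset = binarize(fitted, ds, embedding)
    jaccard, overlap = recovery_scores(ruleset, truth)
    return {
        "cv_f1": float(result.aggregate["f1"].mean()),
        "cv_auc": float(result.aggregate["auc"].mean()),
        "train_f1": f1_score(ds.labels, soft_pred),
        "jaccard": jaccard,
        "window_overlap": overlap,
        "agreement": float(np.mean(ruleset.predictions == soft_pred)),
        "fitted": fitted,
        "embedding": embedding,
        "config": config,
    }


def run_null_benchmark(seed: int) -> dict:
    """No-effect cohort (fold change 1): held-out AUC should be ~0.5.

    A largish cohort keeps the test split (24 subjects) big enough that
    the AUC estimate is not dominated by split noise.
    """
    config = SimulationConfig(n_subjects=96, n_timepoints=8, n_taxa=20,
                              fold_change=1.0, seed=seed)
    ds, _ = simulate_cohort(config)
    embedding = build_embedding(ds.distances)
    train, test = holdout_split(ds, 0.25, np.random.default_rng(seed))
    fitted = fit_map(train, embedding, desk_fit_config(seed))
    scores = predict_proba(fitted.params, fitted.temps, test, embedding)
    return {"auc": auc_score(test.labels, scores)}


def run_noise_benchmark(seed: int, levels=(1, 10, 100, 1000, 10000)) -> dict:
    """Train once, evaluate on test sets with increasing measurement noise."""
    config = SimulationConfig(seed=seed)
    ds, _ = simulate_cohort(config)
    embedding = build_embedding(ds.distances)
    fitted = fit_map(ds, embedding, desk_fit_config(seed))
    # same latent trajectories and labels; only the measurement noise is redrawn
    test_sets, _ = noise_series(config, levels=levels, seed=seed + 77)
    f1s = {}
    for level, test in zip(levels, test_sets):
        scores = predict_proba(fitted.params, fitted.temps, test, embedding)
        f1s[level] = f1_score(test.labels, (scores > 0.5).astype(int))
    return {"f1_by_level": f1s}
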