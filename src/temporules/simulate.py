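"""Semi-synthetic longitudinal cohorts with known clade perturbations.

The generator emulates the statistical structure of real longitudinal
microbiome studies: each taxon follows a smooth population log-abundance
trajectory (a random low-order spline), subjects deviate from it with a
static offset plus temporally correlated wiggle, and measurements add
signal-proportional Gaussian noise before renormalisation to the simplex.
Case subjects additionally have one or two phylogenetic clades shifted by
a known fold change inside a known time window (with short sigmoid ramps,
so the true window is well defined for recovery scoring).

Measurement noise is controlled by a multiplier from
{1, 10, 100, 1000, 10000} mapped onto a base noise standard deviation of
0.3% of signal, i.e. sd percentages {0.3, 3, 30, 300, 3000}.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import expit

from .data import MicrobiomeDataset, patristic_distances

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_reference_tree",
    "simulate_cohort",
    "noise_series",
    "write_cohort",
]

BASE_NOISE_PERCENT = 0.3
NOISE_MULTIPLIERS = (1, 10, 100, 1000, 10000)
RAMP_WIDTH = 0.02  # perturbation on/off ramp, fraction of duration


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 64
    n_timepoints: int = 18
    n_taxa: int = 32
    n_perturb: int = 1
    fold_change: float = 4.0
    window_fraction: tuple = (0.35, 0.65)
    noise_multiplier: int = 1
    sequencing_depth: int | None = None
    duration_days: float = 100.0
    seed: int = 0
    # texture of the baseline trajectories
    base_sd: float = 1.5         # spread of taxon mean log-abundances
    spline_knots: int = 4
    spline_sd: float = 0.7       # amplitude of population trends
    subject_sd: float = 1.0      # per-subject static offset, log scale
    wiggle_sd: float = 0.15      # temporally correlated subject deviation
    wiggle_lengthscale: float = 0.15  # fraction of duration

    def __post_init__(self):
        if self.n_subjects % 2:
            raise ValueError("n_subjects must be even (balanced classes)")
        if self.n_perturb not in (1, 2):
            raise ValueError("n_perturb must be 1 or 2")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        lo, hi = self.window_fraction
        if not 0 <= lo < hi <= 1:
            raise ValueError("window_fraction must satisfy 0 <= start < end <= 1")
        if self.noise_multiplier not in NOISE_MULTIPLIERS:
            raise ValueError(f"noise_multiplier must be one of {NOISE_MULTIPLIERS}")

    @property
    def noise_percent(self) -> float:
        return BASE_NOISE_PERCENT * self.noise_multiplier


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort."""

    clades: list          # list of taxon-id lists, one per perturbation
    windows: list         # list of (start_day, end_day)
    fold_changes: list
    labels: np.ndarray    # (S,) binary
    newick: str
    families: dict = None # taxon index -> family label (tree-derived)


def generate_reference_tree(n_taxa: int, rng: np.random.Generator):
    """Random coalescent tree over `n_taxa` leaves.

    Returns (tree, taxa, distances): a dendropy tree with exponential
    coalescent branch lengths, leaf labels ``T000``..., and the patristic
    distance matrix in leaf-label order.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    taxa = [f"T{i:03d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0,
        rng=_pyrandom.Random(int(rng.integers(2**31))),
    )
    D = patristic_distances(tree, taxa)
    return tree, taxa, D


def family_assignment_from_tree(tree: dendropy.Tree, taxa: list,
                                max_size: int | None = None) -> dict:
    """Partition leaves into monophyletic 'families' by cutting the tree.

    Starting at the root, subtrees are split until none exceeds
    `max_size` leaves (default: n/6, floored at 3). The result maps taxon
    index (position in `taxa`) to a family label, playing the role a
    taxonomic family table plays for real data when deriving the
    phylogenetic-radius prior.
    """
    n = len(taxa)
    if max_size is None:
        max_size = max(3, n // 6)
    index = {t: i for i, t in enumerate(taxa)}
    families: dict = {}
    stack = [tree.seed_node]
    fam = 0
    while stack:
        node = stack.pop()
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if len(leaves) > max_size and not node.is_leaf():
            stack.extend(node.child_nodes())
            continue
        for label in leaves:
            families[index[label]] = fam
        fam += 1
    return families


def _eligible_clades(tree: dendropy.Tree, n_taxa: int):
    """Internal nodes whose leaf sets are usable perturbation targets."""
    cap = max(2, n_taxa // 4)
    clades = []
    for node in tree.preorder_internal_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if 2 <= len(leaves) <= cap:
            clades.append(sorted(leaves))
    return clades


def _latent_cohort(config: SimulationConfig):
    """Noise-free signal plus ground truth; measurement noise is added later."""
    rng = np.random.default_rng(config.seed)
    tree, taxa, D = generate_reference_tree(config.n_taxa, rng)
    S, T, N = config.n_subjects, config.n_timepoints, config.n_taxa
    t_days = np.linspace(0.0, config.duration_days, T)
    tnorm = t_days / config.duration_days

    # population trajectories: taxon base level + smooth random trend
    base = rng.normal(0.0, config.base_sd, size=N)
    knots = np.linspace(0.0, 1.0, config.spline_knots)
    trend = np.empty((T, N))
    for i in range(N):
        vals = rng.normal(0.0, config.spline_sd, size=config.spline_knots)
        trend[:, i] = CubicSpline(knots, vals)(tnorm)

    # per-subject deviations: static offset + correlated wiggle
    offsets = rng.normal(0.0, config.subject_sd, size=(S, 1, N))
    dt = np.abs(tnorm[:, None] - tnorm[None, :])
    cov = config.wiggle_sd**2 * np.exp(-0.5 * (dt / config.wiggle_lengthscale) ** 2)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(T))
    wiggle = np.einsum("tu,sun->stn", chol, rng.standard_normal((S, T, N)))

    log_abund = base[None, None, :] + trend[None, :, :] + offsets + wiggle

    labels = np.array([0] * (S // 2) + [1] * (S // 2))
    eligible = _eligible_clades(tree, N)
    if not eligible:
        raise ValueError("tree has no internal clade of usable size")
    taxon_index = {t: i for i, t in enumerate(taxa)}
    lo_f, hi_f = config.window_fraction
    ramp = expit((tnorm - lo_f) / RAMP_WIDTH) - expit((tnorm - hi_f) / RAMP_WIDTH)

    # Restrict perturbation targets to clades holding a modest share of
    # total abundance. Perturbing a dominant clade moves every other taxon
    # almost as much through renormalisation, making the true target
    # unidentifiable in compositional data.
    pop = np.exp(base[None, :] + trend).mean(axis=0)       # (N,) mean signal
    share = pop / pop.sum()

    def clade_share(clade):
        return float(share[[taxon_index[t] for t in clade]].sum())

    modest = [c for c in eligible if 0.01 <= clade_share(c) <= 0.08]
    if not modest:
        modest = sorted(eligible, key=lambda c: abs(clade_share(c) - 0.04))[:3]

    clades, windows, folds = [], [], []
    chosen_idx: set = set()
    for _ in range(config.n_perturb):
        pool = [c for c in modest
                if not chosen_idx.intersection(taxon_index[t] for t in c)]
        if not pool:
            logger.info("no disjoint clade available; reusing the full pool")
            pool = modest
        clade = pool[rng.integers(len(pool))]
        idx = [taxon_index[t] for t in clade]
        chosen_idx.update(idx)
        shift = np.log(config.fold_change) * ramp          # (T,)
        for s in np.flatnonzero(labels == 1):
            log_abund[s][:, idx] += shift[:, None]
        clades.append(clade)
        windows.append((lo_f * config.duration_days, hi_f * config.duration_days))
        folds.append(config.fold_change)

    truth = SimulationTruth(
        clades=clades, windows=windows, fold_changes=folds,
        labels=labels, newick=tree.as_string(schema="newick").strip(),
        families=family_assignment_from_tree(tree, taxa),
    )
    signal = np.exp(log_abund)   # unnormalised abundances, (S,T,N)
    return taxa, D, t_days, labels, signal, truth


def _noisy_signal(signal: np.ndarray, percent: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise with sd = percent% of |signal| (pre-normalisation)."""
    sd = percent / 100.0 * np.abs(signal)
    return np.clip(signal + rng.normal(0.0, 1.0, signal.shape) * sd, 1e-12, None)


def _measure(signal: np.ndarray, percent: float, rng: np.random.Generator,
             sequencing_depth: int | None = None) -> np.ndarray:
    """Signal-proportional Gaussian noise, then renormalise to the simplex."""
    noisy = _noisy_signal(signal, percent, rng)
    rel = noisy / noisy.sum(axis=2, keepdims=True)
    if sequencing_depth is not None:
        S, T, N = rel.shape
        counts = np.empty_like(rel)
        for s in range(S):
            for t in range(T):
                counts[s, t] = rng.multinomial(sequencing_depth, rel[s, t])
        counts = np.clip(counts, 1e-12, None)
        rel = counts / counts.sum(axis=2, keepdims=True)
    return rel


def _to_dataset(taxa, D, t_days, labels, rel) -> MicrobiomeDataset:
    S, T, _ = rel.shape
    ds = MicrobiomeDataset(
        subjects=[f"S{i:04d}" for i in range(S)],
        labels=labels.copy(),
        taxa=list(taxa),
        times=t_days.copy(),
        abundances=rel,
        mask=np.ones((S, T), dtype=bool),
        distances=D.copy(),
    )
    ds.validate()
    return ds


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort. Returns (MicrobiomeDataset, SimulationTruth)."""
    taxa, D, t_days, labels, signal, truth = _latent_cohort(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    rel = _measure(signal, config.noise_percent, rng, config.sequencing_depth)
    return _to_dataset(taxa, D, t_days, labels, rel), truth


def noise_series(config: SimulationConfig, levels=NOISE_MULTIPLIERS,
                 seed: int | None = None):
    """Test sets sharing the base cohort's signal, at increasing noise levels.

    Only the measurement noise is redrawn; trajectories, perturbations and
    labels are identical across levels. Returns (datasets, truth) with one
    dataset per multiplier in `levels`.
    """
    for level in levels:
        if level not in NOISE_MULTIPLIERS:
            raise ValueError(f"unknown noise multiplier {level}")
    taxa, D, t_days, labels, signal, truth = _latent_cohort(config)
    rng = np.random.default_rng(config.seed + 2_000_003 if seed is None else seed)
    datasets = []
    for level in levels:
        rel = _measure(signal, BASE_NOISE_PERCENT * level, rng,
                       config.sequencing_depth)
        datasets.append(_to_dataset(taxa, D, t_days, labels, rel))
    return datasets, truth


def write_cohort(dataset: MicrobiomeDataset, truth: SimulationTruth, outdir):
    """Write the cohort in the standard input formats plus a truth file."""
    import json
    from pathlib import Path

    from .data import write_abundance_table, write_labels_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(dataset, outdir / "abundances.csv")
    write_labels_table(dataset, outdir / "labels.csv")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(truth.newick + "\n")
    if truth.families is not None:
        import pandas as pd
        pd.DataFrame({
            "taxon": dataset.taxa,
            "family": [truth.families[i] for i in range(len(dataset.taxa))],
        }).to_csv(outdir / "taxonomy.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "clades": truth.clades,
                "windows": [list(w) for w in truth.windows],
                "fold_changes": truth.fold_changes,
                "labels": truth.labels.tolist(),
            },
            fh, indent=1,
        )
    return [outdir / n for n in
            ("abundances.csv", "labels.csv", "tree.nwk", "truth.json")]
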