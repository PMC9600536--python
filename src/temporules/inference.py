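"""Initialisation and annealed MAP optimisation of the rule model.

Fitting is gradient ascent on the log-posterior with an RMSProp-style
adaptive step, run for a fixed number of iterations while every
relaxation temperature is linearly annealed toward sharpness. Training
halts early once the loss (negative log-posterior) has not improved by at
least one unit within a trailing window of iterations.

Initialisation follows a data-driven recipe: phylogenetic centers and
radii from K-means clustering of the embedded taxa, time windows drawn
uniformly from a partition of the study into equal intervals that each
hold at least two samples per subject, thresholds at the subject-mean of
the corresponding initial feature, and all selectors at probability 0.5.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .data import MicrobiomeDataset
from .embedding import PhyloEmbedding
from .model import (
    PARAM_FIELDS,
    ModelParams,
    PriorConfig,
    TemperatureState,
    forward,
    log_posterior_with_grad,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FittedModel",
    "compute_num_windows",
    "init_time_windows",
    "init_phylo",
    "init_thresholds",
    "initialize",
    "anneal",
    "fit_map",
]

# (start, end) of each linear temperature schedule
DEFAULT_SCHEDULES = {
    "tau_u": (1.0, 0.1),
    "tau_v": (1.0, 0.1),
    "tau_z": (1.0, 0.1),
    "tau_q": (1.0, 0.1),
    "tau_g_abund": (1e-2, 1e-3),
    "tau_g_slope": (1e-3, 1e-4),
}

TEMPORAL_PARAMS = ("mu", "sigma_raw")
SELECTOR_PARAMS = ("zeta_z_abund", "zeta_z_slope", "zeta_q")


@dataclass
class FitConfig:
    """Optimiser and model-capacity settings for one MAP fit."""

    n_rules: int = 10
    n_detectors: int = 10
    max_iters: int = 2000
    anneal_iters: int = 1200    # schedules reach their end values here;
                                # training then consolidates at final temps
    lr_temporal: float = 0.01   # step size for window centers/lengths
    lr_selector: float = 0.005  # selector logits
    lr_other: float = 0.001     # everything else
    rms_decay: float = 0.99
    rms_eps: float = 1e-8
    stop_window: int = 100
    stop_delta: float = 1.0
    stop_arm_after: int | None = None   # earliest iteration at which the
                                # plateau criterion may fire; None means the
                                # anneal horizon (mid-anneal plateaus are
                                # transient), 0 arms it from the start
    seed: int = 0
    schedules: dict = field(default_factory=lambda: dict(DEFAULT_SCHEDULES))

    def __post_init__(self):
        if self.lr_temporal <= 0 or self.lr_other <= 0:
            raise ValueError("learning rates must be positive")
        for name, (start, end) in self.schedules.items():
            if not start >= end > 0:
                raise ValueError(f"schedule {name}: need start >= end > 0")

    def save(self, path) -> None:
        """Write the configuration as a plain-text (JSON) file."""
        import json
        from dataclasses import asdict
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FitConfig":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        payload["schedules"] = {k: tuple(v)
                                for k, v in payload["schedules"].items()}
        return cls(**payload)


@dataclass
class FittedModel:
    """Result of a MAP fit."""

    params: ModelParams
    temps: TemperatureState          # temperatures reached when training halted
    temps_schedule_end: TemperatureState  # end of the full anneal schedule
    loss_trace: np.ndarray
    config: FitConfig
    priors: PriorConfig
    dataset_fingerprint: str
    stopped_at: int


def dataset_fingerprint(dataset: MicrobiomeDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.abundances).tobytes())
    h.update(np.ascontiguousarray(dataset.labels).tobytes())
    h.update(np.ascontiguousarray(dataset.times).tobytes())
    return h.hexdigest()[:16]


def compute_num_windows(dataset: MicrobiomeDataset) -> int:
    """Largest N_w such that N_w equal intervals each hold >= 2 samples per subject."""
    per_subject = dataset.mask.sum(axis=1)
    if per_subject.min() < 2:
        raise ValueError("every subject needs at least 2 samples")
    tmin, tmax = dataset.times[0], dataset.times[-1]
    upper = int(per_subject.min()) // 2
    for n_w in range(max(upper, 1), 0, -1):
        edges = np.linspace(tmin, tmax, n_w + 1)
        ok = True
        for s in range(dataset.n_subjects):
            counts, _ = np.histogram(dataset.subject_times(s), bins=edges)
            if counts.min() < 2:
                ok = False
                break
        if ok:
            return n_w
    raise ValueError("no interval count >= 1 leaves 2 samples per subject")


def init_time_windows(duration: float, n_windows: int, n_rules: int,
                      n_detectors: int, rng: np.random.Generator):
    """Draw each detector's initial window from equal segments of the study.

    Returns (mu, sigma) in days: window midpoints and lengths, shape (K, J).
    """
    if n_windows < 1:
        raise ValueError("need at least one interval")
    length = duration / n_windows
    idx = rng.integers(0, n_windows, size=(n_rules, n_detectors))
    mu = (idx + 0.5) * length
    sigma = np.full((n_rules, n_detectors), length)
    return mu, sigma


def init_phylo(E: np.ndarray, n_detectors: int, seed: int,
               radius_floor: float = 1e-4):
    """K-means on the embedded taxa: centroids as centers, cluster spans as radii.

    Returns (centers (J, D), radii (J,)); the same layout is replicated
    across rules by the caller.
    """
    N = E.shape[0]
    if N < n_detectors:
        raise ValueError(
            f"{N} taxa cannot seed {n_detectors} detectors; lower n_detectors"
        )
    km = KMeans(n_clusters=n_detectors, n_init=10, random_state=seed).fit(E)
    centers = km.cluster_centers_
    radii = np.full(n_detectors, radius_floor)
    for j in range(n_detectors):
        members = E[km.labels_ == j]
        if len(members):
            span = np.linalg.norm(members - centers[j], axis=1).max()
            radii[j] = max(span, radius_floor)
    return centers, radii


def init_thresholds(dataset: MicrobiomeDataset, embedding: PhyloEmbedding,
                    params: ModelParams, temps: TemperatureState):
    """Thresholds at the subject-mean of each detector's initial feature.

    Returns (eta_abund, eta_slope, ranges) where ranges holds the (low,
    high) subject-feature envelopes used for the uniform threshold priors.
    """
    nodes = forward(params, temps, dataset, embedding, requires_grad=False)
    b_avg = nodes["b_avg"].value          # (S,K,J)
    b_slope = nodes["b_slope"].value
    eta_a = b_avg.mean(axis=0)
    eta_s = b_slope.mean(axis=0)

    def envelope(b):
        low, high = b.min(axis=0), b.max(axis=0)
        flat = high - low < 1e-8
        pad = np.where(flat, np.maximum(np.abs(high), 1.0) * 1e-3, 0.0)
        return low - pad, high + pad

    return eta_a, eta_s, (envelope(b_avg), envelope(b_slope))


def initialize(dataset: MicrobiomeDataset, embedding: PhyloEmbedding,
               config: FitConfig):
    """Build initial parameters and the matching prior configuration."""
    rng = np.random.default_rng(config.seed)
    K, J, D = config.n_rules, config.n_detectors, embedding.dim

    n_w = compute_num_windows(dataset)
    mu_days, sigma_days = init_time_windows(dataset.duration, n_w, K, J, rng)
    duration = dataset.duration
    # floor initial radii at the family-scale prior location so that every
    # detector's ball actually contains its cluster members at the start
    floor = max(embedding.radius_prior_loc or 0.0, 1e-2)
    centers, radii = init_phylo(embedding.E, J, seed=int(rng.integers(2**31)),
                                radius_floor=floor)

    params = ModelParams(
        gamma=np.broadcast_to(centers, (K, J, D)).copy(),
        kappa_raw=np.log(np.broadcast_to(radii, (K, J))).copy(),
        mu=mu_days / duration,
        sigma_raw=np.log(sigma_days / duration),
        eta_abund=np.zeros((K, J)),
        eta_slope=np.zeros((K, J)),
        zeta_z_abund=np.zeros((K, J)),   # selector probability 0.5
        zeta_z_slope=np.zeros((K, J)),
        zeta_q=np.zeros(K),
        w=rng.standard_normal(K),
        w0=np.zeros(()),
    )
    start_temps = TemperatureState(
        **{k: v[0] for k, v in config.schedules.items()}
    )
    eta_a, eta_s, ((lo_a, hi_a), (lo_s, hi_s)) = init_thresholds(
        dataset, embedding, params, start_temps
    )
    params.eta_abund = eta_a
    params.eta_slope = eta_s

    loc = embedding.radius_prior_loc or 1.0
    scale_var = embedding.radius_prior_scale or 1.0
    # floor the per-axis center-prior scale at the overall rms spread:
    # low-variance embedding axes must not pin the centers in place
    spread = embedding.E.std(axis=0)
    rms = float(np.sqrt(np.mean(spread**2)))
    priors = PriorConfig(
        gamma_mean=embedding.E.mean(axis=0),
        gamma_scale=np.maximum(spread, max(rms, 1e-3)),
        kappa_loc=loc,
        # weakly informative: coefficient of variation >= 1 so radii a few
        # times the family scale stay plausible while tree-spanning balls
        # are discouraged
        kappa_scale=max(np.sqrt(scale_var), loc, 1e-2),
        eta_abund_low=lo_a, eta_abund_high=hi_a,
        eta_slope_low=lo_s, eta_slope_high=hi_s,
    )
    return params, priors


def anneal(start: float, end: float, iteration: int, total_iters: int) -> float:
    """Linear interpolation of a temperature schedule."""
    if not 0 <= iteration <= total_iters:
        raise ValueError("iteration outside [0, total_iters]")
    frac = iteration / total_iters
    return (1.0 - frac) * start + frac * end


def _temps_at(config: FitConfig, iteration: int) -> TemperatureState:
    horizon = min(config.anneal_iters, config.max_iters)
    return TemperatureState(**{
        name: anneal(start, end, min(iteration, horizon), horizon)
        for name, (start, end) in config.schedules.items()
    })


def fit_map(dataset: MicrobiomeDataset, embedding: PhyloEmbedding,
            config: FitConfig | None = None,
            priors: PriorConfig | None = None) -> FittedModel:
    """Annealed RMSProp ascent on the log-posterior.

    Temporal-focus parameters (window centers and lengths) use their own,
    larger step size. The annealing schedules are indexed by `max_iters`
    regardless of early stopping, so the temperature at halt is whatever
    the schedule had reached by then.
    """
    config = config or FitConfig()
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class to fit")
    params, auto_priors = initialize(dataset, embedding, config)
    if priors is None:
        priors = auto_priors

    sq_avg = {f: np.zeros_like(getattr(params, f)) for f in PARAM_FIELDS}
    trace = []
    prefix_min = []  # prefix_min[i] = min(trace[:i+1])
    stopped_at = config.max_iters
    for it in range(config.max_iters):
        temps = _temps_at(config, it)
        try:
            value, grads = log_posterior_with_grad(
                params, temps, priors, dataset, embedding)
        except FloatingPointError as exc:
            raise FloatingPointError(f"iteration {it}: {exc}") from exc
        loss = -value
        trace.append(loss)
        prefix_min.append(min(loss, prefix_min[-1]) if prefix_min else loss)
        # halt once the best loss seen in the trailing window no longer
        # improves on the best loss seen before it by at least stop_delta
        w = config.stop_window
        arm = config.anneal_iters if config.stop_arm_after is None \
            else config.stop_arm_after
        if (it >= max(w, arm)
                and prefix_min[-1] > prefix_min[it - w] - config.stop_delta):
            stopped_at = it
            logger.info("stopping at iteration %d (no %.3g-unit improvement in %d)",
                        it, config.stop_delta, config.stop_window)
            break
        for name in PARAM_FIELDS:
            g = grads[name]
            if name in TEMPORAL_PARAMS:
                lr = config.lr_temporal
            elif name in SELECTOR_PARAMS:
                lr = config.lr_selector
            else:
                lr = config.lr_other
            sq = sq_avg[name]
            sq *= config.rms_decay
            sq += (1.0 - config.rms_decay) * g * g
            update = lr * g / (np.sqrt(sq) + config.rms_eps)
            setattr(params, name, getattr(params, name) + update)

    end_temps = TemperatureState(**{k: v[1] for k, v in config.schedules.items()})
    return FittedModel(
        params=params,
        temps=_temps_at(config, min(stopped_at, config.max_iters)),
        temps_schedule_end=end_temps,
        loss_trace=np.asarray(trace),
        config=config,
        priors=priors,
        dataset_fingerprint=dataset_fingerprint(dataset),
        stopped_at=stopped_at,
    )
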