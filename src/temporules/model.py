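"""Differentiable five-layer temporal-rule model.

The classifier is a stack of continuously relaxed logic operations:

1. *Phylogenetic focus* — each detector owns a center and radius in the
   embedded phylogenetic space; taxa within the ball are softly selected
   and their relative abundances aggregated.
2. *Temporal focus* — a relaxed boxcar over the study window softly
   selects time points; the aggregated abundance is averaged (or its
   slope estimated by weighted least squares) over the window.
3. *Detectors* — sigmoid comparison of the windowed feature against a
   learned threshold.
4. *Rules* — a soft AND over the detectors selected for the rule.
5. *Classification* — logistic regression on the selected rule
   activations.

Every relaxation carries a temperature; as temperatures anneal toward
zero the model converges to discrete rule logic. Priors on all parameters
make the training objective a log-posterior, maximised by gradient
ascent (see :mod:`temporules.inference`).

The public layer functions in this module are plain-numpy, one detector
at a time — the readable reference semantics. The full-tensor autodiff
graph used for fitting lives in :func:`forward`, and the two are held
together by the test suite's cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln

from . import autodiff as ad
from .autodiff import Tensor
from .data import MicrobiomeDataset
from .embedding import PhyloEmbedding

__all__ = [
    "ModelParams",
    "TemperatureState",
    "PriorConfig",
    "phylo_focus",
    "aggregate_abundance",
    "time_window_weights",
    "window_average",
    "window_slope",
    "detector_response",
    "soft_and",
    "selector_value",
    "classify",
    "negbin_logpmf",
    "log_posterior",
    "log_posterior_with_grad",
    "forward",
    "predict_proba",
]

EPS = 1e-10        # weight-normalisation guard
SLOPE_EPS = 1e-12  # slope-denominator guard; small enough that exact
                   # linear data is recovered to ~1e-11
MAX_RULES = 10
MAX_DETECTORS = 10

PARAM_FIELDS = (
    "gamma", "kappa_raw", "mu", "sigma_raw", "eta_abund", "eta_slope",
    "zeta_z_abund", "zeta_z_slope", "zeta_q", "w", "w0",
)


@dataclass
class ModelParams:
    """All trainable parameters.

    Shapes: K rules, J detectors per rule (each detector slot carries both
    an abundance and a slope variant, with independent selectors), D
    embedding dimensions. Radii and window lengths are stored as
    unconstrained logs and exponentiated, keeping them positive.
    """

    gamma: np.ndarray         # (K, J, D) phylogenetic centers
    kappa_raw: np.ndarray     # (K, J) log radii
    mu: np.ndarray            # (K, J) window centers, fraction of duration
    sigma_raw: np.ndarray     # (K, J) log window lengths (fractions)
    eta_abund: np.ndarray     # (K, J) abundance thresholds
    eta_slope: np.ndarray     # (K, J) slope thresholds
    zeta_z_abund: np.ndarray  # (K, J) abundance-detector selector logits
    zeta_z_slope: np.ndarray  # (K, J) slope-detector selector logits
    zeta_q: np.ndarray        # (K,) rule selector logits
    w: np.ndarray             # (K,) rule weights (log-odds)
    w0: np.ndarray            # () bias

    def __post_init__(self):
        for name in PARAM_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.n_rules > MAX_RULES or self.n_detectors > MAX_DETECTORS:
            raise ValueError(
                f"model capacity capped at {MAX_RULES} rules x {MAX_DETECTORS} detectors"
            )

    @property
    def n_rules(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_dims(self) -> int:
        return self.gamma.shape[2]

    @property
    def kappa(self) -> np.ndarray:
        return np.exp(self.kappa_raw)

    @property
    def sigma_win(self) -> np.ndarray:
        return np.exp(self.sigma_raw)

    def copy(self) -> "ModelParams":
        return ModelParams(**{f: getattr(self, f).copy() for f in PARAM_FIELDS})

    def save(self, path) -> None:
        """Serialise to a JSON key-value snapshot."""
        with open(path, "w") as fh:
            json.dump({f: getattr(self, f).tolist() for f in PARAM_FIELDS}, fh)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{f: np.asarray(payload[f]) for f in PARAM_FIELDS})


@dataclass
class TemperatureState:
    """Sharpness of every relaxation; annealed during training.

    Layer temperatures start at 1 and end at 0.1. Detector-threshold
    temperatures match the scales of the compared features: relative
    abundances (~1e-2) and their slopes (~1e-3).
    """

    tau_u: float = 1.0        # phylogenetic focus
    tau_v: float = 1.0        # temporal focus
    tau_z: float = 1.0        # detector selectors
    tau_q: float = 1.0        # rule selectors
    tau_g_abund: float = 1e-2 # abundance-detector threshold
    tau_g_slope: float = 1e-3 # slope-detector threshold

    def __post_init__(self):
        for name in ("tau_u", "tau_v", "tau_z", "tau_q", "tau_g_abund", "tau_g_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class PriorConfig:
    """Hyperparameters of the prior.

    Thresholds get uniform priors over the feature range seen at
    initialisation, enforced with a smooth quadratic barrier. Detector and
    rule soft counts get a continuously extended Negative Binomial with
    mean 1 and variance 5, which concentrates mass on sparse models.
    Window priors are diffuse around a window centered mid-study covering
    30% of the duration.
    """

    gamma_mean: np.ndarray = None      # (D,)
    gamma_scale: np.ndarray = None     # (D,)
    kappa_loc: float = 1.0
    kappa_scale: float = 1.0
    kappa_prior_kind: str = "normal"   # "normal" on kappa, or "lognormal"
    mu_mean: float = 0.5
    mu_scale: float = 1.0
    sigma_mean: float = 0.3
    sigma_scale: float = 1.0
    eta_abund_low: np.ndarray = None   # (K, J)
    eta_abund_high: np.ndarray = None
    eta_slope_low: np.ndarray = None
    eta_slope_high: np.ndarray = None
    barrier_frac: float = 0.01         # barrier scale as fraction of range
    w_scale: float = 10.0
    selector_scale: float = 1.0
    count_mean: float = 1.0            # theta_z
    count_var: float = 5.0             # theta_z'

    def __post_init__(self):
        if self.count_mean <= 0 or self.count_var <= self.count_mean:
            raise ValueError("count prior needs variance > mean > 0")


# ---------------------------------------------------------------------------
# Reference layer semantics (plain numpy, one detector at a time)
# ---------------------------------------------------------------------------

def phylo_focus(E: np.ndarray, gamma: np.ndarray, kappa: float,
                tau_u: float) -> np.ndarray:
    """Soft membership of each taxon in the ball of radius kappa at gamma."""
    if tau_u <= 0 or kappa <= 0:
        raise ValueError("tau_u and kappa must be positive")
    E = np.atleast_2d(E)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (E.shape[1],):
        raise ValueError(f"center has dim {gamma.shape}, embedding dim {E.shape[1]}")
    xi = np.linalg.norm(gamma[None, :] - E, axis=1)
    return expit((kappa - xi) / tau_u)


def aggregate_abundance(X: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Per-sample abundance aggregated over the soft taxon selection."""
    X = np.atleast_2d(X)
    if X.shape[1] != len(u):
        raise ValueError("membership length does not match taxon count")
    return X @ np.asarray(u, dtype=float)


def time_window_weights(times: np.ndarray, mu: float, sigma_win: float,
                        tau_v: float):
    """Relaxed boxcar over [mu - sigma/2, mu + sigma/2] and its normalisation.

    Returns (h, v): soft in-window indicators and weights summing to 1 over
    the subject's observed samples.
    """
    if tau_v <= 0 or sigma_win <= 0:
        raise ValueError("tau_v and sigma_win must be positive")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("subject has no observed samples")
    h = expit((times - mu + sigma_win / 2) / tau_v) \
        - expit((times - mu - sigma_win / 2) / tau_v)
    v = h / (h.sum() + EPS)
    return h, v


def window_average(a: np.ndarray, v: np.ndarray) -> float:
    """Weighted mean of the aggregated abundance over the window."""
    return float(np.dot(a, v))


def window_slope(a: np.ndarray, v: np.ndarray, times: np.ndarray) -> float:
    """Weighted-OLS slope of the aggregated abundance within the window."""
    times = np.asarray(times, dtype=float)
    tbar = np.dot(v, times)
    abar = np.dot(v, a)
    dt = times - tbar
    return float(np.dot(v * dt, a - abar) / (np.dot(v * dt, dt) + SLOPE_EPS))


def detector_response(b, eta, tau_g: float):
    """Soft truth value of 'feature b exceeds threshold eta'."""
    if tau_g <= 0:
        raise ValueError("tau_g must be positive")
    return expit((np.asarray(b, dtype=float) - eta) / tau_g)


def soft_and(g: np.ndarray, z: np.ndarray):
    """Relaxed conjunction of the detectors selected by z."""
    g = np.asarray(g, dtype=float)
    z = np.asarray(z, dtype=float)
    if g.shape != z.shape:
        raise ValueError("g and z must have the same shape")
    return np.prod(1.0 - z * (1.0 - g), axis=-1)


def selector_value(zeta, tau: float):
    """Relaxed Bernoulli gate: sigmoid(zeta / tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return expit(np.asarray(zeta, dtype=float) / tau)


def classify(r: np.ndarray, q: np.ndarray, w: np.ndarray, w0: float):
    """Logistic combination of selected rule activations.

    Returns (p, contributions): the probability of label 1 and each rule's
    log-odds contribution q_k * w_k * r_k.
    """
    r = np.atleast_2d(r)
    contrib = r * (np.asarray(q) * np.asarray(w))[None, :]
    logits = w0 + contrib.sum(axis=1)
    return expit(logits), contrib


def negbin_logpmf(k, theta: float, theta_prime: float):
    """Negative Binomial log-pmf in mean/variance form, extended to real k.

    The (mean, variance) pair maps to the standard (r, p) parameterisation
    via r = theta^2 / (theta' - theta) and p = theta / theta'; the binomial
    coefficient is continued through the gamma function so that soft
    (non-integer) selector counts can be scored.
    """
    if theta <= 0 or theta_prime <= theta:
        raise ValueError("need variance theta' > mean theta > 0")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("count must be nonnegative")
    r = theta**2 / (theta_prime - theta)
    p = theta / theta_prime
    return (gammaln(k + r) - gammaln(r) - gammaln(k + 1.0)
            + r * np.log(p) + k * np.log1p(-p))


# ---------------------------------------------------------------------------
# Full-tensor autodiff forward pass and log-posterior
# ---------------------------------------------------------------------------

def _param_tensors(params: ModelParams, requires_grad: bool) -> dict:
    return {f: Tensor(getattr(params, f), requires_grad=requires_grad)
            for f in PARAM_FIELDS}


# -- fused graph nodes with hand-written gradients (kept hot-path cheap) ---

def _soft_ball(gamma: Tensor, kappa_raw: Tensor, E: np.ndarray,
               tau_u: float) -> Tensor:
    """u_kji = sigmoid((kappa_kj - ||gamma_kj - E_i||) / tau_u)."""
    K, J, D = gamma.shape
    diff = gamma.value[:, :, None, :] - E[None, None, :, :]     # (K,J,N,D)
    xi = np.sqrt((diff**2).sum(axis=3) + 1e-12)                 # (K,J,N)
    kappa = np.exp(kappa_raw.value)
    u = expit((kappa[:, :, None] - xi) / tau_u)
    out = Tensor(u, parents=(gamma, kappa_raw))

    def vjp(g):
        s = g * u * (1.0 - u) / tau_u                           # (K,J,N)
        if kappa_raw.requires_grad:
            kappa_raw.accum(s.sum(axis=2) * kappa)
        if gamma.requires_grad:
            gamma.accum(-np.einsum("kjn,kjnd->kjd", s / xi, diff))

    out._vjp = vjp
    return out


def _boxcar(times: np.ndarray, mu: Tensor, sigma_raw: Tensor,
            tau_v: float, scale: float = 1.0) -> Tensor:
    """Relaxed boxcar h_tkj over windows [mu - sigma/2, mu + sigma/2].

    `times`, `mu` and exp(`sigma_raw`) share one time unit up to `scale`,
    which maps the window parameters onto the axis of `times`.
    """
    sigma = np.exp(sigma_raw.value)                             # (K,J)
    mu_d = mu.value * scale
    sig_d = sigma * scale
    t = times[:, None, None]
    s1 = expit((t - mu_d + sig_d / 2.0) / tau_v)
    s2 = expit((t - mu_d - sig_d / 2.0) / tau_v)
    out = Tensor(s1 - s2, parents=(mu, sigma_raw))

    def vjp(g):
        d1 = s1 * (1.0 - s1)
        d2 = s2 * (1.0 - s2)
        if mu.requires_grad:
            mu.accum((g * (d2 - d1)).sum(axis=0) * (scale / tau_v))
        if sigma_raw.requires_grad:
            sigma_raw.accum((g * (d1 + d2)).sum(axis=0)
                            * (scale / (2.0 * tau_v)) * sigma)

    out._vjp = vjp
    return out


def _windowed_stats(agg: Tensor, h: Tensor, maskf: np.ndarray,
                    tg: np.ndarray):
    """Window-weighted mean and weighted-OLS slope of the aggregated signal.

    Weights v are the masked boxcar normalised per subject. Returns
    (b_avg, b_slope), both (S, K, J), as two graph nodes whose
    vector-Jacobian products are derived analytically with respect to the
    aggregated abundances and the boxcar indicators.
    """
    a = agg.value                                   # (S,T,K,J)
    S, T, K, J = a.shape
    hm = h.value[None, :, :, :] * maskf[:, :, None, None]
    Z = hm.sum(axis=1) + EPS                        # (S,K,J)
    v = hm / Z[:, None]
    t = tg[None, :, None, None]
    b = (v * a).sum(axis=1)                         # window average
    Tm = (v * t).sum(axis=1)
    dtc = t - Tm[:, None]
    am = a - b[:, None]
    den = (v * dtc * dtc).sum(axis=1) + SLOPE_EPS
    c = (v * dtc * am).sum(axis=1) / den            # weighted-OLS slope
    S_t = (v * dtc).sum(axis=1)
    S_a = (v * am).sum(axis=1)

    def _back_through_v(gv, node_grad_a=None):
        """Gradient wrt h from a gradient wrt v (and pass grad_a through)."""
        ghm = (gv - (gv * v).sum(axis=1, keepdims=True)) / Z[:, None]
        gh = (ghm * maskf[:, :, None, None]).sum(axis=0)
        h.accum(gh)

    out_b = Tensor(b, parents=(agg, h))

    def vjp_b(g):
        ge = g[:, None]                             # (S,1,K,J)
        if agg.requires_grad:
            agg.accum(ge * v)
        if h.requires_grad:
            _back_through_v(ge * a)

    out_b._vjp = vjp_b

    out_c = Tensor(c, parents=(agg, h))

    def vjp_c(g):
        ge = (g / den)[:, None]                     # (S,1,K,J)
        if agg.requires_grad:
            agg.accum(ge * v * (dtc - S_t[:, None]))
        if h.requires_grad:
            dnum = dtc * am - t * S_a[:, None] - a * S_t[:, None]
            dden = dtc * dtc - 2.0 * t * S_t[:, None]
            _back_through_v(ge * (dnum - c[:, None] * dden))

    out_c._vjp = vjp_c
    return out_b, out_c


def _bernoulli_ll(logits: Tensor, y: np.ndarray) -> Tensor:
    """Sum over subjects of y log p + (1 - y) log(1 - p)."""
    val = -(np.logaddexp(0.0, -logits.value) + (1.0 - y) * logits.value).sum()
    out = Tensor(val, parents=(logits,))
    out._vjp = lambda g: logits.accum(g * (y - expit(logits.value)))
    return out


def _normal_logpdf_sum(x: Tensor, mean, scale) -> Tensor:
    """Sum of independent Normal log-densities with constant mean/scale."""
    mean = np.asarray(mean, dtype=float)
    scale = np.asarray(scale, dtype=float)
    z = (x.value - mean) / scale
    const = -np.sum(np.broadcast_to(
        np.log(scale) + 0.5 * np.log(2.0 * np.pi), x.shape))
    out = Tensor(-0.5 * np.sum(z**2) + const, parents=(x,))
    out._vjp = lambda g: x.accum(-g * (x.value - mean) / scale**2)
    return out


def _negbin_logpmf_sum(k: Tensor, theta: float, theta_prime: float) -> Tensor:
    """Continuously extended Negative Binomial log-pmf, summed over k."""
    r = theta**2 / (theta_prime - theta)
    p = theta / theta_prime
    kv = k.value
    val = np.sum(gammaln(kv + r) - gammaln(r) - gammaln(kv + 1.0)
                 + r * np.log(p) + kv * np.log1p(-p))
    out = Tensor(val, parents=(k,))
    out._vjp = lambda g: k.accum(
        g * (digamma(kv + r) - digamma(kv + 1.0) + np.log1p(-p)))
    return out


def _uniform_barrier(eta: Tensor, low, high, barrier_frac: float) -> Tensor:
    """Log-density of a uniform prior with a smooth quadratic out-of-range barrier."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    span = high - low + EPS
    scale = barrier_frac * span
    over = np.maximum(eta.value - high, 0.0)
    under = np.maximum(low - eta.value, 0.0)
    excess = over + under
    val = -0.5 * np.sum((excess / scale) ** 2) - np.sum(np.log(span))
    out = Tensor(val, parents=(eta,))

    def vjp(g):
        sign = (eta.value > high).astype(float) - (eta.value < low)
        eta.accum(-g * excess / scale**2 * sign)

    out._vjp = vjp
    return out


def forward(params: ModelParams, temps: TemperatureState,
            dataset: MicrobiomeDataset, embedding: PhyloEmbedding,
            requires_grad: bool = False) -> dict:
    """Evaluate the five layers for every subject, rule, and detector.

    Returns a dict of graph nodes keyed by quantity. Axis order for
    per-sample quantities is (subject, time, rule, detector).
    """
    pt = _param_tensors(params, requires_grad)
    K, J, D = params.n_rules, params.n_detectors, params.n_dims
    E = embedding.E
    if E.shape[1] != D:
        raise ValueError(f"embedding dim {E.shape[1]} != parameter dim {D}")
    X = dataset.abundances
    S, T, N = X.shape
    tg = dataset.times - dataset.times[0]      # days since first observation
    duration = dataset.duration or 1.0
    maskf = dataset.mask.astype(float)

    # layer 1: phylogenetic focus
    u = _soft_ball(pt["gamma"], pt["kappa_raw"], E, temps.tau_u)  # (K,J,N)
    agg = ad.matmul(Tensor(X.reshape(S * T, N)),
                    u.reshape(K * J, N).transpose()).reshape(S, T, K, J)

    # layer 2: temporal focus. The boxcar's time axis is measured in units
    # of the mean sampling interval, so the annealed temperature (1 -> 0.1)
    # starts soft across roughly one interval and ends sharp well below
    # it. The slope regression runs on day-scale times so slope features
    # and thresholds are per day.
    unit = duration / max(T - 1, 1)
    h = _boxcar(tg / unit, pt["mu"], pt["sigma_raw"], temps.tau_v,
                scale=duration / unit)                            # (T,K,J)
    b_avg, b_slope = _windowed_stats(agg, h, maskf, tg)           # (S,K,J)

    # layer 3: detectors
    g_abund = ad.sigmoid((b_avg - pt["eta_abund"]) * (1.0 / temps.tau_g_abund))
    g_slope = ad.sigmoid((b_slope - pt["eta_slope"]) * (1.0 / temps.tau_g_slope))

    # layer 4: soft AND over selected detectors
    z_abund = ad.sigmoid(pt["zeta_z_abund"] * (1.0 / temps.tau_z))
    z_slope = ad.sigmoid(pt["zeta_z_slope"] * (1.0 / temps.tau_z))
    log_terms = (1.0 - z_abund * (1.0 - g_abund) + 1e-30).log() \
        + (1.0 - z_slope * (1.0 - g_slope) + 1e-30).log()
    r = log_terms.sum(axis=2).exp()                               # (S,K)

    # layer 5: classification
    q = ad.sigmoid(pt["zeta_q"] * (1.0 / temps.tau_q))
    logits = pt["w0"] + (r * (q * pt["w"]).reshape(1, K)).sum(axis=1)

    kappa = pt["kappa_raw"].exp()   # constrained values, used by the priors
    sigma = pt["sigma_raw"].exp()
    return {
        "tensors": pt, "u": u, "agg": agg, "h": h,
        "b_avg": b_avg, "b_slope": b_slope,
        "g_abund": g_abund, "g_slope": g_slope,
        "z_abund": z_abund, "z_slope": z_slope,
        "q": q, "r": r, "logits": logits,
        "kappa": kappa, "sigma": sigma,
    }


def _objective(params: ModelParams, temps: TemperatureState,
               priors: PriorConfig, dataset: MicrobiomeDataset,
               embedding: PhyloEmbedding, requires_grad: bool):
    """Log-posterior graph and its additive parts."""
    nodes = forward(params, temps, dataset, embedding, requires_grad)
    pt = nodes["tensors"]
    y = dataset.labels.astype(float)

    parts = {"likelihood": _bernoulli_ll(nodes["logits"], y)}
    D = params.n_dims
    gmean = np.zeros(D) if priors.gamma_mean is None else np.asarray(priors.gamma_mean)
    gscale = np.ones(D) if priors.gamma_scale is None else np.asarray(priors.gamma_scale)
    parts["prior_gamma"] = _normal_logpdf_sum(pt["gamma"], gmean, gscale)
    if priors.kappa_prior_kind == "lognormal":
        log_loc = np.log(max(priors.kappa_loc, 1e-12))
        log_scale = priors.kappa_scale / max(priors.kappa_loc, 1e-12)
        parts["prior_kappa"] = _normal_logpdf_sum(pt["kappa_raw"], log_loc, log_scale)
    else:
        parts["prior_kappa"] = _normal_logpdf_sum(
            nodes["kappa"], priors.kappa_loc, priors.kappa_scale)
    parts["prior_mu"] = _normal_logpdf_sum(pt["mu"], priors.mu_mean, priors.mu_scale)
    parts["prior_sigma"] = _normal_logpdf_sum(
        nodes["sigma"], priors.sigma_mean, priors.sigma_scale)

    K, J = params.n_rules, params.n_detectors
    zeros_kj = np.zeros((K, J))
    lo_a = zeros_kj if priors.eta_abund_low is None else priors.eta_abund_low
    hi_a = zeros_kj + 1.0 if priors.eta_abund_high is None else priors.eta_abund_high
    lo_s = zeros_kj - 1.0 if priors.eta_slope_low is None else priors.eta_slope_low
    hi_s = zeros_kj + 1.0 if priors.eta_slope_high is None else priors.eta_slope_high
    parts["prior_eta"] = _uniform_barrier(pt["eta_abund"], lo_a, hi_a,
                                          priors.barrier_frac) \
        + _uniform_barrier(pt["eta_slope"], lo_s, hi_s, priors.barrier_frac)

    parts["prior_w"] = _normal_logpdf_sum(pt["w"], 0.0, priors.w_scale) \
        + _normal_logpdf_sum(pt["w0"], 0.0, priors.w_scale)
    parts["prior_selectors"] = (
        _normal_logpdf_sum(pt["zeta_z_abund"], 0.0, priors.selector_scale)
        + _normal_logpdf_sum(pt["zeta_z_slope"], 0.0, priors.selector_scale)
        + _normal_logpdf_sum(pt["zeta_q"], 0.0, priors.selector_scale)
    )
    det_count = (nodes["z_abund"] + nodes["z_slope"]).sum(axis=1)   # (K,)
    rule_count = nodes["q"].sum(keepdims=True)
    parts["prior_counts"] = _negbin_logpmf_sum(
        det_count, priors.count_mean, priors.count_var) \
        + _negbin_logpmf_sum(rule_count, priors.count_mean, priors.count_var)

    total = parts["likelihood"]
    for name, term in parts.items():
        if name != "likelihood":
            total = total + term
    if not np.isfinite(total.value):
        bad = [name for name, term in parts.items()
               if not np.all(np.isfinite(term.value))]
        raise FloatingPointError(f"log-posterior diverged in terms: {bad}")
    return total, parts, nodes


def log_posterior(params: ModelParams, temps: TemperatureState,
                  priors: PriorConfig, dataset: MicrobiomeDataset,
                  embedding: PhyloEmbedding, return_parts: bool = False):
    """Joint log-density of labels and parameters (the training objective)."""
    total, parts, _ = _objective(params, temps, priors, dataset, embedding,
                                 requires_grad=False)
    if return_parts:
        return float(total.value), {k: float(t.value.sum()) for k, t in parts.items()}
    return float(total.value)


def log_posterior_with_grad(params: ModelParams, temps: TemperatureState,
                            priors: PriorConfig, dataset: MicrobiomeDataset,
                            embedding: PhyloEmbedding):
    """Objective value and its gradient with respect to every parameter."""
    total, _, nodes = _objective(params, temps, priors, dataset, embedding,
                                 requires_grad=True)
    total.backward()
    grads = {f: nodes["tensors"][f].grad for f in PARAM_FIELDS}
    return float(total.value), grads


def predict_proba(params: ModelParams, temps: TemperatureState,
                  dataset: MicrobiomeDataset, embedding: PhyloEmbedding) -> np.ndarray:
    """Per-subject probability of label 1 under the soft model."""
    nodes = forward(params, temps, dataset, embedding, requires_grad=False)
    return expit(nodes["logits"].value)
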