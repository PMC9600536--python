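"""Discrete readout of a fitted model: human-readable rules and reports.

After annealing, every relaxed gate is close to 0 or 1, so the soft model
is binarised by thresholding at 0.5: rules with selector q > 0.5 are kept,
detectors with selector z > 0.5 are kept, and a detector's taxon group is
the set of taxa with membership u > 0.5. Each kept detector is then
re-evaluated with *hard* logic — samples strictly inside the window, exact
mean or ordinary-least-squares slope, exact threshold comparison — which
is what the rendered rules claim.

Window endpoints are reported in days; slope thresholds are abundance
change per day.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import MicrobiomeDataset
from .embedding import PhyloEmbedding
from .model import forward

logger = logging.getLogger(__name__)

__all__ = [
    "Detector",
    "Rule",
    "RuleSet",
    "binarize",
    "rule_to_text",
    "subject_activation_report",
    "export_report",
    "load_ruleset",
]

CUTOFF = 0.5


@dataclass
class Detector:
    kind: str                 # "abundance" or "slope"
    taxa: list                # taxon ids with membership > 0.5
    taxa_idx: np.ndarray
    window: tuple             # (start_day, end_day)
    threshold: float          # abundance, or abundance change per day
    selector: float           # soft z value retained for reference
    weights: np.ndarray = None  # (N,) taxon aggregation weights (soft u)
    truth: np.ndarray = None  # (S,) hard truth per subject


@dataclass
class Rule:
    detectors: list
    weight: float             # log-odds contribution when the rule fires
    selector: float           # soft q value
    truth: np.ndarray = None  # (S,) conjunction of detector truths


@dataclass
class RuleSet:
    rules: list
    intercept: float
    subjects: list
    duration: float
    predictions: np.ndarray = None   # (S,) hard labels
    log_odds: np.ndarray = None      # (S,) combined log odds
    warning: str | None = None

    @property
    def is_empty(self) -> bool:
        return len(self.rules) == 0


def _hard_detector_truth(det: Detector, dataset: MicrobiomeDataset) -> np.ndarray:
    """Hard re-evaluation: exact window samples, exact threshold comparison.

    Aggregation keeps the detector's membership weights (the annealed u),
    so the recomputed feature matches what the threshold was learned
    against; the taxa list names the members with weight > 0.5.
    """
    lo, hi = det.window
    S = dataset.n_subjects
    truth = np.zeros(S, dtype=bool)
    if det.weights is not None:
        w = np.asarray(det.weights, dtype=float)
    else:
        w = np.zeros(dataset.n_taxa)
        w[det.taxa_idx] = 1.0
    for s in range(S):
        tdays = dataset.subject_times(s)
        inside = (tdays >= lo) & (tdays <= hi)
        if not inside.any():
            continue
        agg = (dataset.subject_abundances(s) @ w)[inside]
        if det.kind == "abundance":
            feature = agg.mean()
        else:
            t = tdays[inside]
            if len(t) < 2 or np.ptp(t) == 0:
                feature = 0.0
            else:
                feature = np.polyfit(t, agg, 1)[0]   # slope per day
        truth[s] = feature > det.threshold
    return truth


def binarize(fitted, dataset: MicrobiomeDataset,
             embedding: PhyloEmbedding) -> RuleSet:
    """Threshold the annealed soft model into a discrete rule set."""
    params = fitted.params
    nodes = forward(params, fitted.temps, dataset, embedding, requires_grad=False)
    u = nodes["u"].value            # (K,J,N)
    h = nodes["h"].value            # (T,K,J) soft in-window indicators
    z_a = nodes["z_abund"].value
    z_s = nodes["z_slope"].value
    q = nodes["q"].value
    times = dataset.times
    duration = dataset.duration

    def snapped_window(k, j):
        """Window edges snapped to inter-sample midpoints, so the hard
        window contains exactly the grid times the soft indicator selects
        (windows are only identified up to the sampling resolution)."""
        inside = np.flatnonzero(h[:, k, j] > CUTOFF)
        if inside.size == 0:
            return None
        lo_i, hi_i = inside[0], inside[-1]
        lo = times[lo_i] if lo_i == 0 else 0.5 * (times[lo_i - 1] + times[lo_i])
        hi = times[hi_i] if hi_i == len(times) - 1 \
            else 0.5 * (times[hi_i] + times[hi_i + 1])
        return float(lo), float(hi)

    rules = []
    notes = []
    for k in range(params.n_rules):
        if q[k] <= CUTOFF:
            continue
        detectors = []
        for j in range(params.n_detectors):
            for kind, z, eta in (
                ("abundance", z_a[k, j], params.eta_abund[k, j]),
                ("slope", z_s[k, j], params.eta_slope[k, j]),
            ):
                if z <= CUTOFF:
                    continue
                idx = np.flatnonzero(u[k, j] > CUTOFF)
                if idx.size == 0:
                    notes.append(f"rule {k}: {kind} detector {j} selects no taxa")
                    continue
                window = snapped_window(k, j)
                if window is None:
                    notes.append(f"rule {k}: {kind} detector {j} has an empty window")
                    continue
                det = Detector(
                    kind=kind,
                    taxa=[dataset.taxa[i] for i in idx],
                    taxa_idx=idx,
                    window=window,
                    threshold=float(eta),
                    selector=float(z),
                    weights=u[k, j].copy(),
                )
                det.truth = _hard_detector_truth(det, dataset)
                detectors.append(det)
        if not detectors:
            notes.append(f"rule {k} kept by selector but has no active detectors")
            continue
        truth = np.logical_and.reduce([d.truth for d in detectors])
        rules.append(Rule(detectors=detectors, weight=float(params.w[k]),
                          selector=float(q[k]), truth=truth))

    warning = "; ".join(notes) if notes else None
    ruleset = RuleSet(rules=rules, intercept=float(params.w0),
                      subjects=list(dataset.subjects), duration=duration,
                      warning=warning)
    if not rules:
        ruleset.warning = (warning + "; " if warning else "") + \
            "no rule survived binarisation"
        warnings.warn(ruleset.warning)
        ruleset.log_odds = np.full(dataset.n_subjects, ruleset.intercept)
        ruleset.predictions = (ruleset.log_odds > 0).astype(int)
        return ruleset
    odds = ruleset.intercept + np.sum(
        [r.weight * r.truth for r in rules], axis=0)
    ruleset.log_odds = odds
    ruleset.predictions = (odds > 0).astype(int)
    return ruleset


def rule_to_text(rule: Rule, duration: float | None = None) -> str:
    """Render a rule as an English conditional clause."""
    clauses = []
    for det in rule.detectors:
        taxa = ", ".join(det.taxa)
        if det.kind == "abundance":
            what = f"the aggregated abundance of {taxa}"
            thresh = f"{det.threshold:.4g}"
        else:
            what = f"the rate of change of abundance of {taxa}"
            thresh = f"{det.threshold:.4g} per day"
        clauses.append(
            f"{what} between day {det.window[0]:.1f} and day {det.window[1]:.1f} "
            f"is above {thresh}"
        )
    return "TRUE if " + " AND ".join(clauses)


def subject_activation_report(ruleset: RuleSet, dataset: MicrobiomeDataset) -> dict:
    """Per-subject truth values and log-odds contributions.

    Returns arrays keyed by: 'detector_truth' (list of (S,) arrays per rule),
    'rule_truth' (R, S), 'rule_log_odds' (R, S), 'combined_log_odds' (S,).
    """
    if ruleset.is_empty:
        raise ValueError("activation report requires a nonempty rule set")
    rule_truth = np.array([r.truth for r in ruleset.rules])
    contrib = np.array([r.weight * r.truth for r in ruleset.rules], dtype=float)
    combined = ruleset.intercept + contrib.sum(axis=0)
    return {
        "detector_truth": [
            np.array([d.truth for d in r.detectors]) for r in ruleset.rules
        ],
        "rule_truth": rule_truth,
        "rule_log_odds": contrib,
        "combined_log_odds": combined,
    }


def _ruleset_payload(ruleset: RuleSet) -> dict:
    return {
        "intercept": ruleset.intercept,
        "duration": ruleset.duration,
        "subjects": list(ruleset.subjects),
        "warning": ruleset.warning,
        "predictions": None if ruleset.predictions is None
        else ruleset.predictions.tolist(),
        "log_odds": None if ruleset.log_odds is None
        else ruleset.log_odds.tolist(),
        "rules": [
            {
                "weight": r.weight,
                "selector": r.selector,
                "truth": r.truth.tolist(),
                "detectors": [
                    {
                        "kind": d.kind,
                        "taxa": list(d.taxa),
                        "taxa_idx": d.taxa_idx.tolist(),
                        "window": list(d.window),
                        "threshold": d.threshold,
                        "selector": d.selector,
                        "weights": None if d.weights is None else d.weights.tolist(),
                        "truth": d.truth.tolist(),
                    }
                    for d in r.detectors
                ],
            }
            for r in ruleset.rules
        ],
    }


def load_ruleset(path) -> RuleSet:
    """Reconstruct a RuleSet from its structured export."""
    with open(path) as fh:
        payload = json.load(fh)
    rules = []
    for rp in payload["rules"]:
        detectors = [
            Detector(
                kind=dp["kind"], taxa=dp["taxa"],
                taxa_idx=np.asarray(dp["taxa_idx"], dtype=int),
                window=tuple(dp["window"]), threshold=dp["threshold"],
                selector=dp["selector"],
                weights=None if dp.get("weights") is None
                else np.asarray(dp["weights"], dtype=float),
                truth=np.asarray(dp["truth"], dtype=bool),
            )
            for dp in rp["detectors"]
        ]
        rules.append(Rule(detectors=detectors, weight=rp["weight"],
                          selector=rp["selector"],
                          truth=np.asarray(rp["truth"], dtype=bool)))
    return RuleSet(
        rules=rules, intercept=payload["intercept"],
        subjects=payload["subjects"], duration=payload["duration"],
        predictions=None if payload["predictions"] is None
        else np.asarray(payload["predictions"], dtype=int),
        log_odds=None if payload["log_odds"] is None
        else np.asarray(payload["log_odds"], dtype=float),
        warning=payload["warning"],
    )


def export_report(ruleset: RuleSet, dataset: MicrobiomeDataset, outdir) -> list:
    """Write the text summary, structured rules, activations, and figures.

    Returns the list of written paths. One figure per rule shows each
    detector's aggregated trajectories with the learned window and
    threshold overlaid.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    txt = outdir / "rules.txt"
    with open(txt, "w") as fh:
        if ruleset.is_empty:
            fh.write("No rules survived binarisation.\n")
            if ruleset.warning:
                fh.write(f"Note: {ruleset.warning}\n")
        else:
            fh.write(f"Intercept (log odds): {ruleset.intercept:.4g}\n\n")
            for i, rule in enumerate(ruleset.rules):
                fh.write(f"Rule {i} (weight {rule.weight:+.4g}):\n")
                fh.write("  " + rule_to_text(rule, ruleset.duration) + "\n\n")
    written.append(txt)

    js = outdir / "rules.json"
    with open(js, "w") as fh:
        json.dump(_ruleset_payload(ruleset), fh, indent=1)
    written.append(js)

    if ruleset.is_empty:
        return written

    act = subject_activation_report(ruleset, dataset)
    table = outdir / "activations.csv"
    import pandas as pd
    df = pd.DataFrame(
        {f"rule_{i}_truth": ruleset.rules[i].truth.astype(int)
         for i in range(len(ruleset.rules))},
        index=ruleset.subjects,
    )
    for i in range(len(ruleset.rules)):
        df[f"rule_{i}_log_odds"] = act["rule_log_odds"][i]
    df["combined_log_odds"] = act["combined_log_odds"]
    df["prediction"] = ruleset.predictions
    df["label"] = dataset.labels
    df.index.name = "subject"
    df.to_csv(table)
    written.append(table)

    tnorm_days = dataset.times
    for i, rule in enumerate(ruleset.rules):
        fig, axes = plt.subplots(
            len(rule.detectors), 1, squeeze=False,
            figsize=(7, 2.6 * len(rule.detectors)),
        )
        for ax, det in zip(axes[:, 0], rule.detectors):
            for s in range(dataset.n_subjects):
                t = dataset.subject_times(s)
                agg = dataset.subject_abundances(s)[:, det.taxa_idx].sum(axis=1)
                color = "tab:red" if dataset.labels[s] else "tab:blue"
                ax.plot(t, agg, color=color, alpha=0.45, lw=0.9)
            ax.axvspan(*det.window, color="0.85", zorder=0)
            if det.kind == "abundance":
                ax.axhline(det.threshold, color="k", ls="--", lw=1)
            label = f"{det.kind}: {len(det.taxa)} taxa"
            ax.set_title(label, fontsize=9)
            ax.set_xlabel("day")
            ax.set_ylabel("aggregated abundance")
            ax.set_xlim(tnorm_days[0], tnorm_days[-1])
        fig.suptitle(f"Rule {i}: weight {rule.weight:+.3g}", fontsize=10)
        fig.tight_layout()
        figpath = outdir / f"rule_{i}.png"
        fig.savefig(figpath, dpi=110)
        plt.close(fig)
        written.append(figpath)
    return written
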