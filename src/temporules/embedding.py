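"""Phylogenetic embedding by principal coordinate analysis (PCoA).

The pairwise phylogenetic distance matrix is embedded into a
low-dimensional Euclidean space so that taxon groups can be parameterised
continuously as balls (center + radius). The embedding dimension is chosen
as the smallest D for which a two-sample Kolmogorov-Smirnov test cannot
distinguish the original distance distribution from the embedded one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ks_2samp

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloEmbedding",
    "pcoa_embed",
    "select_embedding_dim",
    "radius_prior_from_families",
    "build_embedding",
    "load_family_table",
    "write_embedding",
]

DEFAULT_ALPHA = 0.05
DEFAULT_DMAX = 30


@dataclass
class PhyloEmbedding:
    """Coordinates of taxa in the embedded phylogenetic space."""

    E: np.ndarray              # (N, dim) coordinates
    dim: int
    eigenvalues: np.ndarray    # full spectrum of the centered Gram matrix
    radius_prior_loc: float | None = None
    radius_prior_scale: float | None = None

    @property
    def n_taxa(self) -> int:
        return self.E.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        return squareform(pdist(self.E))


def _gram_eigendecomposition(P: np.ndarray):
    """Double-center the squared distance matrix and eigendecompose."""
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    if P.shape != (N, N) or np.any(np.abs(P - P.T) > 1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ (P**2) @ J
    eigvals, eigvecs = eigh(B)          # ascending
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def pcoa_embed(P: np.ndarray, d: int):
    """Classical metric scaling of a distance matrix to d dimensions.

    Returns (coordinates, eigenvalues). Coordinates are the top-d
    eigenvectors of the double-centered Gram matrix scaled by the square
    roots of their eigenvalues. Axes with non-positive eigenvalues cannot
    carry coordinates; asking for more is an error. Each axis' sign is
    fixed so its largest-magnitude entry is positive, making the embedding
    reproducible.
    """
    eigvals, eigvecs = _gram_eigendecomposition(P)
    n_pos = int(np.sum(eigvals > 1e-10))
    if not 1 <= d <= P.shape[0] - 1:
        raise ValueError(f"d must lie in [1, {P.shape[0] - 1}]")
    if d > n_pos:
        raise ValueError(
            f"d={d} exceeds the {n_pos} positive eigenvalues; maximum usable d is {n_pos}"
        )
    E = eigvecs[:, :d] * np.sqrt(eigvals[:d])
    flip = np.sign(E[np.argmax(np.abs(E), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    return E * flip, eigvals


def select_embedding_dim(P: np.ndarray, alpha: float = DEFAULT_ALPHA,
                         dmax: int = DEFAULT_DMAX) -> int:
    """Smallest D whose embedded distances pass a two-sample KS test.

    Scans D = 1..dmax (capped at the number of positive eigenvalues) and
    returns the first D for which the KS p-value comparing original vs
    embedded pairwise distances exceeds `alpha`. If none qualifies, returns
    the scan's last D with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    if N < 3:
        raise ValueError("dimension selection needs at least 3 taxa")
    eigvals, eigvecs = _gram_eigendecomposition(P)
    n_pos = int(np.sum(eigvals > 1e-10))
    cap = min(dmax, n_pos) if n_pos else 1
    orig = squareform(P, checks=False)
    last = 1
    for D in range(1, cap + 1):
        E = eigvecs[:, :D] * np.sqrt(np.maximum(eigvals[:D], 0.0))
        emb = pdist(E)
        if ks_2samp(orig, emb).pvalue > alpha:
            return D
        last = D
    logger.warning(
        "no embedding dimension up to %d passed the KS test at alpha=%g; using %d",
        cap, alpha, last,
    )
    return last


def radius_prior_from_families(E: np.ndarray, family_assignment: dict):
    """Location/scale for the phylogenetic-radius prior from family structure.

    For every taxonomic family with >= 2 members, collect the pairwise
    embedded distances among members. The prior location is the median of
    all such distances pooled over families; the scale is the median over
    families of the within-family distance variances (population variance;
    zero for a two-member family).

    `family_assignment` maps taxon index (row of E) to a family label.
    """
    groups: dict = {}
    for idx, fam in family_assignment.items():
        groups.setdefault(fam, []).append(idx)
    pooled, variances = [], []
    for members in groups.values():
        if len(members) < 2:
            continue
        dists = pdist(E[np.asarray(members)])
        pooled.extend(dists)
        variances.append(float(np.var(dists)))
    if not pooled:
        raise ValueError(
            "no family has >= 2 members; fall back to a constant radius prior "
            "(e.g. the median of all pairwise embedded distances)"
        )
    return float(np.median(pooled)), float(np.median(variances))


def radius_prior_global(E: np.ndarray):
    """Fallback radius prior when no family annotation exists.

    Uses the median and variance of all pairwise embedded distances.
    """
    dists = pdist(E)
    logger.info("no family annotation: radius prior from all pairwise distances")
    return float(np.median(dists)), float(np.var(dists))


def load_family_table(path, taxa: list, delimiter=None) -> dict:
    """Read a two-column (taxon, family) table as a taxon-index map.

    Taxa absent from the table are placed in singleton families (they
    simply contribute nothing to the radius prior).
    """
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter,
                     engine="python" if delimiter is None else "c")
    if df.shape[1] < 2:
        raise ValueError("taxonomy table needs two columns: taxon, family")
    mapping = {str(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}
    return {i: mapping.get(t, f"_singleton_{i}") for i, t in enumerate(taxa)}


def write_embedding(embedding: PhyloEmbedding, taxa: list, path) -> None:
    """Export the coordinates as a delimited matrix (taxa x axes)."""
    import pandas as pd

    pd.DataFrame(embedding.E, index=taxa,
                 columns=[f"axis_{i}" for i in range(embedding.dim)]).to_csv(path)


def build_embedding(P: np.ndarray, alpha: float = DEFAULT_ALPHA,
                    dmax: int = DEFAULT_DMAX,
                    family_assignment: dict | None = None) -> PhyloEmbedding:
    """End-to-end embedding: choose D, embed, and derive the radius prior."""
    dim = select_embedding_dim(P, alpha=alpha, dmax=dmax)
    E, eigvals = pcoa_embed(P, dim)
    if family_assignment:
        loc, scale = radius_prior_from_families(E, family_assignment)
    else:
        loc, scale = radius_prior_global(E)
    return PhyloEmbedding(E=E, dim=dim, eigenvalues=eigvals,
                          radius_prior_loc=loc, radius_prior_scale=scale)
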