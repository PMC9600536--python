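"""Loading, validation and filtering of longitudinal microbiome cohorts.

The canonical in-memory object is :class:`MicrobiomeDataset`: per-subject
relative-abundance time series aligned on the union grid of all observed
sample times, with a boolean presence mask, binary host labels, and a
pairwise phylogenetic distance matrix over the taxa.

Time is kept in the original units (days, 0-based at the first
observation). The model itself works on times normalised to [0, 1] by the
study duration; :attr:`MicrobiomeDataset.normalized_times` provides that
view.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "MicrobiomeDataset",
    "load_abundance_table",
    "load_labels_table",
    "load_phylo_distances",
    "patristic_distances",
    "normalize_relative",
    "filter_prevalence",
    "assemble_dataset",
    "write_abundance_table",
    "write_labels_table",
    "write_distance_matrix",
]

SUBJECT_COL = "subject"
TIME_COL = "time"


@dataclass
class MicrobiomeDataset:
    """Aligned longitudinal cohort.

    Attributes
    ----------
    subjects : list of str
        Subject identifiers, one per row of `labels`.
    labels : (S,) int array
        Binary host status per subject (0/1).
    taxa : list of str
        Taxon identifiers, columns of the abundance tensor.
    times : (T,) float array
        Union grid of observed sample times, in days, strictly increasing.
    abundances : (S, T, N) float array
        Relative abundances; rows at unobserved grid points are zero.
    mask : (S, T) bool array
        True where subject s was sampled at grid time t.
    distances : (N, N) float array
        Symmetric nonnegative phylogenetic distances, zero diagonal.
    """

    subjects: list
    labels: np.ndarray
    taxa: list
    times: np.ndarray
    abundances: np.ndarray
    mask: np.ndarray
    distances: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def duration(self) -> float:
        """Study length in days: max observed time minus min observed time."""
        return float(self.times[-1] - self.times[0])

    @property
    def normalized_times(self) -> np.ndarray:
        """Grid times mapped to [0, 1] by the study duration."""
        span = self.duration
        if span == 0:
            return np.zeros_like(self.times)
        return (self.times - self.times[0]) / span

    def subject_times(self, s: int) -> np.ndarray:
        return self.times[self.mask[s]]

    def subject_abundances(self, s: int) -> np.ndarray:
        return self.abundances[s][self.mask[s]]

    def validate(self) -> None:
        S, T, N = self.abundances.shape
        if len(self.subjects) != S or len(self.taxa) != N:
            raise ValueError("subject/taxon lists inconsistent with tensor shape")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must take values in {0, 1}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("union time grid must be strictly increasing")
        if not self.mask.any(axis=1).all():
            bad = [self.subjects[i] for i in np.flatnonzero(~self.mask.any(axis=1))]
            raise ValueError(f"subjects with no samples: {bad}")
        obs = self.abundances[self.mask]
        if np.any(obs < 0):
            raise ValueError("negative abundances")
        sums = obs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("observed abundance rows must sum to 1 within 1e-8")
        D = self.distances
        if D.shape != (N, N):
            raise ValueError("distance matrix shape does not match taxa")
        if np.any(D < 0) or np.any(np.abs(D - D.T) > 1e-10) or np.any(np.diag(D) != 0):
            raise ValueError("distances must be symmetric, nonnegative, zero-diagonal")

    def subset_subjects(self, idx) -> "MicrobiomeDataset":
        idx = np.asarray(idx)
        mask = self.mask[idx]
        keep = mask.any(axis=0)
        return replace(
            self,
            subjects=[self.subjects[i] for i in idx],
            labels=self.labels[idx],
            times=self.times[keep],
            abundances=self.abundances[idx][:, keep],
            mask=mask[:, keep],
        )


def load_abundance_table(path, delimiter=None, ignore_columns=()) -> pd.DataFrame:
    """Read a longitudinal abundance table.

    One row per (subject, sample time); a ``subject`` column, a ``time``
    column (days, coerced to float), and one numeric column per taxon.
    Columns listed in `ignore_columns` are dropped before validation.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    df = df.drop(columns=list(ignore_columns), errors="ignore")
    for col in (SUBJECT_COL, TIME_COL):
        if col not in df.columns:
            raise ValueError(f"abundance table is missing required column {col!r}")
    df[TIME_COL] = pd.to_numeric(df[TIME_COL], errors="raise")
    dup = df.duplicated(subset=[SUBJECT_COL, TIME_COL])
    if dup.any():
        pairs = df.loc[dup, [SUBJECT_COL, TIME_COL]].values.tolist()
        raise ValueError(f"duplicated (subject, time) rows: {pairs}")
    taxa = [c for c in df.columns if c not in (SUBJECT_COL, TIME_COL)]
    if not taxa:
        raise ValueError("abundance table has no taxon columns")
    for col in taxa:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ValueError(
                f"non-numeric abundance in column {col!r}, rows {bad}"
            ) from exc
    return df


def load_labels_table(path, delimiter=None) -> dict:
    """Read a two-column (subject, label) table into a dict."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if df.shape[1] < 2:
        raise ValueError("labels table needs two columns: subject, label")
    subj_col, label_col = df.columns[:2]
    labels = {}
    for _, row in df.iterrows():
        val = row[label_col]
        if val not in (0, 1):
            raise ValueError(f"label for subject {row[subj_col]!r} is {val!r}, not 0/1")
        labels[str(row[subj_col])] = int(val)
    return labels


def patristic_distances(tree: dendropy.Tree, taxa: list) -> np.ndarray:
    """Leaf-to-leaf branch-length path sums, ordered to `taxa`."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length} in tree")
    pdm = tree.phylogenetic_distance_matrix()
    leaves = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    N = len(taxa)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            D[i, j] = D[j, i] = pdm.patristic_distance(leaves[taxa[i]], leaves[taxa[j]])
    return D


def load_phylo_distances(source, taxa: list, delimiter=None) -> np.ndarray:
    """Load phylogenetic distances from a newick tree or a square matrix file.

    The result is restricted and ordered to `taxa`. A file whose content
    starts with ``(`` is treated as newick; otherwise it is parsed as a
    delimited square matrix with matching row/column labels.
    """
    with open(source) as fh:
        text = fh.read()
    if text.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=text, schema="newick")
        return patristic_distances(tree, taxa)
    df = pd.read_csv(io.StringIO(text), sep=delimiter,
                     engine="python" if delimiter is None else "c", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    missing = [t for t in taxa if t not in df.index or t not in df.columns]
    if missing:
        raise ValueError(f"taxa absent from distance matrix: {missing}")
    D = df.loc[taxa, taxa].to_numpy(dtype=float)
    if np.any(np.abs(D - D.T) > 1e-8) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric and nonnegative")
    np.fill_diagonal(D, 0.0)
    return D


def normalize_relative(counts: np.ndarray) -> np.ndarray:
    """Divide each row by its sum, producing relative abundances."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    sums = counts.sum(axis=-1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero sample rows at indices {zero.tolist()}")
    return counts / sums[..., None]


def filter_prevalence(dataset: MicrobiomeDataset, cutoff: float) -> MicrobiomeDataset:
    """Drop taxa present (abundance > 0) in fewer than `cutoff` of all samples.

    Prevalence is pooled over the samples of every subject. Surviving rows
    are re-normalised to the simplex; the distance matrix is subset to the
    surviving taxa.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    obs = dataset.abundances[dataset.mask]  # (total samples, N)
    prevalence = (obs > 0).mean(axis=0)
    keep = np.flatnonzero(prevalence >= cutoff)
    if keep.size == 0:
        raise ValueError(f"prevalence cutoff {cutoff} removed every taxon")
    sub = dataset.abundances[:, :, keep]
    out = np.zeros_like(sub)
    sums = sub.sum(axis=2)
    dead = dataset.mask & (sums <= 0)
    if dead.any():
        s, t = np.argwhere(dead)[0]
        raise ValueError(
            f"sample (subject {dataset.subjects[s]}, t={dataset.times[t]}) "
            "lost all abundance mass under the prevalence filter"
        )
    np.divide(sub, sums[..., None], out=out, where=sums[..., None] > 0)
    return replace(
        dataset,
        taxa=[dataset.taxa[i] for i in keep],
        abundances=out,
        distances=dataset.distances[np.ix_(keep, keep)],
    )


def assemble_dataset(abundance_df: pd.DataFrame, labels: dict,
                     distances: np.ndarray) -> MicrobiomeDataset:
    """Build the aligned dataset from a parsed table, labels, and distances.

    Subjects are the intersection-checked union of the abundance table's
    subject column; each must have a label in `labels`. The union time grid
    is the sorted set of all observed times, with a per-subject mask.
    """
    taxa = [c for c in abundance_df.columns if c not in (SUBJECT_COL, TIME_COL)]
    subjects = sorted({str(s) for s in abundance_df[SUBJECT_COL]})
    if not subjects:
        raise ValueError("abundance table contains no subjects")
    missing = [s for s in subjects if s not in labels]
    if missing:
        raise ValueError(f"labels missing for subjects: {missing}")
    grid = np.array(sorted(abundance_df[TIME_COL].unique()), dtype=float)
    t_index = {t: i for i, t in enumerate(grid)}
    S, T, N = len(subjects), len(grid), len(taxa)
    X = np.zeros((S, T, N))
    mask = np.zeros((S, T), dtype=bool)
    for s, subj in enumerate(subjects):
        rows = abundance_df[abundance_df[SUBJECT_COL].astype(str) == subj]
        rows = rows.sort_values(TIME_COL)
        for _, row in rows.iterrows():
            t = t_index[float(row[TIME_COL])]
            mask[s, t] = True
            X[s, t] = normalize_relative(row[taxa].to_numpy(dtype=float))
    y = np.array([labels[s] for s in subjects], dtype=int)
    ds = MicrobiomeDataset(
        subjects=subjects, labels=y, taxa=taxa, times=grid,
        abundances=X, mask=mask, distances=np.asarray(distances, dtype=float),
    )
    ds.validate()
    return ds


# -- writers (round-trip with the loaders; used by the simulator) ----------

def write_abundance_table(dataset: MicrobiomeDataset, path) -> None:
    rows = []
    for s in range(dataset.n_subjects):
        for t in np.flatnonzero(dataset.mask[s]):
            rows.append(
                [dataset.subjects[s], dataset.times[t], *dataset.abundances[s, t]]
            )
    df = pd.DataFrame(rows, columns=[SUBJECT_COL, TIME_COL, *dataset.taxa])
    df.to_csv(path, index=False)


def write_labels_table(dataset: MicrobiomeDataset, path) -> None:
    pd.DataFrame({SUBJECT_COL: dataset.subjects, "label": dataset.labels}).to_csv(
        path, index=False
    )


def write_distance_matrix(dataset: MicrobiomeDataset, path) -> None:
    pd.DataFrame(dataset.distances, index=dataset.taxa, columns=dataset.taxa).to_csv(
        path
    )
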