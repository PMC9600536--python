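"""Loading, validation, filtering, and phylogenetic distances."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from temporules.data import (
    assemble_dataset,
    filter_prevalence,
    load_abundance_table,
    load_labels_table,
    load_phylo_distances,
    normalize_relative,
    patristic_distances,
    write_abundance_table,
    write_labels_table,
)
from temporules.simulate import SimulationConfig, simulate_cohort

from conftest import make_manual_dataset


def brute_force_patristic(tree, taxa):
    """Independent oracle: path sums via root-to-leaf branch traces."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        trace = {}
        node = leaf
        dist = 0.0
        while node is not None:
            trace[id(node)] = dist
            dist += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = trace
    N = len(taxa)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            ti, tj = paths[taxa[i]], paths[taxa[j]]
            shared = set(ti) & set(tj)
            D[i, j] = D[j, i] = min(ti[s] + tj[s] for s in shared)
    return D


class TestAbundanceTable:
    def make_csv(self, tmp_path, text):
        path = tmp_path / "ab.csv"
        path.write_text(text)
        return path

    def test_basic_parse(self, tmp_path):
        path = self.make_csv(
            tmp_path,
            "subject,time,TA,TB\nA,0,1,2\nA,7,2,2\nB,0,3,1\n",
        )
        df = load_abundance_table(path)
        assert df.shape == (3, 4)
        assert list(df.columns[2:]) == ["TA", "TB"]

    def test_duplicate_subject_time_rejected(self, tmp_path):
        path = self.make_csv(tmp_path, "subject,time,TA\nA,0,1\nA,0,2\n")
        with pytest.raises(ValueError, match="duplicated"):
            load_abundance_table(path)

    def test_ignored_metadata_column(self, tmp_path):
        path = self.make_csv(
            tmp_path, "subject,time,site,TA\nA,0,gut,1\nA,7,gut,2\n"
        )
        df = load_abundance_table(path, ignore_columns=("site",))
        assert list(df.columns) == ["subject", "time", "TA"]

    def test_non_numeric_abundance_names_column(self, tmp_path):
        path = self.make_csv(tmp_path, "subject,time,TA\nA,0,oops\n")
        with pytest.raises(ValueError, match="TA"):
            load_abundance_table(path)

    def test_round_trip_bit_exact(self, tmp_path):
        ds, _ = simulate_cohort(
            SimulationConfig(n_subjects=4, n_timepoints=5, n_taxa=6, seed=2)
        )
        write_abundance_table(ds, tmp_path / "ab.csv")
        write_labels_table(ds, tmp_path / "lab.csv")
        df = load_abundance_table(tmp_path / "ab.csv")
        labels = load_labels_table(tmp_path / "lab.csv")
        ds2 = assemble_dataset(df, labels, ds.distances)
        assert ds2.taxa == ds.taxa
        assert np.array_equal(ds2.mask, ds.mask)
        assert np.allclose(ds2.abundances, ds.abundances, atol=1e-12)


class TestPhyloDistances:
    def test_three_leaf_example(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        D = load_phylo_distances(path, ["A", "B", "C"])
        assert np.allclose(D, [[0, 2, 4], [2, 0, 4], [4, 4, 0]])

    def test_single_leaf(self):
        tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
        D = patristic_distances(tree, ["A"])
        assert D.shape == (1, 1) and D[0, 0] == 0

    def test_random_tree_matches_path_sum_oracle(self):
        rng = np.random.default_rng(3)
        from temporules.simulate import generate_reference_tree
        tree, taxa, D = generate_reference_tree(8, rng)
        assert np.allclose(D, brute_force_patristic(tree, taxa), atol=1e-10)

    def test_missing_taxon_listed(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        with pytest.raises(ValueError, match="ZZZ"):
            load_phylo_distances(path, ["A", "ZZZ"])

    def test_negative_branch_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:-0.5);", schema="newick")
        with pytest.raises(ValueError, match="negative"):
            patristic_distances(tree, ["A", "B"])

    def test_matrix_file_loading(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame([[0, 1.5], [1.5, 0]], index=["A", "B"],
                     columns=["A", "B"]).to_csv(path)
        D = load_phylo_distances(path, ["B", "A"])
        assert np.allclose(D, [[0, 1.5], [1.5, 0]])

    def test_four_point_condition_on_random_trees(self):
        # patristic distances on an additive tree satisfy, for any quartet,
        # that the two largest of the three pairings are equal
        from itertools import combinations

        from temporules.simulate import generate_reference_tree
        rng = np.random.default_rng(9)
        _, taxa, D = generate_reference_tree(6, rng)
        for i, j, k, l in combinations(range(6), 4):
            sums = sorted([D[i, j] + D[k, l], D[i, k] + D[j, l],
                           D[i, l] + D[j, k]])
            assert sums[2] - sums[1] < 1e-9


class TestNormalize:
    def test_direct_division(self):
        assert np.allclose(normalize_relative([[2, 3, 5]]), [[0.2, 0.3, 0.5]])

    def test_idempotent(self):
        row = np.array([[0.2, 0.3, 0.5]])
        assert np.allclose(normalize_relative(row), row)

    def test_random_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = normalize_relative(rng.uniform(0.1, 5, size=(5, 4)))
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_zero_row_identified(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_relative(np.array([[1, 2], [0, 0]]))


class TestPrevalenceFilter:
    def sparse_dataset(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(3, 10, 6))
        X[:, :, 0] = 0.0
        X[0, 0, 0] = 0.5          # taxon 0 present in 1 of 30 samples
        X /= X.sum(axis=2, keepdims=True)
        return make_manual_dataset(X, np.arange(10.0), [0, 1, 0])

    def test_rare_taxon_removed_at_5_percent(self):
        ds = self.sparse_dataset()
        out = filter_prevalence(ds, 0.05)
        assert "T0" not in out.taxa
        obs = out.abundances[out.mask]
        assert np.allclose(obs.sum(axis=1), 1.0)

    def test_cutoff_zero_keeps_everything(self):
        ds = self.sparse_dataset()
        out = filter_prevalence(ds, 0.0)
        assert out.taxa == ds.taxa

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(4, 6, 8)) * (rng.uniform(size=(4, 6, 8)) > 0.6)
        X += 1e-6  # keep rows normalizable
        X /= X.sum(axis=2, keepdims=True)
        ds = make_manual_dataset(X, np.arange(6.0), [0, 0, 1, 1])
        cutoff = 0.4
        obs = ds.abundances[ds.mask]
        expected = [ds.taxa[i] for i in range(8)
                    if np.mean(obs[:, i] > 0) >= cutoff]
        assert filter_prevalence(ds, cutoff).taxa == expected

    def test_monotone_in_cutoff(self):
        ds = self.sparse_dataset()
        kept = [set(filter_prevalence(ds, c).taxa) for c in (0.0, 0.3, 0.6)]
        assert kept[2] <= kept[1] <= kept[0]

    def test_all_removed_is_error(self):
        # every taxon absent from half the samples -> cutoff 0.9 removes all
        X = np.zeros((1, 4, 2))
        X[0, :2, 0] = 1.0
        X[0, 2:, 1] = 1.0
        ds = make_manual_dataset(X, np.arange(4.0), [0])
        with pytest.raises(ValueError, match="removed every taxon"):
            filter_prevalence(ds, 0.9)


class TestAssemble:
    def test_union_grid_and_masks(self):
        df = pd.DataFrame(
            {
                "subject": ["A", "A", "B", "B"],
                "time": [0.0, 7.0, 0.0, 14.0],
                "TA": [1, 2, 3, 4],
                "TB": [1, 1, 1, 1],
            }
        )
        ds = assemble_dataset(df, {"A": 0, "B": 1}, np.array([[0, 1], [1, 0]], float))
        assert np.allclose(ds.times, [0, 7, 14])
        assert ds.mask.tolist() == [[True, True, False], [True, False, True]]
        assert ds.duration == 14

    def test_unordered_times_sorted_consistently(self):
        df = pd.DataFrame(
            {
                "subject": ["A", "A", "A"],
                "time": [14.0, 0.0, 7.0],
                "TA": [3.0, 1.0, 2.0],
                "TB": [1.0, 1.0, 1.0],
            }
        )
        ds = assemble_dataset(df, {"A": 0}, np.array([[0, 1], [1, 0]], float))
        # abundances follow the sorted time order: TA/(TA+TB) increasing
        ratios = ds.abundances[0, :, 0]
        assert np.all(np.diff(ratios) > 0)

    def test_missing_label_is_error(self):
        df = pd.DataFrame({"subject": ["A"], "time": [0.0], "TA": [1.0]})
        with pytest.raises(ValueError, match="labels missing"):
            assemble_dataset(df, {}, np.zeros((1, 1)))
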