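"""Gene clustering vs a naive Ward oracle, cluster labeling, Venn consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mibc_subtyper.consensus_panel import (
    cluster_genes,
    correlation_distance,
    intersect_cohorts,
    label_clusters,
    ward_linkage,
)
from mibc_subtyper.io_formats import ExpressionMatrix
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform


def _expr(values, genes, platform="log2-array"):
    samples = [f"s{j}" for j in range(np.shape(values)[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples, dtype=float),
        platform=platform,
        gene_roles={g: "endogenous" for g in genes},
    )


# ---------------------------------------------------------------------------
# independent O(n^3) Lance-Williams Ward oracle (agglomerates the given
# dissimilarities directly, never through an embedding)
# ---------------------------------------------------------------------------

def naive_ward(dist: np.ndarray):
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), height = min(d.items(), key=lambda kv: kv[1])
        ni, nj = len(active[i]), len(active[j])
        members = active.pop(i) + active.pop(j)
        new = {}
        for k in active:
            nk = len(active[k])
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            new[(k, next_id)] = ((ni + nk) * dik + (nj + nk) * djk
                                 - nk * height) / (ni + nj + nk)
        d = {key: v for key, v in d.items() if i not in key and j not in key}
        d.update(new)
        active[next_id] = members
        merges.append((height, sorted(members)))
        next_id += 1
    return merges


def naive_ward_partition(dist: np.ndarray, k: int):
    n = dist.shape[0]
    merges = naive_ward(dist)
    # replay merges, stopping when k clusters remain
    clusters = [{i} for i in range(n)]
    for height, members in merges:
        if len(clusters) == k:
            break
        members = set(members)
        absorbed = [c for c in clusters if c <= members]
        clusters = [c for c in clusters if not (c <= members)]
        clusters.append(set().union(*absorbed))
    return {frozenset(c) for c in clusters}


class TestClusterGenes:
    def test_three_orthogonal_blocks_form_three_clusters(self):
        pattern = {
            "A": [5, 5, 5, 0, 0, 0, 0, 0, 0],
            "B": [0, 0, 0, 5, 5, 5, 0, 0, 0],
            "C": [0, 0, 0, 0, 0, 0, 5, 5, 5],
        }
        genes = ["a1", "a2", "b1", "b2", "c1", "c2"]
        values = [pattern["A"], pattern["A"], pattern["B"], pattern["B"],
                  pattern["C"], pattern["C"]]
        clusters, _ = cluster_genes(_expr(values, genes), genes, k=3)
        assert clusters["a1"] == clusters["a2"]
        assert clusters["b1"] == clusters["b2"]
        assert clusters["c1"] == clusters["c2"]
        assert len({clusters["a1"], clusters["b1"], clusters["c1"]}) == 3

    @pytest.mark.parametrize("seed", range(30))
    def test_merge_heights_match_naive_ward_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(5, 11))
        genes = [f"g{i}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, 12))
        matrix = _expr(values, genes)
        condensed = correlation_distance(matrix, genes)
        z = ward_linkage(condensed, ward_on="distance")
        oracle = naive_ward(squareform(condensed, checks=False))
        np.testing.assert_allclose(
            np.sort(z[:, 2]), np.sort([h for h, _ in oracle]), rtol=1e-8
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_k3_partition_matches_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes = [f"g{i}" for i in range(8)]
        values = rng.normal(size=(8, 15))
        matrix = _expr(values, genes)
        condensed = correlation_distance(matrix, genes)
        clusters, _ = cluster_genes(matrix, genes, k=3)
        mine = {
            frozenset(i for i, g in enumerate(genes) if clusters[g] == c)
            for c in set(clusters.values())
        }
        oracle = naive_ward_partition(squareform(condensed, checks=False), 3)
        assert mine == oracle

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(9)]
        values = rng.normal(size=(9, 20))
        matrix = _expr(values, genes)
        shuffled = _expr(values[:, rng.permutation(20)], genes)
        a, _ = cluster_genes(matrix, genes, k=3)
        b, _ = cluster_genes(shuffled, genes, k=3)
        assert a == b

    def test_zero_variance_gene_listed_in_error(self):
        genes = ["flat", "g1", "g2"]
        values = [[3, 3, 3, 3], [1, 2, 3, 4], [4, 1, 2, 2]]
        with pytest.raises(ValueError, match="flat"):
            cluster_genes(_expr(values, genes), genes, k=2)


class TestLabelClusters:
    SEEDS = {
        "basal": {"b1", "b2", "b3"},
        "luminal": {"l1", "l2", "l3"},
        "p53-like": {"p1", "p2"},
    }

    def test_disjoint_seed_hits(self):
        mapping = {"KRT5": 1, "KRT14": 1, "KRT20": 2, "UPK2": 2,
                   "CD14": 3, "CCL2": 3}
        seeds = {"basal": {"KRT5", "KRT14"}, "luminal": {"KRT20", "UPK2"},
                 "p53-like": {"CD14", "CCL2"}}
        labeled = label_clusters(mapping, seeds)
        assert labeled.cluster_labels == {1: "basal", 2: "luminal",
                                          3: "p53-like"}

    def test_overlap_matrix_against_exhaustive_permutation_oracle(self):
        # overlap rows [[2,0,0],[1,3,0],[0,0,2]] -> identity assignment, total 7
        mapping = {"b1": 1, "b2": 1, "b3": 2, "l1": 2, "l2": 2, "l3": 2,
                   "p1": 3, "p2": 3}
        labeled = label_clusters(mapping, self.SEEDS)
        overlap = labeled.overlap
        assert overlap.to_numpy().tolist() == [[2, 0, 0], [1, 3, 0], [0, 0, 2]]
        # independent exhaustive search over all 3! label permutations
        best = max(
            itertools.permutations(overlap.columns),
            key=lambda perm: sum(
                overlap.loc[c, lab] for c, lab in zip(overlap.index, perm)
            ),
        )
        assert labeled.cluster_labels == dict(zip(overlap.index, best))
        assert sum(overlap.loc[c, lab]
                   for c, lab in labeled.cluster_labels.items()) == 7

    def test_tied_assignment_is_an_error(self):
        mapping = {"b1": 1, "l1": 1, "b2": 2, "l2": 2, "p1": 3}
        with pytest.raises(ValueError, match="ambiguous"):
            label_clusters(mapping, self.SEEDS)

    def test_absent_seed_set_is_an_error(self):
        mapping = {"b1": 1, "l1": 2, "x": 3}
        with pytest.raises(ValueError, match="p53-like"):
            label_clusters(mapping, self.SEEDS)


def _labeled(cohort_id, gene_labels):
    """LabeledGeneClusters with one cluster per distinct label."""
    from mibc_subtyper.consensus_panel import LabeledGeneClusters
    clusters, labels, next_cluster = {}, {}, {}
    for g, lab in gene_labels.items():
        if lab not in next_cluster:
            next_cluster[lab] = len(next_cluster) + 1
            labels[next_cluster[lab]] = lab
        clusters[g] = next_cluster[lab]
    return LabeledGeneClusters(cohort_id=cohort_id, gene_to_cluster=clusters,
                               cluster_labels=labels,
                               linkage_matrix=np.empty((0, 4)))


class TestIntersectCohorts:
    BASE = {"A": "basal", "B": "basal", "C": "basal",
            "L": "luminal", "P": "p53-like"}

    def test_identical_labels_give_full_consensus(self):
        cohorts = [_labeled(f"c{i}", self.BASE) for i in range(4)]
        consensus = intersect_cohorts(cohorts)
        assert consensus.label_sets["basal"] == {"A", "B", "C"}
        assert consensus.unstable_genes == []

    def test_discordant_gene_reported_unstable(self):
        flipped = dict(self.BASE, A="luminal")
        cohorts = [_labeled(f"c{i}", self.BASE) for i in range(3)]
        cohorts.append(_labeled("c4", flipped))
        consensus = intersect_cohorts(cohorts)
        assert consensus.label_sets["basal"] == {"B", "C"}
        assert consensus.unstable_genes == ["A"]
        assert consensus.provenance.loc["A", "c4"] == "luminal"

    def test_cohort_order_invariance(self):
        flipped = dict(self.BASE, A="luminal")
        one = intersect_cohorts([_labeled("c1", self.BASE),
                                 _labeled("c2", flipped)])
        other = intersect_cohorts([_labeled("c2", flipped),
                                   _labeled("c1", self.BASE)])
        assert one.label_sets == other.label_sets

    def test_adding_a_cohort_never_enlarges_consensus(self):
        rng = np.random.default_rng(0)
        labels = ["basal", "luminal", "p53-like"]
        cohorts = [
            _labeled(f"c{i}",
                     {g: labels[rng.integers(0, 3)] for g in "ABCDEFGH"})
            for i in range(4)
        ]
        small = intersect_cohorts(cohorts[:2])
        big = intersect_cohorts(cohorts)
        for lab in labels:
            assert big.label_sets[lab] <= small.label_sets[lab]

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            intersect_cohorts([_labeled("c1", self.BASE)])
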