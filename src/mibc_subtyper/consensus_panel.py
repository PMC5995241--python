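"""Cross-cohort consensus gene panel derivation.

Per cohort, the subtyping genes are clustered hierarchically (distance
1 - Pearson correlation across samples, Ward agglomeration), the tree is
cut into three clusters, and each cluster is labeled basal / luminal /
p53-like by maximal overlap with seed marker lists (the optimal assignment
over all 3! label permutations — ties are a hard error, never a silent
guess).  The consensus panel keeps exactly the genes that carry the same
label in every cohort; discordant genes are reported as unstable.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, SUBTYPE_LABELS

logger = logging.getLogger(__name__)

WARD_MODES = ("distance", "squared")


@dataclass
class LabeledGeneClusters:
    """One cohort's gene clustering with semi-supervised cluster labels."""

    cohort_id: str
    gene_to_cluster: dict[str, int]
    cluster_labels: dict[int, str]
    linkage_matrix: np.ndarray
    overlap: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        k = len(set(self.gene_to_cluster.values()))
        if set(self.cluster_labels) != set(self.gene_to_cluster.values()):
            raise ValueError("cluster labels must cover exactly the clusters")
        if k == 3 and len(set(self.cluster_labels.values())) != 3:
            raise ValueError("labels must be a bijection cluster <-> label at k=3")

    def gene_labels(self) -> dict[str, str]:
        return {g: self.cluster_labels[c] for g, c in self.gene_to_cluster.items()}


@dataclass
class ConsensusPanel:
    """Signature-label -> gene-set map surviving cross-cohort intersection."""

    label_sets: dict[str, set[str]]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["consensus"])
    )
    n_cohorts: int = 0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for lab, genes in self.label_sets.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} under two labels: {seen[g]!r}, {lab!r}"
                    )
                seen[g] = lab

    @property
    def genes(self) -> list[str]:
        return sorted(g for s in self.label_sets.values() for g in s)

    @property
    def unstable_genes(self) -> list[str]:
        if "consensus" not in self.provenance.columns:
            return []
        return sorted(self.provenance.index[
            self.provenance["consensus"] == "unstable"
        ])

    def sizes(self) -> dict[str, int]:
        return {lab: len(s) for lab, s in self.label_sets.items()}

    @classmethod
    def from_labels(cls, label_sets: Mapping[str, Iterable[str]]) -> "ConsensusPanel":
        return cls(label_sets={lab: set(g) for lab, g in label_sets.items()})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label_sets": {lab: sorted(s) for lab, s in self.label_sets.items()},
            "n_cohorts": self.n_cohorts,
            "provenance": self.provenance.reset_index()
            .rename(columns={"index": "gene"}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusPanel":
        payload = json.loads(Path(path).read_text())
        prov = pd.DataFrame(payload.get("provenance", []))
        if not prov.empty:
            prov = prov.set_index("gene")
        return cls(
            label_sets={lab: set(s) for lab, s in payload["label_sets"].items()},
            provenance=prov,
            n_cohorts=payload.get("n_cohorts", 0),
        )


def correlation_distance(matrix: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Condensed 1 - Pearson distance between genes, over samples."""
    data = matrix.values.loc[list(genes)].to_numpy(dtype=float)
    variances = data.var(axis=1)
    zero_var = [g for g, v in zip(genes, variances) if v == 0]
    if zero_var:
        raise ValueError(
            f"zero-variance gene(s), correlation undefined: {zero_var}"
        )
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    return squareform(dist, checks=False)


def ward_linkage(condensed: np.ndarray, ward_on: str = "distance") -> np.ndarray:
    """Ward agglomeration on a precomputed dissimilarity.

    ``ward_on="distance"`` applies the Lance-Williams Ward update to the
    dissimilarities as given (the classic hclust ward.D usage on 1 - r),
    realized by running Ward on the square roots and squaring the merge
    heights.  ``ward_on="squared"`` treats the input as Euclidean distances
    (ward.D2 behavior).
    """
    if ward_on not in WARD_MODES:
        raise ValueError(f"ward_on must be one of {WARD_MODES}")
    if ward_on == "distance":
        z = linkage(np.sqrt(condensed), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
        return z
    return linkage(condensed, method="ward")


def cluster_genes(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    k: int = 3,
    ward_on: str = "distance",
) -> tuple[dict[str, int], np.ndarray]:
    """Cut the Ward tree over 1 - Pearson gene distances into ``k`` clusters.

    Returns the gene -> cluster map (clusters renumbered 1..k in order of
    first appearance along the input gene list) and the linkage record.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    condensed = correlation_distance(matrix, genes)
    z = ward_linkage(condensed, ward_on=ward_on)
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(f"could not cut tree into exactly {k} clusters")
    renumber: dict[int, int] = {}
    for c in raw:
        if c not in renumber:
            renumber[c] = len(renumber) + 1
    return {g: renumber[c] for g, c in zip(genes, raw)}, z


def _optimal_label_assignment(
    overlap: pd.DataFrame,
) -> dict[int, str]:
    """Maximize total seed overlap over all label permutations; tie -> error."""
    clusters = list(overlap.index)
    labels = list(overlap.columns)
    best_total, best_perms = -1, []
    for perm in itertools.permutations(labels):
        total = sum(overlap.loc[c, lab] for c, lab in zip(clusters, perm))
        if total > best_total:
            best_total, best_perms = total, [perm]
        elif total == best_total:
            best_perms.append(perm)
    if len(best_perms) > 1:
        raise ValueError(
            "ambiguous cluster labeling: multiple optimal label assignments "
            f"(total overlap {best_total}); supply more seed markers"
        )
    return dict(zip(clusters, best_perms[0]))


def label_clusters(
    gene_to_cluster: Mapping[str, int],
    seed_sets: Mapping[str, Iterable[str]],
    cohort_id: str = "cohort",
    linkage_matrix: np.ndarray | None = None,
) -> LabeledGeneClusters:
    """Assign basal/luminal/p53-like labels to gene clusters by seed overlap."""
    seed_sets = {lab: set(g) for lab, g in seed_sets.items()}
    if set(seed_sets) != set(SUBTYPE_LABELS):
        raise ValueError(f"seed sets must cover exactly {SUBTYPE_LABELS}")
    universe = set(gene_to_cluster)
    for lab, seeds in seed_sets.items():
        if not (seeds & universe):
            raise ValueError(
                f"no seed marker of label {lab!r} present among the "
                "clustered genes"
            )
    clusters = sorted(set(gene_to_cluster.values()))
    overlap = pd.DataFrame(
        [
            [
                sum(1 for g in seed_sets[lab] if gene_to_cluster.get(g) == c)
                for lab in SUBTYPE_LABELS
            ]
            for c in clusters
        ],
        index=clusters,
        columns=list(SUBTYPE_LABELS),
    )
    assignment = _optimal_label_assignment(overlap)
    return LabeledGeneClusters(
        cohort_id=cohort_id,
        gene_to_cluster=dict(gene_to_cluster),
        cluster_labels=assignment,
        linkage_matrix=(linkage_matrix if linkage_matrix is not None
                        else np.empty((0, 4))),
        overlap=overlap,
    )


def intersect_cohorts(
    labeled: Sequence[LabeledGeneClusters],
    require_nonempty: bool = False,
) -> ConsensusPanel:
    """Venn intersection: keep genes labeled identically in every cohort."""
    if len(labeled) < 2:
        raise ValueError("consensus needs at least 2 cohorts")
    per_cohort = [lc.gene_labels() for lc in labeled]
    shared = set(per_cohort[0])
    for labels in per_cohort[1:]:
        shared &= set(labels)
    rows = {}
    label_sets: dict[str, set[str]] = {lab: set() for lab in SUBTYPE_LABELS}
    for g in sorted(shared):
        labels = [labels_map[g] for labels_map in per_cohort]
        if len(set(labels)) == 1:
            label_sets[labels[0]].add(g)
            consensus = labels[0]
        else:
            consensus = "unstable"
        rows[g] = {
            **{lc.cohort_id: lab for lc, lab in zip(labeled, labels)},
            "consensus": consensus,
        }
    for lab, genes in label_sets.items():
        if not genes:
            msg = f"consensus set for label {lab!r} is empty"
            if require_nonempty:
                raise ValueError(msg)
            logger.warning(msg)
    provenance = pd.DataFrame.from_dict(rows, orient="index")
    return ConsensusPanel(label_sets=label_sets, provenance=provenance,
                          n_cohorts=len(labeled))
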