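"""Sample-level subtype assignment on the consensus gene panel.

Samples are clustered by unsupervised hierarchical clustering on their
per-gene z-scored consensus-panel profiles (distance 1 - Pearson across
genes, Ward agglomeration, tree cut at k=3).  Each cluster is then named
after the subtype whose signature mean z-score is highest in it, using the
same exhaustive 3!-optimal assignment as the gene-cluster labeling so the
naming is deterministic and auditable.  The p53-like signature label maps
to the "infiltrated" subtype.

Cross-cohort prediction uses a Pearson nearest-centroid rule on the same
z-scored consensus profiles: each new sample is assigned the subtype of
the centroid it correlates with best, with the margin between best and
second-best correlation reported per sample.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus_panel import ConsensusPanel, correlation_distance, ward_linkage
from .io_formats import ExpressionMatrix, SUBTYPE_LABELS
from scipy.cluster.hierarchy import fcluster

logger = logging.getLogger(__name__)

SUBTYPES = ("luminal", "basal", "infiltrated")

#: signature label -> sample subtype name used in all outputs
LABEL_TO_SUBTYPE = {"basal": "basal", "luminal": "luminal", "p53-like": "infiltrated"}
SUBTYPE_TO_LABEL = {v: k for k, v in LABEL_TO_SUBTYPE.items()}


@dataclass
class SubtypeAssignment:
    """Per-sample subtype calls with cluster ids and signature scores."""

    subtypes: pd.Series                   # sample -> subtype
    clusters: pd.Series                   # sample -> cluster index
    scores: pd.DataFrame                  # sample x {basal, luminal, infiltrated}
    method: str = "cluster"               # "cluster" | "centroid"
    margins: pd.Series | None = None      # centroid method only

    def __post_init__(self) -> None:
        if self.method not in ("cluster", "centroid"):
            raise ValueError(f"unknown method {self.method!r}")
        bad = set(self.subtypes.unique()) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype(s) {sorted(bad)}")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("signature scores must be finite")
        if not self.subtypes.index.equals(self.scores.index):
            raise ValueError("scores must cover exactly the assigned samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.subtypes.index)

    def counts(self) -> dict[str, int]:
        return {s: int((self.subtypes == s).sum()) for s in SUBTYPES}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "subtype": self.subtypes,
            "cluster": self.clusters,
            "score_basal": self.scores["basal"],
            "score_luminal": self.scores["luminal"],
            "score_infiltrated": self.scores["infiltrated"],
        })
        if self.margins is not None:
            df["margin"] = self.margins
        df.index.name = "sample_id"
        return df


@dataclass
class SubtypeCentroids:
    """Per-subtype mean z-scored consensus-gene profile."""

    profiles: pd.DataFrame                # consensus genes x subtypes

    def __post_init__(self) -> None:
        missing = set(SUBTYPES) - set(self.profiles.columns)
        if missing:
            raise ValueError(f"centroids missing subtype(s) {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": list(self.profiles.index),
            "profiles": {s: self.profiles[s].tolist() for s in SUBTYPES},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeCentroids":
        payload = json.loads(Path(path).read_text())
        return cls(profiles=pd.DataFrame(
            {s: payload["profiles"][s] for s in SUBTYPES},
            index=payload["genes"],
        ))


def _present_consensus_genes(matrix: ExpressionMatrix,
                             genes: list[str],
                             min_fraction: float = 0.8) -> list[str]:
    present = [g for g in genes if g in matrix.values.index]
    if len(present) < min_fraction * len(genes):
        raise ValueError(
            f"only {len(present)}/{len(genes)} consensus genes present; "
            f"need at least {min_fraction:.0%}"
        )
    dropped = sorted(set(genes) - set(present))
    if dropped:
        logger.warning("consensus genes absent from matrix: %s", dropped)
    return present


def _zscore_genes(matrix: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Per-gene z-score across samples; genes in rows."""
    data = matrix.values.loc[genes].astype(float)
    sd = data.std(axis=1, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance consensus gene(s): {zero}")
    return data.sub(data.mean(axis=1), axis=0).div(sd, axis=0)


def signature_scores(matrix: ExpressionMatrix,
                     consensus: ConsensusPanel) -> pd.DataFrame:
    """Per-sample mean z-score of each signature's genes.

    Columns are subtype-named (p53-like rendered as infiltrated).
    """
    genes = _present_consensus_genes(matrix, consensus.genes)
    z = _zscore_genes(matrix, genes)
    cols = {}
    for label, sig_genes in consensus.label_sets.items():
        present = [g for g in sig_genes if g in z.index]
        if not present:
            raise ValueError(f"no genes of signature {label!r} present")
        cols[LABEL_TO_SUBTYPE[label]] = z.loc[present].mean(axis=0)
    return pd.DataFrame(cols)[list(SUBTYPES)]


def _optimal_cluster_subtypes(cluster_scores: pd.DataFrame) -> dict[int, str]:
    """Assign subtypes to clusters maximizing total mean signature score."""
    clusters = list(cluster_scores.index)
    best_total, best_perms = -np.inf, []
    for perm in itertools.permutations(SUBTYPES):
        total = sum(cluster_scores.loc[c, s] for c, s in zip(clusters, perm))
        if total > best_total + 1e-12:
            best_total, best_perms = total, [perm]
        elif abs(total - best_total) <= 1e-12:
            best_perms.append(perm)
    if len(best_perms) > 1:
        raise ValueError(
            "ambiguous cluster -> subtype assignment (tied signature scores)"
        )
    return dict(zip(clusters, best_perms[0]))


def call_subtypes(matrix: ExpressionMatrix, consensus: ConsensusPanel,
                  k: int = 3, ward_on: str = "distance") -> SubtypeAssignment:
    """Cluster samples on the consensus panel and name the clusters.

    Requires at least ``k`` samples and >=80% of the consensus genes present.
    """
    if matrix.n_samples < k:
        raise ValueError(f"need at least k={k} samples, got {matrix.n_samples}")
    genes = _present_consensus_genes(matrix, consensus.genes)
    z = _zscore_genes(matrix, genes)
    # samples as rows for sample-sample correlation distance
    sample_matrix = ExpressionMatrix(
        values=z.T,
        platform="log2-array",
        gene_roles={s: "endogenous" for s in z.columns},
    )
    condensed = correlation_distance(sample_matrix, list(z.columns))
    linkage_matrix = ward_linkage(condensed, ward_on=ward_on)
    raw = fcluster(linkage_matrix, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(f"could not cut sample tree into exactly {k} clusters")
    renumber: dict[int, int] = {}
    for c in raw:
        if c not in renumber:
            renumber[c] = len(renumber) + 1
    clusters = pd.Series([renumber[c] for c in raw], index=z.columns,
                         name="cluster")
    scores = signature_scores(matrix, consensus)
    cluster_means = scores.groupby(clusters).mean()
    assignment = _optimal_cluster_subtypes(cluster_means)
    subtypes = clusters.map(assignment).rename("subtype")
    return SubtypeAssignment(subtypes=subtypes, clusters=clusters,
                             scores=scores.loc[subtypes.index], method="cluster")


def fit_centroids(matrix: ExpressionMatrix, assignment: SubtypeAssignment,
                  consensus: ConsensusPanel) -> SubtypeCentroids:
    """Per-subtype mean of z-scored consensus-gene expression."""
    missing = set(matrix.sample_ids) - set(assignment.sample_ids)
    if missing:
        raise ValueError(f"assignment does not cover sample(s) {sorted(missing)}")
    genes = _present_consensus_genes(matrix, consensus.genes)
    z = _zscore_genes(matrix, genes)
    profiles = {}
    for subtype in SUBTYPES:
        members = assignment.subtypes.index[assignment.subtypes == subtype]
        if len(members) == 0:
            raise ValueError(f"subtype {subtype!r} has no samples")
        profiles[subtype] = z[members].mean(axis=1)
    return SubtypeCentroids(profiles=pd.DataFrame(profiles))


def predict_subtypes(matrix: ExpressionMatrix,
                     centroids: SubtypeCentroids,
                     consensus: ConsensusPanel | None = None,
                     ) -> SubtypeAssignment:
    """Pearson nearest-centroid prediction for a new cohort.

    Profiles are per-gene z-scored within the new cohort when it has at
    least 3 samples; smaller cohorts are correlated on raw profiles (the
    per-gene standardization is undefined there).
    """
    genes = _present_consensus_genes(matrix, centroids.genes)
    z = (_zscore_genes(matrix, genes) if matrix.n_samples >= 3
         else matrix.values.loc[genes].astype(float))
    profiles = centroids.profiles.loc[genes]
    n = len(genes)
    subtypes, margins, rows = {}, {}, {}
    for sample in z.columns:
        v = z[sample].to_numpy()
        rs = {}
        for subtype in SUBTYPES:
            c = profiles[subtype].to_numpy()
            denominator = np.std(v) * np.std(c)
            if denominator == 0:
                raise ValueError(f"flat profile: cannot correlate sample {sample!r}")
            rs[subtype] = float(np.mean((v - v.mean()) * (c - c.mean()))
                                / denominator)
        ranked = sorted(rs.items(), key=lambda kv: kv[1], reverse=True)
        if ranked[0][1] == ranked[1][1]:
            raise ValueError(
                f"exact correlation tie for sample {sample!r}: "
                f"{ranked[0][0]} vs {ranked[1][0]}"
            )
        subtypes[sample] = ranked[0][0]
        margins[sample] = ranked[0][1] - ranked[1][1]
        rows[sample] = rs
    score_frame = (pd.DataFrame.from_dict(rows, orient="index")[list(SUBTYPES)]
                   if consensus is None
                   else signature_scores(matrix, consensus))
    index = pd.Index(z.columns)
    return SubtypeAssignment(
        subtypes=pd.Series(subtypes, name="subtype").reindex(index),
        clusters=pd.Series(pd.NA, index=index, name="cluster"),
        scores=score_frame.reindex(index),
        method="centroid",
        margins=pd.Series(margins, name="margin").reindex(index),
    )
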