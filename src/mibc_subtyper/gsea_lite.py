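"""Minimal gene-set enrichment analysis.

Implements the weighted Kolmogorov-Smirnov enrichment statistic: genes are
ranked by a differential-expression metric between two phenotype classes
(signal-to-noise by default, Welch t as an alternative), a running sum is
incremented at set members in proportion to |score|^p (normalized to 1)
and decremented by 1/(N - Nh) at non-members, and the enrichment score ES
is the extremum of that running sum.  Significance comes from phenotype
label permutations: the nominal p is the add-one-smoothed fraction of
permuted ES at least as extreme on the matching sign side, and NES divides
the observed ES by the mean magnitude of same-sign permuted scores.  When
the label-permutation space is smaller than the requested permutation
count the distinct labelings are enumerated exhaustively instead (with a
warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

METRICS = ("signal2noise", "t")

#: GSEA-style variance floor for the signal-to-noise denominator
_SD_FLOOR_FRACTION = 0.2


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    n_perm: int
    seed: int
    metric: str
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.es <= 1.0 + 1e-9:
            raise ValueError(f"ES {self.es} outside [-1, 1]")
        for name in ("p", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def _metric_scores(data: np.ndarray, mask_a: np.ndarray,
                   metric: str) -> np.ndarray:
    """Per-gene class-contrast scores; positive = higher in class A."""
    a, b = data[:, mask_a], data[:, ~mask_a]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    if metric == "signal2noise":
        sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
        sd_a = np.maximum(sd_a, np.maximum(_SD_FLOOR_FRACTION * np.abs(mu_a),
                                           _SD_FLOOR_FRACTION))
        sd_b = np.maximum(sd_b, np.maximum(_SD_FLOOR_FRACTION * np.abs(mu_b),
                                           _SD_FLOOR_FRACTION))
        return (mu_a - mu_b) / (sd_a + sd_b)
    var_a = a.var(axis=1, ddof=1) / a.shape[1]
    var_b = b.var(axis=1, ddof=1) / b.shape[1]
    return (mu_a - mu_b) / np.sqrt(np.maximum(var_a + var_b, 1e-12))


def rank_genes(matrix: ExpressionMatrix, phenotype: pd.Series,
               metric: str = "signal2noise") -> pd.DataFrame:
    """Rank genes by class contrast, descending; ties break by gene symbol.

    ``phenotype`` is a boolean series over the matrix samples (True =
    class A).  Both classes need at least 3 samples for the variance floor
    to be meaningful.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    phenotype = phenotype.reindex(matrix.sample_ids)
    if phenotype.isna().any():
        raise ValueError("phenotype must cover every sample")
    mask = phenotype.astype(bool).to_numpy()
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each phenotype class needs at least 3 samples")
    scores = _metric_scores(matrix.values.to_numpy(dtype=float), mask, metric)
    out = pd.DataFrame({"gene": matrix.gene_ids, "score": scores})
    out = out.sort_values(["score", "gene"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    return out


def enrichment_score(ranked: pd.DataFrame, gene_set: Iterable[str],
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS running sum over a ranked gene list.

    Returns the signed extremum (ES) and the full running-sum curve.  Hits
    are weighted by |score|^weight normalized to one; misses decrement by
    1/(N - Nh).  A set disjoint from the list is a hard error.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    in_set = np.isin(genes, list(set(gene_set)))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    n = len(genes)
    hit_weights = np.abs(scores) ** weight * in_set
    total = hit_weights.sum()
    if total == 0:  # all hit scores exactly zero: fall back to uniform steps
        hit_weights = in_set / n_hits
    else:
        hit_weights = hit_weights / total
    miss_penalty = 0.0 if n == n_hits else 1.0 / (n - n_hits)
    steps = hit_weights - miss_penalty * (~in_set)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _phenotype_permutations(mask: np.ndarray, n_perm: int,
                            rng: np.random.Generator):
    """Yield permuted class-A masks; exhaustive when the space is small."""
    n, n_a = mask.size, int(mask.sum())
    space = comb(n, n_a)
    if space <= n_perm:
        warnings.warn(
            f"only {space} distinct labelings; enumerating exhaustively",
            stacklevel=3,
        )
        for idx in combinations(range(n), n_a):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            yield m
        return
    for _ in range(n_perm):
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=n_a, replace=False)] = True
        yield m


def gsea_test(matrix: ExpressionMatrix, phenotype: pd.Series,
              gene_set: Iterable[str], set_name: str = "set",
              n_perm: int = 1000, seed: int = 0,
              metric: str = "signal2noise",
              weight: float = 1.0) -> GseaResult:
    """Phenotype-permutation GSEA for one gene set."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    gene_set = set(gene_set)
    ranked = rank_genes(matrix, phenotype, metric=metric)
    es, _ = enrichment_score(ranked, gene_set, weight=weight)

    phenotype = phenotype.reindex(matrix.sample_ids).astype(bool)
    mask = phenotype.to_numpy()
    data = matrix.values.to_numpy(dtype=float)
    genes = np.array(matrix.gene_ids)
    rng = np.random.default_rng(seed)
    perm_es = []
    exhaustive = comb(mask.size, int(mask.sum())) <= n_perm
    for m in _phenotype_permutations(mask, n_perm, rng):
        scores = _metric_scores(data, m, metric)
        order = np.lexsort((genes, -scores))
        perm_ranked = pd.DataFrame({"gene": genes[order],
                                    "score": scores[order]})
        es_p, _ = enrichment_score(perm_ranked, gene_set, weight=weight)
        perm_es.append(es_p)
    perm_es = np.array(perm_es)
    n_done = perm_es.size

    same_sign = perm_es * np.sign(es) > 0
    extreme = same_sign & (np.abs(perm_es) >= abs(es))
    p = (1 + int(extreme.sum())) / (n_done + 1)

    mean_same = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / mean_same if np.isfinite(mean_same) and mean_same > 0 else np.nan

    # single-set FDR: share of same-sign permuted NES at least as extreme
    if same_sign.any() and np.isfinite(nes):
        perm_nes = np.abs(perm_es[same_sign]) / mean_same
        fdr_q = min(1.0, float((perm_nes >= abs(nes)).mean()))
    else:
        fdr_q = 1.0
    return GseaResult(set_name=set_name, es=es,
                      nes=float(nes) if np.isfinite(nes) else 0.0,
                      p=p, fdr_q=fdr_q, n_perm=n_done, seed=seed,
                      metric=metric, exhaustive=exhaustive)
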