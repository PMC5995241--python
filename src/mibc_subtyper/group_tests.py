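"""Exact r x c association tests and rank tests for group comparisons.

The Fisher exact test is generalized to r x c tables with the
Freeman-Halton probability-ordering rule: the two-sided p-value is the sum
of multivariate-hypergeometric probabilities, over all tables with the
observed margins, of the tables whose probability does not exceed the
observed table's (up to a small relative tolerance guarding against
floating-point drift in the comparison).  Tables are enumerated exactly
when the lattice is small enough, otherwise a margin-preserving Monte
Carlo estimate is used with a reported seed and replicate count.
Probabilities are computed in log space so n ~ 50-scale tables cannot
overflow.  Continuous variables are compared with the Kruskal-Wallis rank
test (midranks, tie correction, chi-square reference distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, kruskal

from .io_formats import ExpressionMatrix
from .subtype_caller import SubtypeAssignment, SUBTYPES

#: relative tolerance for the "probability <= observed" comparison
PROB_TOL = 1e-7

DEFAULT_ENUM_CAP = 5_000_000
DEFAULT_MC_REPS = 100_000
DEFAULT_MC_SEED = 20_180_525


@dataclass
class ContingencyTable:
    """r x c grid of non-negative integer counts with labeled margins."""

    values: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)) or (arr < 0).any():
                raise ValueError("entries must be non-negative integers")
            arr = arr.astype(int)
        self.values = arr.astype(np.int64)
        if (self.values.sum(axis=1) == 0).any():
            raise ValueError("row margin with all zeros")
        if (self.values.sum(axis=0) == 0).any():
            raise ValueError("column margin with all zeros")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GroupTestResult:
    test: str
    p: float
    statistic: float = float("nan")
    df: int | None = None
    method: str = "exact-enumeration"
    mc_reps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _log_table_prob(table: np.ndarray, log_fact: np.ndarray,
                    log_const: float) -> float:
    """log multivariate-hypergeometric probability given precomputed pieces."""
    return log_const - log_fact[table].sum()


def _enumerate_tables(row_sums: np.ndarray, col_sums: np.ndarray,
                      cap: int):
    """Yield all integer tables with the given margins; raise if > cap."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)
    count = 0

    def fill_row(i: int, remaining_cols: np.ndarray):
        nonlocal count
        if i == r - 1:
            if (remaining_cols >= 0).all():
                table[i] = remaining_cols
                count += 1
                if count > cap:
                    raise _EnumerationCapExceeded
                yield table
            return
        yield from fill_cell(i, 0, row_sums[i], remaining_cols)

    def fill_cell(i: int, j: int, row_left: int, remaining_cols: np.ndarray):
        if j == c - 1:
            if 0 <= row_left <= remaining_cols[j]:
                table[i, j] = row_left
                remaining_cols[j] -= row_left
                yield from fill_row(i + 1, remaining_cols)
                remaining_cols[j] += row_left
            return
        hi = min(row_left, remaining_cols[j])
        for v in range(hi + 1):
            table[i, j] = v
            remaining_cols[j] -= v
            yield from fill_cell(i, j + 1, row_left - v, remaining_cols)
            remaining_cols[j] += v

    yield from fill_row(0, col_sums.copy())


class _EnumerationCapExceeded(Exception):
    pass


def fisher_exact_rxc(table: ContingencyTable | Sequence[Sequence[int]],
                     enum_cap: int = DEFAULT_ENUM_CAP,
                     mc_reps: int = DEFAULT_MC_REPS,
                     seed: int = DEFAULT_MC_SEED) -> GroupTestResult:
    """Two-sided Freeman-Halton exact test on an r x c table.

    The 2 x 2 case reduces to the classic two-sided hypergeometric test.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(values=np.asarray(table))
    obs = table.values
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())
    log_fact = gammaln(np.arange(n + 1) + 1.0)
    log_const = (log_fact[row_sums].sum() + log_fact[col_sums].sum()
                 - log_fact[n])
    log_p_obs = _log_table_prob(obs, log_fact, log_const)
    # relative tolerance on probabilities == additive tolerance on logs
    threshold = log_p_obs + np.log1p(PROB_TOL)

    try:
        total = 0.0
        for t in _enumerate_tables(row_sums, col_sums, enum_cap):
            lp = _log_table_prob(t, log_fact, log_const)
            if lp <= threshold:
                total += np.exp(lp)
        return GroupTestResult(test="fisher-freeman-halton",
                               p=min(total, 1.0), df=None,
                               method="exact-enumeration")
    except _EnumerationCapExceeded:
        pass

    # Monte Carlo over margin-preserving tables via label permutation
    rng = np.random.default_rng(seed)
    r, c = obs.shape
    row_labels = np.repeat(np.arange(r), row_sums)
    col_labels = np.repeat(np.arange(c), col_sums)
    hits = 0
    batch = 2000
    done = 0
    while done < mc_reps:
        b = min(batch, mc_reps - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        permuted_cols = col_labels[perms]
        idx = row_labels[None, :] * c + permuted_cols
        counts = np.zeros((b, r * c), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(b), n), idx.ravel()), 1)
        lps = log_const - gammaln(counts + 1.0).sum(axis=1)
        hits += int((lps <= threshold).sum())
        done += b
    return GroupTestResult(test="fisher-freeman-halton",
                           p=hits / mc_reps, df=None,
                           method="monte-carlo", mc_reps=mc_reps, seed=seed)


def kruskal_wallis(values_by_group: Sequence[Iterable[float]],
                   ) -> GroupTestResult:
    """Kruskal-Wallis H test with midrank ties and tie correction.

    The degenerate all-values-equal case returns H = 0, p = 1 by
    convention.
    """
    groups = [np.asarray(list(g), dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(g.size for g in groups) < 3:
        raise ValueError("Kruskal-Wallis needs a total n of at least 3")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(test="kruskal-wallis", p=1.0, statistic=0.0,
                               df=df, method="chi-square")
    h, p = kruskal(*groups)
    return GroupTestResult(test="kruskal-wallis", p=float(p),
                           statistic=float(h), df=df, method="chi-square")


def drug_target_screen(matrix: ExpressionMatrix,
                       assignment: SubtypeAssignment,
                       target_genes: Sequence[str],
                       subtyping_genes: Iterable[str] = (),
                       ) -> pd.DataFrame:
    """Kruskal-Wallis screen of drug targets across the called subtypes.

    Targets must be disjoint from the subtyping panel so the screen is a
    clustering-independent assessment; an overlap is a hard error.  The
    direction summary names the subtype with the highest median expression.
    P-values are reported unadjusted.
    """
    target_genes = list(target_genes)
    overlap = set(target_genes) & set(subtyping_genes)
    if overlap:
        raise ValueError(
            f"drug target(s) overlap the subtyping panel: {sorted(overlap)}"
        )
    missing = [g for g in target_genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"target gene(s) absent from matrix: {missing}")
    samples = assignment.sample_ids
    members = {s: assignment.subtypes.index[assignment.subtypes == s]
               for s in SUBTYPES}
    rows = []
    for gene in target_genes:
        expr = matrix.values.loc[gene, samples]
        by_group = [expr[members[s]].to_numpy(dtype=float) for s in SUBTYPES]
        res = kruskal_wallis(by_group)
        medians = {s: float(np.median(v)) for s, v in zip(SUBTYPES, by_group)}
        rows.append({
            "gene": gene,
            "H": res.statistic,
            "p": res.p,
            "direction": max(medians, key=medians.get),
            **{f"median_{s}": medians[s] for s in SUBTYPES},
        })
    return pd.DataFrame(rows).set_index("gene")
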