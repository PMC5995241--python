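"""nCounter count normalization and microarray quantile normalization.

The nCounter chain runs, in order: (1) per-sample positive-control scaling
to the cohort geometric mean of positive-control geomeans; (2) background
subtraction using the negative-control probes (policy configurable:
``mean``, ``mean_2sd`` or ``max``), floored at zero; (3) per-sample
housekeeping scaling so every sample's reference-gene geometric mean equals
the cohort geometric mean; (4) log2(x + 1).  Control and reference probes
are removed from the output.  Microarray intensities are assumed already
log2; quantile normalization equalizes every sample's distribution to the
across-sample mean of order statistics, with ties sharing the mean of the
quantile values they span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

BACKGROUND_POLICIES = ("mean", "mean_2sd", "max")


@dataclass
class NormalizationReport:
    """Per-sample normalization factors, for audit.

    ``positive_factor`` and ``reference_factor`` are the multiplicative
    scale factors applied in steps 1 and 3; ``background`` is the count
    level subtracted in step 2.  ``flags`` marks samples whose factors fall
    outside the conventional 0.3–3 quality window.
    """

    positive_factor: pd.Series
    background: pd.Series
    reference_factor: pd.Series
    flags: pd.Series
    background_policy: str = "mean"

    def __post_init__(self) -> None:
        if (self.positive_factor <= 0).any() or (self.reference_factor <= 0).any():
            raise ValueError("scale factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "positive_factor": self.positive_factor,
            "background": self.background,
            "reference_factor": self.reference_factor,
            "flag": self.flags,
        })


def _geomean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Geometric mean; exact zero whenever any value is zero."""
    values = np.asarray(values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(values)
        means = np.mean(logs, axis=axis)
    return np.where(np.isfinite(means), np.exp(means), 0.0)


def normalize_ncounter(
    raw: ExpressionMatrix,
    background_policy: str = "mean",
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Run the four-step nCounter normalization chain.

    Returns the log2 matrix of endogenous probes only, plus a per-sample
    report.  Hard errors: zero positive-control geomean, or a sample whose
    reference-gene geometric mean is zero after background subtraction.
    """
    if raw.platform != "ncounter-raw":
        raise ValueError(f"expected platform 'ncounter-raw', got {raw.platform!r}")
    if background_policy not in BACKGROUND_POLICIES:
        raise ValueError(f"unknown background policy {background_policy!r}")
    pos = raw.genes_with_role("positive-control")
    neg = raw.genes_with_role("negative-control")
    ref = raw.genes_with_role("reference")
    endo = raw.genes_with_role("endogenous")
    for role, genes in (("positive-control", pos), ("negative-control", neg),
                        ("reference", ref)):
        if not genes:
            raise ValueError(f"no {role} probes present")

    values = raw.values.to_numpy(dtype=float).copy()
    samples = raw.sample_ids
    gene_pos = raw.values.index.get_indexer(pos)
    gene_neg = raw.values.index.get_indexer(neg)
    gene_ref = raw.values.index.get_indexer(ref)

    # step 1: positive-control scaling
    pos_geomeans = _geomean(values[gene_pos, :], axis=0)
    if (pos_geomeans == 0).any():
        bad = [samples[j] for j in np.nonzero(pos_geomeans == 0)[0]]
        raise ValueError(f"zero positive-control geometric mean for sample(s) {bad}")
    pos_target = _geomean(pos_geomeans)
    pos_factor = pos_target / pos_geomeans
    values = values * pos_factor[None, :]

    # step 2: background subtraction from negative controls
    negs = values[gene_neg, :]
    if background_policy == "mean":
        background = negs.mean(axis=0)
    elif background_policy == "mean_2sd":
        background = negs.mean(axis=0) + 2 * negs.std(axis=0, ddof=1)
    else:
        background = negs.max(axis=0)
    values = np.maximum(values - background[None, :], 0.0)

    # step 3: reference-gene (housekeeping) scaling on the subtracted counts
    ref_geomeans = _geomean(values[gene_ref, :], axis=0)
    if (ref_geomeans == 0).any() or np.isnan(ref_geomeans).any():
        bad = [samples[j] for j in np.nonzero(~(ref_geomeans > 0))[0]]
        raise ValueError(
            f"reference-gene geometric mean is zero after background "
            f"subtraction for sample(s) {bad}"
        )
    ref_target = _geomean(ref_geomeans)
    ref_factor = ref_target / ref_geomeans
    values = values * ref_factor[None, :]

    # step 4: log2 with unit pseudocount, endogenous probes only
    gene_endo = raw.values.index.get_indexer(endo)
    log2_values = np.log2(values[gene_endo, :] + 1.0)

    out = ExpressionMatrix(
        values=pd.DataFrame(log2_values, index=endo, columns=samples),
        platform="ncounter-normalized",
        gene_roles={g: "endogenous" for g in endo},
    )
    factors = pd.DataFrame({"p": pos_factor, "r": ref_factor}, index=samples)
    flags = ((factors < 0.3) | (factors > 3.0)).any(axis=1)
    report = NormalizationReport(
        positive_factor=pd.Series(pos_factor, index=samples),
        background=pd.Series(background, index=samples),
        reference_factor=pd.Series(ref_factor, index=samples),
        flags=flags,
        background_policy=background_policy,
    )
    return out, report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization across samples.

    After normalization every sample's sorted value vector equals the
    across-sample mean of order statistics.  Ties within a sample receive
    the mean of the quantile values their positions span, which keeps the
    transform deterministic and rank-preserving up to ties.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not supported")
    n_genes, n_samples = values.shape
    mean_order_stats = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = mean_order_stats.copy()
        # tie groups share the mean of the quantile values they span
        sorted_col = col[order]
        i = 0
        while i < n_genes:
            k = i
            while k + 1 < n_genes and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[i:k + 1] = mean_order_stats[i:k + 1].mean()
            i = k + 1
        out[order, j] = ranked
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.values.index,
                            columns=matrix.values.columns),
        platform=matrix.platform,
        gene_roles=dict(matrix.gene_roles),
    )
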