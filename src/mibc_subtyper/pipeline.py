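"""End-to-end orchestration: simulate -> normalize -> consensus -> subtype
-> survival -> associations -> drug targets -> GSEA.

A single :class:`RunConfig` (optionally loaded from YAML) drives the run.
Every stage draws its randomness from a seed derived as
``crc32(f"{seed}:{stage}") % 2**31`` so inserting a stage never perturbs
the streams of the others, and re-running the same config reproduces all
outputs byte for byte (the report carries no timestamps).  Intermediate
artifacts are persisted as TSV/JSON in the output directory; logs go to
stderr only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus_panel import intersect_cohorts, label_clusters, cluster_genes
from .group_tests import ContingencyTable, fisher_exact_rxc, kruskal_wallis, \
    drug_target_screen
from .gsea_lite import gsea_test
from .io_formats import write_clinical, write_counts, write_json
from .normalization import normalize_ncounter, quantile_normalize
from .subtype_caller import call_subtypes, fit_centroids, predict_subtypes
from .survival_stats import cox_fit, km_by_group, logrank_test, \
    stratify_luminal
from .synthetic_cohort import (
    SUBTYPES,
    SimulationConfig,
    default_panel,
    generate_multicohort,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "consensus", "subtype", "survival",
          "assoc", "targets", "gsea")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % 2**31


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic run."""

    seed: int = 0
    out_dir: str = "mibc_run"
    cohort_sizes: tuple[int, ...] = (47, 58, 61, 51)
    cohort_platforms: tuple[str, ...] = ("ncounter-raw", "log2-array",
                                         "log2-array", "log2-array")
    k: int = 3
    background_policy: str = "mean"
    endpoints: tuple[str, ...] = ("DSS",)
    covariates: tuple[str, ...] = ("luminal", "stage", "node", "ac")
    selection: str = "forward"
    gsea_n_perm: int = 500
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != len(self.cohort_platforms):
            raise ValueError("cohort_sizes and cohort_platforms differ in length")
        if len(self.cohort_sizes) < 2:
            raise ValueError("pipeline needs at least 2 cohorts")
        for endpoint in self.endpoints:
            if endpoint not in ("OS", "DSS"):
                raise ValueError(f"unknown endpoint {endpoint!r}")
        # fail fast on bad simulation overrides, before any stage runs
        SimulationConfig(**self.simulation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("cohort_sizes", "cohort_platforms", "endpoints",
                    "covariates"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
        "warnings": [],
    }

    # -- simulate ----------------------------------------------------------
    sim_seed = stage_seed(config.seed, "simulate")
    panel = default_panel()
    configs = [
        SimulationConfig(n_samples=n, platform=p, seed=sim_seed + j,
                         **config.simulation)
        for j, (n, p) in enumerate(zip(config.cohort_sizes,
                                       config.cohort_platforms))
    ]
    cohorts = generate_multicohort(configs, panel=panel)
    for j, cohort in enumerate(cohorts):
        write_counts(cohort.expression, out / f"cohort{j + 1}_expression.tsv")
        write_clinical(cohort.clinical, out / f"cohort{j + 1}_clinical.tsv")
        cohort.truth.rename("subtype").to_csv(out / f"cohort{j + 1}_truth.tsv",
                                              sep="\t")
    report["stages"]["simulate"] = {
        "n_cohorts": len(cohorts),
        "cohort_sizes": [c.expression.n_samples for c in cohorts],
    }

    # -- normalize ---------------------------------------------------------
    normalized = []
    norm_info = []
    for j, cohort in enumerate(cohorts):
        if cohort.expression.platform == "ncounter-raw":
            norm, rep = normalize_ncounter(
                cohort.expression, background_policy=config.background_policy)
            rep.to_frame().to_csv(out / f"cohort{j + 1}_norm_report.tsv",
                                  sep="\t")
            norm_info.append({"platform": "ncounter-raw",
                              "flagged": int(rep.flags.sum())})
        else:
            norm = quantile_normalize(cohort.expression)
            norm_info.append({"platform": "log2-array", "flagged": 0})
        write_counts(norm, out / f"cohort{j + 1}_normalized.tsv")
        normalized.append(norm)
    report["stages"]["normalize"] = norm_info

    # -- consensus ---------------------------------------------------------
    labeled = []
    for j, norm in enumerate(normalized):
        genes = [g for g in panel.subtyping_genes if g in norm.values.index]
        clusters, z = cluster_genes(norm, genes, k=config.k)
        labeled.append(label_clusters(clusters, panel.seed_sets(),
                                      cohort_id=f"cohort{j + 1}",
                                      linkage_matrix=z))
    consensus = intersect_cohorts(labeled)
    consensus.to_json(out / "consensus_panel.json")
    consensus.provenance.to_csv(out / "consensus_membership.tsv", sep="\t")
    report["stages"]["consensus"] = {
        "sizes": consensus.sizes(),
        "n_unstable": len(consensus.unstable_genes),
    }

    # -- subtype -----------------------------------------------------------
    assignment = call_subtypes(normalized[0], consensus, k=config.k)
    assignment.to_frame().to_csv(out / "subtypes.tsv", sep="\t")
    centroids = fit_centroids(normalized[0], assignment, consensus)
    centroids.to_json(out / "centroids.json")
    predicted = predict_subtypes(normalized[1], centroids, consensus=consensus)
    predicted.to_frame().to_csv(out / "subtypes_predicted_cohort2.tsv",
                                sep="\t")
    report["stages"]["subtype"] = {
        "counts": assignment.counts(),
        "predicted_counts": predicted.counts(),
    }

    # -- survival ----------------------------------------------------------
    clinical = cohorts[0].clinical
    luminal = stratify_luminal(assignment)
    surv_report = {}
    km_frames = []
    for endpoint in config.endpoints:
        tcol, ecol = (("os_time", "os_event") if endpoint == "OS"
                      else ("dss_time", "dss_event"))
        df = clinical.data.set_index("sample_id")
        times = df[tcol].astype(float).to_numpy()
        events = df[ecol].astype(bool).to_numpy()
        groups = assignment.subtypes.reindex(df.index).to_numpy()
        curves = km_by_group(times, events, groups)
        for curve in curves.values():
            frame = curve.to_frame()
            frame.insert(0, "endpoint", endpoint)
            km_frames.append(frame)
        chi2, df_lr, p_lr = logrank_test(
            [(times[groups == s], events[groups == s]) for s in SUBTYPES]
        )
        cox = cox_fit(clinical, config.covariates, endpoint=endpoint,
                      selection=config.selection, luminal=luminal)
        cox.summary.to_csv(out / f"cox_{endpoint.lower()}.tsv", sep="\t")
        surv_report[endpoint] = {
            "logrank_chi2": chi2,
            "logrank_df": df_lr,
            "logrank_p": p_lr,
            "cox_selected": list(cox.summary.index),
            "cox_hr": {c: cox.hazard_ratio(c) for c in cox.summary.index},
            "survival_96mo_by_subtype": {
                s: curves[s].survival_at(96.0) for s in curves
            },
        }
    pd.concat(km_frames, ignore_index=True).to_csv(out / "km_curves.tsv",
                                                   sep="\t", index=False)
    report["stages"]["survival"] = surv_report

    # -- associations (clinical table layout) ------------------------------
    df = clinical.data.set_index("sample_id")
    subtype_of = assignment.subtypes.reindex(df.index)
    assoc_rows = []
    for name, indicator in (
        ("sex_female", df["sex"] == "F"),
        ("node_positive", df["node"] == "N+"),
        ("metastasis_positive", df["metastasis"] == "M+"),
    ):
        table = _two_by_k(indicator, subtype_of)
        if table is not None:
            res = fisher_exact_rxc(table)
            assoc_rows.append({"variable": name, "test": res.test, "p": res.p})
    stage_counts = pd.crosstab(df["stage"], subtype_of)
    if (stage_counts.to_numpy().sum(axis=1) > 0).all() and stage_counts.shape[0] >= 2:
        res = fisher_exact_rxc(stage_counts.to_numpy())
        assoc_rows.append({"variable": "stage", "test": res.test, "p": res.p})
    age_groups = [df.loc[subtype_of == s, "age"].dropna().astype(float)
                  for s in SUBTYPES]
    res = kruskal_wallis(age_groups)
    assoc_rows.append({"variable": "age", "test": res.test, "p": res.p})
    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    report["stages"]["assoc"] = assoc.to_dict(orient="records")

    # -- drug targets ------------------------------------------------------
    screen = drug_target_screen(normalized[0], assignment,
                                sorted(panel.drug_targets),
                                subtyping_genes=consensus.genes)
    screen.to_csv(out / "drug_targets.tsv", sep="\t")
    report["stages"]["targets"] = {
        "n_significant": int((screen["p"] < 0.05).sum()),
        "directions": screen["direction"].to_dict(),
    }

    # -- GSEA --------------------------------------------------------------
    gsea_seed = stage_seed(config.seed, "gsea")
    phenotype = (predicted.subtypes == "infiltrated")
    gsea = gsea_test(normalized[1], phenotype, panel.immune_genes,
                     set_name="immune_infiltration",
                     n_perm=config.gsea_n_perm, seed=gsea_seed)
    report["stages"]["gsea"] = {
        "set": gsea.set_name, "es": gsea.es, "nes": gsea.nes,
        "p": gsea.p, "fdr_q": gsea.fdr_q, "n_perm": gsea.n_perm,
    }

    write_json(report, out / "run_report.json")
    return report


def _two_by_k(indicator: pd.Series, subtype_of: pd.Series):
    """2 x k table (indicator yes/no by subtype) or None if degenerate."""
    tab = pd.crosstab(indicator, subtype_of)
    if tab.shape[0] < 2:
        return None
    arr = tab.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return None
    return arr
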