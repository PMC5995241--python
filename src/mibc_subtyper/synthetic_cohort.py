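"""Synthetic MIBC cohort generator.

Emulates the statistical structure the subtyping analysis assumes: three
latent tumor subtypes (luminal, basal, infiltrated) with block-structured
marker expression, nCounter-style probe chemistry (housekeeping reference
genes, a positive-control spike-in ladder, low-count negative controls),
drug-target genes with subtype-specific shifts, an immune-infiltration
signal confined to infiltrated tumors, and subtype-dependent survival with
administrative plus random censoring.

Counts are drawn from a gamma-Poisson (negative-binomial) model because
digital counting data are overdispersed relative to Poisson.  Survival
times are exponential per subtype so that the Cox hazard ratio has a known
truth for parameter-recovery tests.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GenePanel,
    SUBTYPE_LABELS,
    STAGES,
)

SUBTYPES = ("luminal", "basal", "infiltrated")

#: signature label carried by the marker genes of each tumor subtype
SUBTYPE_TO_LABEL = {"luminal": "luminal", "basal": "basal", "infiltrated": "p53-like"}
LABEL_TO_SUBTYPE = {v: k for k, v in SUBTYPE_TO_LABEL.items()}

#: nCounter positive-control spike-in ladder (expected counts, 4-fold steps)
POSITIVE_LADDER = (32768.0, 8192.0, 2048.0, 512.0, 128.0, 32.0)

REFERENCE_GENES = ("CALM2", "RPL37A", "B2M", "TUBB", "GAPDH", "G6PD")

# --- the curated 64-gene subtyping panel -----------------------------------
# 36 genes with a stable one-subtype block pattern (16 basal / 8 luminal /
# 12 p53-like) and 28 genes planted as cross-cohort unstable, among them the
# late-cell-cycle genes shared by the basal/luminal axis.

_BASAL_STABLE = (
    "KRT5", "KRT14", "KRT6A", "KRT6B", "KRT16", "CD44", "CDH3", "DSC3",
    "DSG3", "PI3", "TGM1", "SERPINB3", "SERPINB4", "COL17A1", "GSDMC", "KRT1",
)
_LUMINAL_STABLE = (
    "KRT20", "UPK2", "UPK1A", "UPK1B", "PPARG", "FGFR3", "CD24", "FOXA1",
)
_P53_STABLE = (
    "FAS", "NCAM1", "CCL2", "CD14", "MDM4", "CDK6", "CDKN1A",
    "PDGFRA", "DES", "CNN1", "MYH11", "ACTC1",
)

LATE_CELL_CYCLE = ("AURKA", "AURKB", "CCNB1", "CCNA2", "MAD2L1")

# planted-unstable remainder of the 64-gene panel, with base labels used
# only as the anchor for the deterministic per-cohort label rotation
_UNSTABLE_BASE = {
    # basal-anchored (12)
    "AURKA": "basal", "AURKB": "basal", "CCNB1": "basal", "CCNA2": "basal",
    "MAD2L1": "basal", "TP63": "basal", "MKI67": "basal", "TOP2A": "basal",
    "EZH2": "basal", "BIRC5": "basal", "CDKN2A": "basal", "E2F3": "basal",
    # luminal-anchored (6)
    "GATA3": "luminal", "ERBB3": "luminal", "CDH1": "luminal",
    "KRT8": "luminal", "KRT18": "luminal", "CCND1": "luminal",
    # p53-like-anchored (10)
    "VIM": "p53-like", "ZEB1": "p53-like", "ZEB2": "p53-like",
    "SNAI2": "p53-like", "TWIST1": "p53-like", "ACTA2": "p53-like",
    "PGM5": "p53-like", "THBS1": "p53-like", "RB1": "p53-like",
    "FBXW7": "p53-like",
}

#: drug targets with their simulated subtype attribution (log2 shift in
#: that subtype; negative = suppressed there).  Zero-effect targets are
#: carried so the screen also sees honest nulls.
DRUG_TARGET_EFFECTS: dict[str, tuple[str, float]] = {
    "ERBB2": ("luminal", 2.5),
    "FGFR2": ("luminal", 1.5),
    "FGFR1": ("infiltrated", 2.0),
    "PDGFRB": ("infiltrated", 2.0),
    "AR": ("basal", -2.0),
    "ESR2": ("basal", -1.2),
    "CLDN3": ("basal", -1.5),
    "CLDN4": ("basal", -1.5),
    "CLDN7": ("basal", -1.5),
    "EGFR": ("luminal", 0.0),
    "ERBB4": ("luminal", 0.0),
    "FGFR4": ("luminal", 0.0),
    "ESR1": ("luminal", 0.0),
    "PGR": ("luminal", 0.0),
}

IMMUNE_GENES = (
    "PTPRC", "CD3E", "CD4", "CD8A", "CD19", "MS4A1", "CD68", "ITGAM",
    "TLR4", "IL6", "TNF", "IFNG", "CXCL9", "CXCL10", "CCL5", "CCR7",
    "FOXP3", "GZMB", "PRF1", "LCK",
)

N_BACKGROUND = 40  # unregulated filler genes for ranking/GSEA universes


def default_panel() -> GenePanel:
    """The default simulated nCounter panel.

    64 subtyping genes (36 stable: 16 basal / 8 luminal / 12 p53-like, plus
    28 planted-unstable including the late-cell-cycle axis), 6 housekeeping
    reference genes, 6 positive and 8 negative control probes, 14 drug
    targets kept out of the subtyping set, and an immune signature block.
    """
    subtyping: dict[str, str] = {}
    for g in _BASAL_STABLE:
        subtyping[g] = "basal"
    for g in _LUMINAL_STABLE:
        subtyping[g] = "luminal"
    for g in _P53_STABLE:
        subtyping[g] = "p53-like"
    subtyping.update(_UNSTABLE_BASE)

    roles: dict[str, str] = {}
    for g in subtyping:
        roles[g] = "endogenous"
    for g in DRUG_TARGET_EFFECTS:
        roles[g] = "endogenous"
    for g in IMMUNE_GENES:
        roles[g] = "endogenous"
    for i in range(N_BACKGROUND):
        roles[f"BG{i + 1:03d}"] = "endogenous"
    for g in REFERENCE_GENES:
        roles[g] = "reference"
    for i in range(6):
        roles[f"POS_{chr(65 + i)}"] = "positive-control"
    for i in range(8):
        roles[f"NEG_{chr(65 + i)}"] = "negative-control"

    seed_labels = {
        "KRT5": "basal", "KRT14": "basal", "CD44": "basal",
        "KRT20": "luminal", "UPK2": "luminal", "PPARG": "luminal",
        "FGFR3": "luminal", "CD24": "luminal",
        "FAS": "p53-like", "NCAM1": "p53-like", "CCL2": "p53-like",
        "CD14": "p53-like", "MDM4": "p53-like", "CDK6": "p53-like",
        "CDKN1A": "p53-like",
    }
    return GenePanel(
        roles=roles,
        subtyping_labels=subtyping,
        seed_labels=seed_labels,
        shared_axis_genes=set(LATE_CELL_CYCLE),
        drug_targets=set(DRUG_TARGET_EFFECTS),
        drug_target_effects=dict(DRUG_TARGET_EFFECTS),
        immune_genes=set(IMMUNE_GENES),
        unstable_genes=set(_UNSTABLE_BASE),
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference cohort: subtype proportions 9/47 luminal,
    13/47 basal, 25/47 infiltrated; a five-fold disease-specific hazard for
    luminal tumors; 4-fold (log2 effect 2) marker elevation.
    """

    n_samples: int = 47
    subtype_proportions: tuple[float, float, float] = (9 / 47, 13 / 47, 25 / 47)
    marker_effect: float = 2.0
    drug_target_effects: Mapping[str, tuple[str, float]] | None = None
    infiltration_effect: float = 1.5
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.4)
    baseline_hazard: float = 0.0033      # disease-specific deaths / month
                                         # (infiltrated 8-year DSS ~ 73%)
    other_cause_hazard: float = 0.002
    subtype_hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"luminal": 5.0, "basal": 2.0, "infiltrated": 1.0}
    )
    censoring_rate: float = 0.004        # random censorings / month
    followup_cap: float = 120.0          # administrative censoring, months
    background_count: float = 2.0        # additive ambient counts per probe
    array_noise_sd: float = 0.5          # log2 noise for the array platform
    platform: str = "ncounter-raw"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.platform not in ("ncounter-raw", "log2-array"):
            raise ValueError(f"unsupported platform {self.platform!r}")
        for name in ("marker_effect", "infiltration_effect", "dispersion",
                     "baseline_hazard", "censoring_rate", "followup_cap"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: pd.Series                     # sample_id -> true subtype
    panel: GenePanel

    def __post_init__(self) -> None:
        samples = set(self.expression.sample_ids)
        if set(self.truth.index) != samples:
            raise ValueError("truth labels must cover exactly the cohort samples")


def _base_log2_mean(gene: str) -> float:
    """Deterministic per-gene baseline abundance, shared across cohorts."""
    h = zlib.crc32(gene.encode()) % 10_000 / 10_000
    return 5.0 + 4.0 * h  # log2 counts in [5, 9]


def _expected_means(panel: GenePanel, subtypes: np.ndarray,
                    config: SimulationConfig,
                    label_overrides: Mapping[str, str] | None) -> pd.DataFrame:
    """Noise-free expected expression (linear scale) per gene and sample."""
    overrides = dict(label_overrides or {})
    target_effects = dict(config.drug_target_effects
                          if config.drug_target_effects is not None
                          else panel.drug_target_effects)
    genes = [g for g, r in panel.roles.items() if r in ("endogenous", "reference")]
    mat = np.empty((len(genes), len(subtypes)))
    for i, g in enumerate(genes):
        base = 2.0 ** _base_log2_mean(g)
        shift = np.zeros(len(subtypes))
        if g in panel.subtyping_labels:
            if g in overrides:
                lab = overrides[g]
                shift += config.marker_effect * (
                    subtypes == LABEL_TO_SUBTYPE[lab]
                )
            elif g in panel.shared_axis_genes:
                shift += config.marker_effect * np.isin(
                    subtypes, ("basal", "luminal")
                )
            else:
                lab = panel.subtyping_labels[g]
                shift += config.marker_effect * (
                    subtypes == LABEL_TO_SUBTYPE[lab]
                )
        if g in target_effects:
            sub, eff = target_effects[g]
            shift += eff * (subtypes == sub)
        if g in panel.immune_genes:
            shift += config.infiltration_effect * (subtypes == "infiltrated")
        mat[i] = base * 2.0 ** shift
    return pd.DataFrame(mat, index=genes)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam).astype(float)


def generate_cohort(config: SimulationConfig, panel: GenePanel | None = None,
                    label_overrides: Mapping[str, str] | None = None,
                    sample_prefix: str = "S") -> SyntheticCohort:
    """Draw one cohort (expression + clinical + truth) from the model.

    ``label_overrides`` reassigns the signature label of individual
    subtyping genes for this cohort only; :func:`generate_multicohort` uses
    it to plant cross-cohort-unstable genes.
    """
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    props = np.asarray(config.subtype_proportions, dtype=float)
    if (n * props < 3).any():
        raise ValueError(
            "n_samples too small: every subtype needs an expected count >= 3"
        )
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]
    subtypes = rng.choice(SUBTYPES, size=n, p=props)

    means = _expected_means(panel, subtypes, config, label_overrides)
    lib = rng.uniform(*config.library_size_range, size=n)

    if config.platform == "ncounter-raw":
        genes = (
            list(means.index)
            + [f"POS_{chr(65 + i)}" for i in range(6)]
            + [f"NEG_{chr(65 + i)}" for i in range(8)]
        )
        values = np.empty((len(genes), n))
        n_main = means.shape[0]
        for j in range(n):
            mu = means.iloc[:, j].to_numpy() * lib[j] + config.background_count
            values[:n_main, j] = _nb_counts(rng, mu, config.dispersion)
            # spike-ins are technical controls: Poisson counting noise only
            pos_mu = np.asarray(POSITIVE_LADDER) * lib[j]
            values[n_main:n_main + 6, j] = rng.poisson(pos_mu)
            values[n_main + 6:, j] = rng.poisson(config.background_count, size=8)
        matrix = ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=sample_ids),
            platform="ncounter-raw",
            gene_roles={g: panel.roles[g] for g in genes},
        )
    else:  # log2-array: endogenous + reference probes only, log2 intensities
        offset = rng.normal(0.0, 0.3, size=n)
        noise = rng.normal(0.0, config.array_noise_sd, size=means.shape)
        values = np.log2(means.to_numpy()) + noise + offset[None, :]
        matrix = ExpressionMatrix(
            values=pd.DataFrame(values, index=list(means.index),
                                columns=sample_ids),
            platform="log2-array",
            gene_roles={g: panel.roles[g] for g in means.index},
        )

    clinical = _simulate_clinical(rng, sample_ids, subtypes, config)
    truth = pd.Series(subtypes, index=sample_ids, name="subtype")
    return SyntheticCohort(expression=matrix, clinical=clinical,
                           truth=truth, panel=panel)


def _simulate_clinical(rng: np.random.Generator, sample_ids: list[str],
                       subtypes: np.ndarray,
                       config: SimulationConfig) -> ClinicalTable:
    n = len(sample_ids)
    hr = np.array([config.subtype_hazard_ratios[s] for s in subtypes])
    h_dss = config.baseline_hazard * hr
    t_disease = rng.exponential(1.0 / h_dss)
    t_other = (rng.exponential(1.0 / config.other_cause_hazard, size=n)
               if config.other_cause_hazard > 0 else np.full(n, np.inf))
    t_censor = (rng.exponential(1.0 / config.censoring_rate, size=n)
                if config.censoring_rate > 0 else np.full(n, np.inf))
    t_censor = np.minimum(t_censor, config.followup_cap)
    t_death = np.minimum(t_disease, t_other)
    os_time = np.minimum(t_death, t_censor)
    os_event = t_death <= t_censor
    dss_event = t_disease <= np.minimum(t_other, t_censor)

    # covariates deliberately independent of subtype: the reference cohort's
    # clinical table shows no significant subtype association
    age = np.round(rng.normal(67, 10, size=n)).clip(30, 95)
    sex = rng.choice(["F", "M"], size=n, p=[13 / 47, 34 / 47])
    stage = rng.choice(list(STAGES), size=n, p=[3 / 47, 11 / 47, 26 / 47, 7 / 47])
    node = rng.choice(["N+", "N0"], size=n, p=[17 / 47, 30 / 47])
    metastasis = rng.choice(["M+", "M0"], size=n, p=[8 / 47, 39 / 47])
    nac = rng.random(n) < 1 / 47
    ac = rng.random(n) < 7 / 47
    df = pd.DataFrame({
        "sample_id": sample_ids,
        "age": pd.array(age, dtype="Float64"),
        "sex": sex,
        "stage": stage,
        "node": node,
        "metastasis": metastasis,
        "nac": pd.array(nac, dtype="boolean"),
        "ac": pd.array(ac, dtype="boolean"),
        "os_time": pd.array(os_time, dtype="Float64"),
        "os_event": pd.array(os_event, dtype="boolean"),
        "dss_time": pd.array(os_time, dtype="Float64"),
        "dss_event": pd.array(dss_event, dtype="boolean"),
    })
    return ClinicalTable(data=df)


def rotated_label(base: str, cohort_index: int) -> str:
    """Deterministic per-cohort label rotation for planted-unstable genes."""
    i = SUBTYPE_LABELS.index(base)
    return SUBTYPE_LABELS[(i + cohort_index) % 3]


def generate_multicohort(configs: Sequence[SimulationConfig],
                         panel: GenePanel | None = None,
                         unstable_genes: set[str] | None = None,
                         ) -> list[SyntheticCohort]:
    """Generate >=2 cohorts sharing the stable signature structure.

    Planted-unstable genes carry a deterministically rotated signature label
    in each cohort (rotation by the cohort index), so with >=3 cohorts every
    planted-unstable gene is guaranteed discordant and drops out of the
    cross-cohort consensus, while stable genes keep their label everywhere.
    """
    if len(configs) < 2:
        raise ValueError("multicohort generation needs at least 2 configs")
    if panel is None:
        panel = default_panel()
    if unstable_genes is None:
        unstable_genes = set(panel.unstable_genes)
    unknown = unstable_genes - set(panel.subtyping_labels)
    if unknown:
        raise ValueError(f"unstable genes not in the subtyping panel: {sorted(unknown)}")
    cohorts = []
    for j, cfg in enumerate(configs):
        overrides = {
            g: rotated_label(panel.subtyping_labels[g], j) for g in unstable_genes
        }
        cohorts.append(generate_cohort(cfg, panel=panel, label_overrides=overrides,
                                       sample_prefix=f"C{j + 1}_S"))
    return cohorts


def default_multicohort_configs(seed: int = 0) -> list[SimulationConfig]:
    """Four cohorts at the study's sample sizes and platforms."""
    sizes = [47, 58, 61, 51]           # nCounter cohort + three array cohorts
    platforms = ["ncounter-raw", "log2-array", "log2-array", "log2-array"]
    return [
        SimulationConfig(n_samples=n, platform=p, seed=seed * 1000 + j)
        for j, (n, p) in enumerate(zip(sizes, platforms))
    ]


def truth_consensus_sets(panel: GenePanel) -> dict[str, set[str]]:
    """Planted-stable signature sets (the ground truth the consensus should find)."""
    stable = set(panel.subtyping_labels) - panel.unstable_genes
    out: dict[str, set[str]] = {lab: set() for lab in SUBTYPE_LABELS}
    for g in stable:
        out[panel.subtyping_labels[g]].add(g)
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
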