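"""Readers and writers for every external representation the pipeline touches.

Expression matrices are gene-by-sample (genes in rows, samples in columns,
matching the GEO series-matrix convention) and carry a platform tag plus a
probe role for every gene.  Clinical tables are typed, with missing values
kept explicit (empty string on disk, pandas NA in memory).  Gene sets use
the standard GMT dialect.  Floats are serialized with 6 significant digits
so that write/read round-trips are bitwise stable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("endogenous", "reference", "positive-control", "negative-control")
PLATFORMS = ("ncounter-raw", "ncounter-normalized", "log2-array")
SUBTYPE_LABELS = ("basal", "luminal", "p53-like")
STAGES = ("pTa/pT1/pTis", "pT2", "pT3", "pT4")

#: nCounter CodeClass -> internal probe role
RCC_CODECLASS_MAP = {
    "Endogenous": "endogenous",
    "Housekeeping": "reference",
    "Positive": "positive-control",
    "Negative": "negative-control",
}

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression grid with per-gene probe roles.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index, sample ids as columns.
        Counts (non-negative integers) for platform ``ncounter-raw``,
        arbitrary reals for the log2 platforms.
    platform
        One of ``ncounter-raw``, ``ncounter-normalized``, ``log2-array``.
    gene_roles
        Mapping gene -> role; every gene must have exactly one role in
        {endogenous, reference, positive-control, negative-control}.
    """

    values: pd.DataFrame
    platform: str
    gene_roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate gene id(s): {dups}")
        cols = self.values.columns
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise FormatError(f"duplicate sample id(s): {dups}")
        missing = [g for g in idx if g not in self.gene_roles]
        if missing:
            raise FormatError(f"genes without a probe role: {missing}")
        bad = {g: r for g, r in self.gene_roles.items() if r not in ROLES}
        if bad:
            raise FormatError(f"invalid probe roles: {bad}")
        if self.platform == "ncounter-raw":
            arr = self.values.to_numpy()
            if np.isnan(arr).any() or (arr < 0).any() or (arr != np.floor(arr)).any():
                i, j = np.argwhere(np.isnan(arr) | (arr < 0) | (arr != np.floor(arr)))[0]
                raise FormatError(
                    "platform 'ncounter-raw' requires non-negative integer counts; "
                    f"offending value {arr[i, j]!r} at gene {idx[i]!r}, "
                    f"sample {cols[j]!r}"
                )

    # -- convenience views ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [g for g in self.values.index if self.gene_roles[g] == role]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(
            values=self.values.loc[genes].copy(),
            platform=self.platform,
            gene_roles={g: self.gene_roles[g] for g in genes},
        )

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trips
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.platform == other.platform
            and self.gene_roles == other.gene_roles
            and self.values.equals(other.values)
        )


@dataclass
class ClinicalTable:
    """Typed clinical covariates with explicit missingness.

    Columns: sample_id, age, sex (F/M), stage (pTa/pT1/pTis, pT2, pT3, pT4),
    node (N0/N+), metastasis (M0/M+), nac, ac (booleans), os_time, os_event,
    dss_time, dss_event.  Times are months >= 0; events are booleans.
    Missing cells are pandas NA, never silently dropped.
    """

    data: pd.DataFrame

    COLUMNS = (
        "sample_id", "age", "sex", "stage", "node", "metastasis",
        "nac", "ac", "os_time", "os_event", "dss_time", "dss_event",
    )

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in self.COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"clinical table missing column(s): {missing_cols}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in clinical table")
        for col in ("os_time", "dss_time"):
            vals = df[col].dropna()
            if (vals < 0).any():
                bad = df.loc[df[col] < 0, "sample_id"].tolist()
                raise FormatError(f"negative {col} for sample(s) {bad}")
        for col, allowed in (
            ("sex", {"F", "M"}),
            ("stage", set(STAGES)),
            ("node", {"N0", "N+"}),
            ("metastasis", {"M0", "M+"}),
        ):
            vals = set(df[col].dropna().unique())
            unknown = vals - allowed
            if unknown:
                raise FormatError(f"unknown {col} categories: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GenePanel:
    """The curated nCounter-style panel: probe roles plus subtyping structure.

    ``seed_labels`` names the seed markers anchoring each signature
    (basal / luminal / p53-like); ``subtyping_genes`` is the full clustering
    panel; ``shared_axis_genes`` are late-cell-cycle genes elevated in both
    basal and luminal tumors; ``drug_targets`` are excluded from subtyping.
    """

    roles: dict[str, str]
    subtyping_labels: dict[str, str]          # gene -> planted signature label
    seed_labels: dict[str, str]               # seed marker -> signature label
    shared_axis_genes: set[str] = field(default_factory=set)
    drug_targets: set[str] = field(default_factory=set)
    drug_target_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    immune_genes: set[str] = field(default_factory=set)
    unstable_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {g: r for g, r in self.roles.items() if r not in ROLES}
        if bad:
            raise FormatError(f"invalid probe roles: {bad}")
        overlap = self.drug_targets & set(self.subtyping_labels)
        if overlap:
            raise FormatError(
                f"drug targets may not be subtyping genes: {sorted(overlap)}"
            )
        for g, lab in self.subtyping_labels.items():
            if lab not in SUBTYPE_LABELS:
                raise FormatError(f"bad signature label {lab!r} for gene {g!r}")

    @property
    def subtyping_genes(self) -> list[str]:
        return sorted(self.subtyping_labels)

    @property
    def reference_genes(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "reference")

    def seed_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {lab: set() for lab in SUBTYPE_LABELS}
        for g, lab in self.seed_labels.items():
            out[lab].add(g)
        return out


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, panel: GenePanel | None = None) -> ExpressionMatrix:
    """Read raw nCounter counts from a TSV or RCC-style sectioned file.

    TSV dialect: first column ``gene``, optional second column ``role``,
    remaining columns one per sample.  When the file carries no role column
    a ``panel`` supplying roles is required.  RCC dialect: CodeClass/Name/
    Count columns inside a ``<Code_Summary>`` section (one sample per file).
    """
    path = Path(path)
    text = path.read_text()
    if "<Code_Summary>" in text:
        return _read_rcc(path, text)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    has_role_col = len(df.columns) > 1 and df.columns[1] == "role"
    genes = df["gene"].tolist()
    dup = df["gene"][df["gene"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate gene id(s): {sorted(dup.unique())}")
    if has_role_col:
        roles = dict(zip(genes, df["role"]))
        counts = df.drop(columns=["gene", "role"]).set_axis(genes, axis=0)
    else:
        if panel is None:
            raise FormatError(f"{path}: no role column and no panel supplied")
        missing = [g for g in genes if g not in panel.roles]
        if missing:
            raise FormatError(
                f"{path}: gene(s) absent from panel roles: {missing}"
            )
        roles = {g: panel.roles[g] for g in genes}
        counts = df.drop(columns=["gene"]).set_axis(genes, axis=0)
    _check_counts(counts, path)
    return ExpressionMatrix(values=counts.astype(float), platform="ncounter-raw",
                            gene_roles=roles)


def _check_counts(counts: pd.DataFrame, path: Path) -> None:
    for sample in counts.columns:
        col = pd.to_numeric(counts[sample], errors="coerce")
        bad = col.isna() | (col < 0) | (col != np.floor(col))
        if bad.any():
            gene = counts.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: invalid count {counts.loc[gene, sample]!r} "
                f"for gene {gene!r} in sample {sample!r}"
            )


def _read_rcc(path: Path, text: str) -> ExpressionMatrix:
    """Parse one RCC-style per-sample section file (CodeClass, Name, Count)."""
    lines = text.splitlines()
    try:
        start = lines.index("<Code_Summary>") + 1
        stop = lines.index("</Code_Summary>")
    except ValueError as exc:
        raise FormatError(f"{path}: malformed Code_Summary section") from exc
    sample_id = path.stem
    for ln in lines[:start]:
        if ln.startswith("ID,"):
            sample_id = ln.split(",", 1)[1].strip()
    header = lines[start].split(",")
    if header[:3] != ["CodeClass", "Name", "Count"]:
        raise FormatError(f"{path}: expected CodeClass,Name,Count header")
    genes, roles, counts = [], {}, []
    for ln in lines[start + 1 : stop]:
        if not ln.strip():
            continue
        code_class, name, count = ln.split(",")[:3]
        if code_class not in RCC_CODECLASS_MAP:
            raise FormatError(f"{path}: unknown CodeClass {code_class!r}")
        if name in roles:
            raise FormatError(f"{path}: duplicate gene id(s): ['{name}']")
        val = float(count)
        if val < 0 or val != math.floor(val):
            raise FormatError(
                f"{path}: invalid count {count!r} for gene {name!r} "
                f"in sample {sample_id!r}"
            )
        genes.append(name)
        roles[name] = RCC_CODECLASS_MAP[code_class]
        counts.append(val)
    values = pd.DataFrame({sample_id: counts}, index=genes)
    return ExpressionMatrix(values=values, platform="ncounter-raw", gene_roles=roles)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as gene/role/sample TSV."""
    df = matrix.values.copy()
    df.insert(0, "role", [matrix.gene_roles[g] for g in df.index])
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression(path: str | Path, platform: str = "log2-array") -> ExpressionMatrix:
    """Read a log2 expression TSV written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if "role" in df.columns:
        roles = dict(df["role"])
        df = df.drop(columns=["role"])
    else:
        roles = {g: "endogenous" for g in df.index}
    return ExpressionMatrix(values=df.astype(float), platform=platform,
                            gene_roles=roles)


# ---------------------------------------------------------------------------
# Clinical I/O
# ---------------------------------------------------------------------------

_CLINICAL_DTYPES = {
    "age": "Float64", "os_time": "Float64", "dss_time": "Float64",
    "nac": "boolean", "ac": "boolean", "os_event": "boolean",
    "dss_event": "boolean",
}


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; empty cells become explicit missing values."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    for col, dtype in _CLINICAL_DTYPES.items():
        if col in df.columns:
            if dtype == "boolean":
                df[col] = df[col].map(
                    {"True": True, "False": False, "1": True, "0": False, pd.NA: pd.NA}
                ).astype("boolean")
            else:
                df[col] = pd.array(
                    [float(v) if v is not pd.NA else pd.NA for v in df[col]],
                    dtype="Float64",
                )
    return ClinicalTable(data=df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.copy()
    for col in ("nac", "ac", "os_event", "dss_event"):
        df[col] = df[col].map({True: "True", False: "False", pd.NA: ""})
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members``.

    Duplicate members within a line are de-duplicated with a logged warning;
    a line with fewer than 3 fields is a hard error naming the line.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("GMT set %s: %d duplicate member(s) removed",
                               name, len(members) - len(unique))
            sets[name] = set(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Panel + JSON helpers
# ---------------------------------------------------------------------------


def write_panel(panel: GenePanel, path: str | Path) -> None:
    payload = {
        "roles": panel.roles,
        "subtyping_labels": panel.subtyping_labels,
        "seed_labels": panel.seed_labels,
        "shared_axis_genes": sorted(panel.shared_axis_genes),
        "drug_targets": sorted(panel.drug_targets),
        "drug_target_effects": {
            g: [s, e] for g, (s, e) in panel.drug_target_effects.items()
        },
        "immune_genes": sorted(panel.immune_genes),
        "unstable_genes": sorted(panel.unstable_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_panel(path: str | Path) -> GenePanel:
    payload = json.loads(Path(path).read_text())
    return GenePanel(
        roles=payload["roles"],
        subtyping_labels=payload["subtyping_labels"],
        seed_labels=payload["seed_labels"],
        shared_axis_genes=set(payload.get("shared_axis_genes", [])),
        drug_targets=set(payload.get("drug_targets", [])),
        drug_target_effects={
            g: (s, float(e))
            for g, (s, e) in payload.get("drug_target_effects", {}).items()
        },
        immune_genes=set(payload.get("immune_genes", [])),
        unstable_genes=set(payload.get("unstable_genes", [])),
    )


def write_json(payload: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
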