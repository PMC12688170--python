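"""Readers, writers and the shared multi-omics cohort container.

All tabular formats are plain text (TSV/CSV/GMT) with a header row. Expression
files follow the GCT orientation convention: genes in rows, samples in
columns. Gene identifiers are opaque strings; no symbol mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("leukotype")

VALID_GENE_CLASSES = frozenset({"mRNA", "lncRNA", "other"})
VALID_EFFECTS = frozenset({"nonsense", "missense", "silent", "other"})
VALID_CGI_CLASSES = frozenset({"island", "shore", "shelf", "openSea"})
VALID_REGION_FLAGS = frozenset({"promoter", "enhancer", "gene_body", "UTR"})

MUTATION_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "context", "effect", "vaf",
]
#: MAF-lite header names as they appear on disk, mapped to internal names.
MAF_LITE_COLUMNS = {
    "Sample": "sample_id", "Hugo_Symbol": "gene", "Chromosome": "chrom",
    "Position": "pos", "Ref": "ref", "Alt": "alt", "Context": "context",
    "Effect": "effect", "VAF": "vaf",
}


class CohortError(ValueError):
    """Raised when an input file or layer combination violates a contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene × sample expression (TPM or log2(TPM+1)) with gene-class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Nonnegative.
    gene_class
        Series mapping every gene id to ``mRNA``/``lncRNA``/``other``.
    log_transformed
        Whether ``values`` already hold ``log2(TPM + 1)``.
    """

    values: pd.DataFrame
    gene_class: pd.Series
    log_transformed: bool = False

    def __post_init__(self) -> None:
        dup_g = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_g):
            raise CohortError(f"duplicate gene ids: {list(dup_g)}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise CohortError(f"duplicate sample ids: {list(dup_s)}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise CohortError("expression contains missing values")
        neg = np.argwhere(arr < 0)
        if len(neg):
            i, j = neg[0]
            raise CohortError(
                f"negative expression at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        self.gene_class = self.gene_class.reindex(self.values.index)
        if self.gene_class.isna().any():
            missing = self.gene_class.index[self.gene_class.isna()]
            raise CohortError(f"gene_class missing for: {list(missing[:5])}")
        bad = set(self.gene_class.unique()) - VALID_GENE_CLASSES
        if bad:
            raise CohortError(f"unknown gene classes: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> "ExpressionMatrix":
        """Return a log2(TPM+1)-scale copy (identity if already transformed)."""
        if self.log_transformed:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), self.gene_class, True)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.gene_class, self.log_transformed
        )


@dataclass
class MutationTable:
    """Long-format somatic SNV records (one row per sample × variant)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise CohortError(f"mutation table missing columns: {missing}")
        r = self.records
        if len(r):
            vaf = r["vaf"].to_numpy(float)
            if ((vaf <= 0) | (vaf > 1)).any():
                bad = r.index[(vaf <= 0) | (vaf > 1)][0]
                raise CohortError(f"vaf outside (0, 1] at record {bad}")
            same = r["ref"] == r["alt"]
            if same.any():
                raise CohortError(
                    f"ref equals alt at record {r.index[same][0]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def genes_by_sample(self) -> pd.DataFrame:
        """Binary gene × sample mutation indicator (observed samples only)."""
        if not len(self.records):
            return pd.DataFrame(dtype=int)
        return (
            pd.crosstab(self.records["gene"], self.records["sample_id"])
            .gt(0).astype(int)
        )


@dataclass
class MethylationMatrix:
    """Probe × sample β values in [0, 1] with tumor/normal sample groups."""

    beta: pd.DataFrame
    sample_group: pd.Series  # sample_id -> {"tumor", "normal"}

    def __post_init__(self) -> None:
        arr = self.beta.to_numpy(float)
        if np.isnan(arr).any():
            raise CohortError("missing β values are not allowed")
        if (arr < 0).any() or (arr > 1).any():
            raise CohortError("β values must lie in [0, 1]")
        self.sample_group = self.sample_group.reindex(self.beta.columns)
        if self.sample_group.isna().any():
            missing = self.sample_group.index[self.sample_group.isna()]
            raise CohortError(f"samples without group label: {list(missing)}")
        bad = set(self.sample_group.unique()) - {"tumor", "normal"}
        if bad:
            raise CohortError(f"unknown sample groups: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def tumor_samples(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == "tumor"])

    def normal_samples(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == "normal"])


@dataclass
class ProbeAnnotation:
    """Per-probe CpG-island class and genomic region flags.

    ``table`` is indexed by probe id with a ``cgi_class`` column and one
    boolean column per region flag. Probes without annotation are simply
    absent (never defaulted).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "cgi_class" not in self.table.columns:
            raise CohortError("probe annotation needs a cgi_class column")
        bad = set(self.table["cgi_class"].unique()) - VALID_CGI_CLASSES
        if bad:
            raise CohortError(f"unknown CGI classes: {sorted(bad)}")
        for flag in VALID_REGION_FLAGS:
            if flag not in self.table.columns:
                self.table[flag] = False
            self.table[flag] = self.table[flag].astype(bool)

    def probes_of_class(self, cgi_class: str) -> list[str]:
        return list(self.table.index[self.table["cgi_class"] == cgi_class])


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and survival endpoints."""

    table: pd.DataFrame

    CATEGORICAL_LEVELS = {
        "sex": {"M", "F"},
        "disease_status": {"ND", "RR"},
        "ph_status": {"pos", "neg"},
        "mrd1": {"pos", "neg"},
        "mrd2": {"pos", "neg"},
    }

    def __post_init__(self) -> None:
        t = self.table
        for col in ("os_time", "efs_time"):
            if col in t.columns and (t[col].dropna() < 0).any():
                raise CohortError(f"negative survival time in {col}")
        if "age" in t.columns and (t["age"].dropna() < 0).any():
            raise CohortError("negative age")
        for col, levels in self.CATEGORICAL_LEVELS.items():
            if col in t.columns:
                observed = set(t[col].dropna().unique())
                bad = observed - levels
                if bad:
                    raise CohortError(f"unknown levels in {col}: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise CohortError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def items(self):
        for name, (desc, genes) in self.sets.items():
            yield name, desc, list(genes)


@dataclass
class OmicsCohort:
    """Aligned expression / mutation / methylation / clinical layers.

    Expression is mandatory and its samples define the master sample list;
    every optional layer must stay within that list (tumor methylation
    samples only — the paired normal panel lives outside the cohort).
    """

    expression: ExpressionMatrix
    mutations: MutationTable | None = None
    methylation: MethylationMatrix | None = None
    clinical: ClinicalTable | None = None

    def __post_init__(self) -> None:
        master = set(self.expression.sample_ids)
        layers = {
            "mutations": None if self.mutations is None else set(self.mutations.sample_ids),
            "methylation": None
            if self.methylation is None
            else set(self.methylation.tumor_samples()),
            "clinical": None if self.clinical is None else set(self.clinical.sample_ids),
        }
        for name, ids in layers.items():
            if ids is not None and not ids <= master:
                extra = sorted(ids - master)
                raise CohortError(
                    f"{name} layer has samples outside the master list: {extra[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path,
    log_transform: bool = False,
    gene_class_path=None,
    gene_class_column: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes × samples TSV/GCT expression matrix.

    GCT files (``#1.2`` header) are detected by extension/first line; the
    Description column is dropped. ``gene_class`` comes from a companion
    annotation TSV (columns: gene, class) or an in-file column; genes without
    an assigned class default to ``mRNA``.
    """
    path = str(path)
    skiprows = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        skiprows = 2
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0)
    if skiprows and "Description" in df.columns:
        df = df.drop(columns=["Description"])
    gene_class = None
    if gene_class_column is not None:
        if gene_class_column not in df.columns:
            raise CohortError(f"gene class column {gene_class_column!r} absent")
        gene_class = df[gene_class_column].astype(str)
        df = df.drop(columns=[gene_class_column])
    if transpose:
        df = df.T
    df = df.astype(float)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    if gene_class_path is not None:
        ann = pd.read_csv(gene_class_path, sep="\t", index_col=0)
        gene_class = ann.iloc[:, 0].astype(str)
    if gene_class is None:
        gene_class = pd.Series("mRNA", index=df.index)
    gene_class = gene_class.reindex(df.index).fillna("mRNA")
    if log_transform:
        if (df.to_numpy() < 0).any():
            raise CohortError("cannot log-transform a matrix with negatives")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, gene_class, log_transformed=log_transform)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_mutations(path, min_vaf: float = 0.005) -> MutationTable:
    """Read a MAF-lite TSV, keeping records with ``vaf > min_vaf``.

    Column dialect: Sample, Hugo_Symbol, Chromosome, Position, Ref, Alt,
    Context, Effect, VAF.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in MAF_LITE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"MAF-lite file missing columns: {missing}")
    df = df.rename(columns=MAF_LITE_COLUMNS)[MUTATION_COLUMNS]
    if len(df):
        vaf = df["vaf"].to_numpy(float)
        if ((vaf <= 0) | (vaf > 1)).any():
            raise CohortError("VAF outside (0, 1]")
        keep = vaf > min_vaf
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("read_mutations: dropped %d records with VAF <= %g",
                        n_drop, min_vaf)
        df = df[keep].reset_index(drop=True)
    return MutationTable(df)


def write_mutations(mut: MutationTable, path) -> None:
    out = mut.records.rename(columns={v: k for k, v in MAF_LITE_COLUMNS.items()})
    out.to_csv(path, sep="\t", index=False)


def read_beta_matrix(path, groups_path) -> MethylationMatrix:
    """Read a probes × samples β TSV plus a sample → tumor/normal group TSV."""
    beta = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    beta.index = beta.index.rename(None)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0].astype(str)
    groups.index = groups.index.rename(None)
    groups.name = None
    return MethylationMatrix(beta, groups)


def write_beta_matrix(meth: MethylationMatrix, path, groups_path=None) -> None:
    meth.beta.to_csv(path, sep="\t", index_label="probe_id")
    if groups_path is not None:
        meth.sample_group.rename("group").to_csv(
            groups_path, sep="\t", index_label="sample_id"
        )


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a probe annotation TSV: probe_id, cgi_class, one column per flag."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="probe_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, then tab-separated member genes)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CohortError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise CohortError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in collection.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


_CLINICAL_BOOLS = {"ph_like", "hsct", "os_event", "efs_event"}
_CLINICAL_NUMERIC = {"age", "wbc", "os_time", "efs_time"}


def _parse_bool(value, column: str):
    if pd.isna(value):
        return np.nan
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "t"}:
        return True
    if s in {"0", "false", "no", "f"}:
        return False
    raise CohortError(f"unparseable boolean {value!r} in column {column}")


def read_clinical(path) -> ClinicalTable:
    """Read the per-sample clinical CSV (first column = sample id).

    Antigen-call columns are any columns named ``antigen_<MARKER>`` with
    levels negative/low/high; blanks in mrd1/mrd2 are kept as missing.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if col in _CLINICAL_BOOLS:
            df[col] = df[col].map(lambda v: _parse_bool(v, col))
        elif col in _CLINICAL_NUMERIC:
            df[col] = pd.to_numeric(df[col])
        elif col.startswith("antigen_"):
            observed = set(df[col].dropna().unique())
            bad = observed - {"negative", "low", "high"}
            if bad:
                raise CohortError(f"unknown antigen levels in {col}: {sorted(bad)}")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    out = clin.table.copy()
    for col in out.columns:
        if col in _CLINICAL_BOOLS:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(bool(v)).lower()
            )
    out.to_csv(path, index_label="sample_id")


def assemble_cohort(
    expression: ExpressionMatrix,
    mutations: MutationTable | None = None,
    methylation: MethylationMatrix | None = None,
    clinical: ClinicalTable | None = None,
    intersect: bool = False,
) -> OmicsCohort:
    """Assemble layers into an :class:`OmicsCohort`.

    By default any layer sample outside the expression master list is an
    error; ``intersect=True`` instead restricts every layer to the common
    samples (with a logged count).
    """
    if intersect:
        master = set(expression.sample_ids)
        if mutations is not None and len(mutations.records):
            rec = mutations.records
            keep = rec["sample_id"].isin(master)
            if (~keep).any():
                logger.info("assemble_cohort: dropping %d mutation records "
                            "outside master list", int((~keep).sum()))
            mutations = MutationTable(rec[keep].reset_index(drop=True))
        if methylation is not None:
            keep_cols = [
                s for s in methylation.sample_ids
                if s in master or methylation.sample_group[s] == "normal"
            ]
            methylation = MethylationMatrix(
                methylation.beta[keep_cols], methylation.sample_group[keep_cols]
            )
        if clinical is not None:
            keep_idx = [s for s in clinical.sample_ids if s in master]
            clinical = ClinicalTable(clinical.table.loc[keep_idx])
    return OmicsCohort(expression, mutations, methylation, clinical)
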