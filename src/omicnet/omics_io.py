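"""Readers, writers, and validators for the tables the pipeline touches.

Every modality travels as an :class:`OmicsMatrix` — a samples x features
table plus a boolean missing mask — keyed by one of the six registered
omics types. Gene sets come in as GMT, gene annotations as BED4+ or GFF3
(normalised to 0-based half-open coordinates), and result tables round-trip
through plain CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

#: Cell spellings treated as missing on read (case-insensitive).
MISSING_SPELLINGS = frozenset({"", "na", "nan"})

#: Symbol used internally for a missing SNP genotype (it is a first-class
#: state with its own one-hot channel).
SNP_MISSING = "missing"


@dataclass(frozen=True)
class OmicsType:
    """One omics data type: its name, value domain, and categorical alphabet.

    ``alphabet`` is the ordered list of admissible symbols for categorical
    modalities (one one-hot channel per symbol); empty for continuous ones.
    """

    name: str
    value_domain: str  # "continuous" | "categorical"
    alphabet: tuple = ()

    @property
    def is_continuous(self) -> bool:
        return self.value_domain == "continuous"

    @property
    def n_channels(self) -> int:
        """One-hot channel count: alphabet size, or 1 for continuous."""
        return len(self.alphabet) if self.alphabet else 1


#: Registry of the six supported omics types, in canonical order
#: (expression-like modalities first, then SNP and gene-level CNV).
MODALITIES: dict[str, OmicsType] = {
    "gene_expression": OmicsType("gene_expression", "continuous"),
    "mirna_expression": OmicsType("mirna_expression", "continuous"),
    "dna_methylation": OmicsType("dna_methylation", "continuous"),
    "protein_expression": OmicsType("protein_expression", "continuous"),
    "snp": OmicsType("snp", "categorical", ("A", "C", "G", "T", SNP_MISSING)),
    "cnv": OmicsType("cnv", "categorical", (-2, -1, 0, 1, 2)),
}

#: Canonical modality ordering used for deterministic combination enumeration.
CANONICAL_ORDER: tuple[str, ...] = tuple(MODALITIES)


def get_modality(modality: str | OmicsType) -> OmicsType:
    """Resolve a modality name (or pass through an :class:`OmicsType`)."""
    if isinstance(modality, OmicsType):
        return modality
    try:
        return MODALITIES[modality]
    except KeyError:
        raise KeyError(
            f"unknown modality {modality!r}; expected one of {sorted(MODALITIES)}"
        ) from None


@dataclass
class OmicsMatrix:
    """One modality's samples x features table with an explicit missing mask.

    ``values`` is indexed by sample ID with feature IDs as columns; cells hold
    floats for continuous modalities and alphabet symbols for categorical
    ones. ``missing_mask`` shares the exact shape and is True where the
    source cell was empty/NA.
    """

    modality: OmicsType
    values: pd.DataFrame
    missing_mask: pd.DataFrame

    def __post_init__(self) -> None:
        self.modality = get_modality(self.modality)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature ID {dup!r}")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.missing_mask.shape}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SurvivalTable:
    """Per-sample survival time in years plus an event indicator.

    ``event`` is 1 when death was observed and 0 when the sample was censored
    at last follow-up.
    """

    data: pd.DataFrame  # index sample_id; columns survival_time, event

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        missing = {"survival_time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"survival table lacks columns {sorted(missing)}")
        if (df["survival_time"] < 0).any():
            bad = df.index[df["survival_time"] < 0][0]
            raise ValueError(f"negative survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])][0]
            raise ValueError(f"event for sample {bad!r} not in {{0, 1}}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype: categorical labels or quantitative values."""

    labels: pd.Series  # index sample_id
    task: str  # "classification" | "regression"

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.labels.index.has_duplicates:
            dup = self.labels.index[self.labels.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        if self.task == "classification" and self.labels.nunique() < 2:
            raise ValueError("classification phenotype needs >= 2 distinct labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


@dataclass
class GeneAnnotation:
    """Gene intervals in 0-based half-open coordinates.

    ``records`` columns: chromosome, start, end, strand, gene_id.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"chromosome", "start", "end", "strand", "gene_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"annotation lacks columns {sorted(missing)}")
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"empty/inverted interval for gene {row['gene_id']!r}: "
                f"[{row['start']}, {row['end']})"
            )
        if (df["gene_id"].astype(str) == "").any():
            raise ValueError("annotation contains an empty gene_id")

    def by_chromosome(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.records.groupby("chromosome", sort=False)}


@dataclass
class GeneSetCollection:
    """Mapping pathway_id -> (description, member gene set)."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class ValidationReport:
    """Outcome of a matrix check: error/warning lists with cell loci."""

    errors: list = field(default_factory=list)  # (locus, message)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# readers


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_SPELLINGS


def read_omics_csv(
    path: str | Path, modality: str | OmicsType, id_column: str = "sample_id"
) -> OmicsMatrix:
    """Read one modality's CSV (rows = samples, columns = features).

    Empty cells and the spellings "NA"/"NaN" (any case) become missing.
    Categorical symbols are kept verbatim apart from SNP genotypes, which are
    upper-cased; sample order is preserved as uploaded.
    """
    modality = get_modality(modality)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    ids = raw[id_column].astype(str).str.strip()
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample ID {dup.iloc[0]!r} in {path}")
    body = raw.drop(columns=[id_column])
    body.index = pd.Index(ids, name=id_column)
    mask = body.apply(lambda col: col.str.strip().str.lower().isin(MISSING_SPELLINGS))

    if modality.is_continuous:
        numeric = body.apply(pd.to_numeric, errors="coerce")
        if (numeric.isna() & ~mask).any().any():
            # keep unparseable cells verbatim so validation can cite them
            values = numeric.astype(object)
            bad = numeric.isna() & ~mask
            values = values.mask(bad, body)
        else:
            values = numeric
        values = values.mask(mask, np.nan)
    elif modality.name == "snp":
        values = body.apply(lambda col: col.str.strip().str.upper())
        values = values.mask(mask, SNP_MISSING)
    else:  # cnv: integer levels, unparseable kept verbatim for validation
        numeric = body.apply(pd.to_numeric, errors="coerce")
        values = numeric.astype(object)
        bad = numeric.isna() & ~mask
        values = values.mask(bad, body)
        ok_int = numeric.notna()
        values = values.mask(ok_int, numeric.round().astype("Int64").astype(object))
        values = values.mask(mask, np.nan)
    return OmicsMatrix(modality=modality, values=values, missing_mask=mask)


def read_survival_csv(
    path: str | Path,
    id_column: str = "sample_id",
    time_column: str = "survival_time",
    event_column: str = "event",
) -> SurvivalTable:
    df = pd.read_csv(path)
    for col in (id_column, time_column, event_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    out = df.set_index(id_column)[[time_column, event_column]]
    out.columns = ["survival_time", "event"]
    out.index = out.index.astype(str)
    return SurvivalTable(out)


def read_phenotype_csv(
    path: str | Path,
    task: str,
    id_column: str = "sample_id",
    label_column: str = "label",
) -> PhenotypeTable:
    df = pd.read_csv(path)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    labels = df.set_index(id_column)[label_column]
    labels.index = labels.index.astype(str)
    if task == "regression":
        labels = labels.astype(float)
    return PhenotypeTable(labels=labels, task=task)


def validate_matrix(matrix: OmicsMatrix) -> ValidationReport:
    """Check value domains against the modality's contract.

    Continuous modalities must hold numbers; categorical modalities only
    symbols from their alphabet. All-missing features are warned about.
    The input matrix is never mutated.
    """
    report = ValidationReport()
    vals = matrix.values
    mask = matrix.missing_mask
    if matrix.modality.is_continuous:
        for feat in vals.columns:
            col = vals[feat]
            for sample, cell in col.items():
                if mask.at[sample, feat]:
                    continue
                if not isinstance(cell, (int, float, np.integer, np.floating)) or (
                    isinstance(cell, float) and np.isnan(cell)
                ):
                    report.errors.append(
                        (
                            (sample, feat),
                            f"non-numeric value {cell!r} in continuous modality "
                            f"{matrix.modality.name}",
                        )
                    )
    else:
        allowed = set(matrix.modality.alphabet)
        for feat in vals.columns:
            for sample, cell in vals[feat].items():
                if mask.at[sample, feat]:
                    continue
                if cell not in allowed:
                    report.errors.append(
                        (
                            (sample, feat),
                            f"symbol {cell!r} outside the {matrix.modality.name} "
                            f"alphabet {list(matrix.modality.alphabet)}",
                        )
                    )
    all_missing = mask.all(axis=0)
    for feat in mask.columns[all_missing]:
        report.warnings.append(f"feature {feat!r} is missing in every sample")
    return report


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file: one set per line, tab-separated
    (pathway_id, description, member genes...). Duplicate members within a
    line are deduplicated."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            pid, desc, *genes = fields
            if pid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway ID {pid!r}")
            members = frozenset(g for g in genes if g.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {pid!r} is empty")
            sets[pid] = members
            descriptions[pid] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|Name|gene_id)=([^;]+)")


def read_gene_annotation(path: str | Path, format: str) -> GeneAnnotation:
    """Read gene intervals from BED4+ (kept verbatim, 0-based half-open) or
    GFF3 (1-based closed, converted to 0-based half-open via start-1)."""
    if format not in ("bed", "gff"):
        raise ValueError(f"unknown annotation format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "bed":
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
                chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            else:
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
                chrom = fields[0]
                start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(fields[4])
                strand = fields[6] if fields[6] in "+-" else "+"
                m = _GFF_ID_RE.search(fields[8])
                gene_id = m.group(1).strip() if m else f"{chrom}:{start}-{end}"
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty/inverted interval [{start}, {end})"
                )
            rows.append((chrom, start, end, strand, gene_id))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "strand", "gene_id"])
    )


# ---------------------------------------------------------------------------
# result tables

#: Canonical column order per result-table kind.
TABLE_COLUMNS: dict[str, list[str]] = {
    "predictions": ["sample_id", "prediction", "score"],
    "markers": ["modality", "feature_id", "saliency", "dense_rank"],
    "enrichment": [
        "pathway_id",
        "overlap_size",
        "set_size",
        "query_size",
        "background_size",
        "p_value",
        "adjusted_p",
        "overlap_genes",
    ],
    "gene_map": ["gene_id", "best_rank", "n_markers", "marker_ids"],
}


def write_table(records, path: str | Path, kind: str) -> Path:
    """Write a result table as CSV with a deterministic column order.

    ``records`` may be a DataFrame or an iterable of mappings; an empty input
    produces a header-only file. Floats are formatted at 12 significant
    digits so write/read round-trips are lossless for practical purposes.
    """
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    canonical = TABLE_COLUMNS[kind]
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=canonical)
    ordered = [c for c in canonical if c in df.columns]
    extra = [c for c in df.columns if c not in canonical]
    df = df[ordered + extra]
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    return pd.read_csv(path)
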