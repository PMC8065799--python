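"""Readers, writers and containers for expression matrices, clinical tables,
immune-fraction tables and GMT gene-set collections.

Gene identifiers are HGNC-style symbols throughout; there is no identifier
mapping layer. Expression matrices are genes x samples with an explicit scale
tag distinguishing linear TPM from log2(x+1) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "SurvivalCohort",
    "GeneSetCollection",
    "AlignmentReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "read_fraction_table",
    "read_gmt",
    "write_gmt",
    "align_genes",
]


class Scale(str, Enum):
    """Scale of an expression matrix: linear TPM or log2(TPM + 1)."""

    LINEAR_TPM = "linear_tpm"
    LOG2P1 = "log2p1"


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample identifiers as columns.
    scale
        ``Scale.LINEAR_TPM`` for linear TPM, ``Scale.LOG2P1`` for log2(x+1).
    """

    values: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if arr.size and (arr < 0).any():
            raise ValueError("expression values must be non-negative")

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

    def to_linear(self) -> "ExpressionMatrix":
        """Return the matrix on the linear scale (back-transforming log2p1)."""
        if self.scale is Scale.LINEAR_TPM:
            return self
        lin = np.power(2.0, self.values) - 1.0
        lin = lin.clip(lower=0.0)
        return ExpressionMatrix(lin, Scale.LINEAR_TPM)

    def to_log2p1(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(x+1) scale."""
        if self.scale is Scale.LOG2P1:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), Scale.LOG2P1)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.scale)


def read_expression_matrix(path: str | Path, scale: Scale | str) -> ExpressionMatrix:
    """Read a genes-x-samples TSV/CSV into an :class:`ExpressionMatrix`.

    First column holds gene symbols, header row holds sample ids. Duplicate
    gene rows are collapsed by taking the per-sample maximum (logged);
    duplicate sample ids and non-numeric cells are errors.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicate sample id in header: {s!r}")
        seen.add(s)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = samples
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {raw.iat[gi, si]!r} at "
            f"gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if num.index.has_duplicates:
        dups = num.index[num.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene symbols by max: %s",
                       len(dups), dups[:5])
        num = num.groupby(level=0, sort=False).max()
    return ExpressionMatrix(num, Scale(scale))


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV/CSV (extension decides the separator)."""
    path = Path(path)
    mat.values.to_csv(path, sep=_sep_for(path), index_label="gene")


CLINICAL_COLUMNS = (
    "dss_time",
    "dss_event",
    "stage",
    "age_band",
    "gender",
    "anatomic_location",
    "residual_disease",
)

_CATEGORICAL = CLINICAL_COLUMNS[2:]


@dataclass
class SurvivalCohort:
    """Patients with disease-specific survival (DSS) and clinical covariates.

    ``clinical`` is indexed by patient id with columns ``dss_time`` (days),
    ``dss_event`` (1 = disease-specific death), ``stage``, ``age_band``,
    ``gender``, ``anatomic_location`` and ``residual_disease``. Rows with a
    missing time or event are retained but flagged unusable for survival;
    each downstream statistic decides its own exclusions.
    """

    clinical: pd.DataFrame
    expression: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        miss = [c for c in ("dss_time", "dss_event") if c not in self.clinical.columns]
        if miss:
            raise ValueError(f"clinical table lacks columns: {miss}")
        t = self.clinical["dss_time"]
        if (t.dropna() < 0).any():
            raise ValueError("negative dss_time")
        ev = self.clinical["dss_event"].dropna()
        if not ev.isin([0, 1, 0.0, 1.0]).all():
            raise ValueError("dss_event must be 0/1 after recoding")
        if self.expression is not None:
            if list(self.expression.sample_ids) != list(self.clinical.index):
                raise ValueError("expression columns and clinical rows disagree; "
                                 "use attach_expression to align")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def usable_for_survival(self) -> pd.Series:
        """Boolean mask of patients with both DSS time and event recorded."""
        return self.clinical["dss_time"].notna() & self.clinical["dss_event"].notna()

    def usable(self) -> pd.DataFrame:
        return self.clinical.loc[self.usable_for_survival]

    def attach_expression(self, expr: ExpressionMatrix) -> "SurvivalCohort":
        """Intersect patients with the expression columns and align both."""
        shared = [p for p in self.clinical.index if p in set(expr.sample_ids)]
        dropped = len(self.clinical) - len(shared)
        if dropped:
            logger.info("attach_expression: %d patients lack expression, dropped", dropped)
        if not shared:
            raise ValueError("no shared patients between clinical table and expression")
        return SurvivalCohort(self.clinical.loc[shared],
                              expr.subset_samples(shared))


def read_clinical_table(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
    event_recode: Mapping[str, int] | None = None,
) -> SurvivalCohort:
    """Read a clinical TSV into a :class:`SurvivalCohort` (no expression).

    ``column_map`` maps canonical names (``patient_id``, ``dss_time``,
    ``dss_event``, ``stage``, ``age_band``, ``gender``, ``anatomic_location``,
    ``residual_disease``) to the file's column names; it may be a dict or a
    path to a YAML file with optional ``columns:`` and ``event_recode:`` keys.
    Categorical fields absent from the file are filled with ``"missing"``.
    """
    path = Path(path)
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            cfg = yaml.safe_load(fh) or {}
        event_recode = event_recode or cfg.get("event_recode")
        column_map = cfg.get("columns", {})
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=_sep_for(path))
    pid_col = column_map.get("patient_id", "patient_id")
    if pid_col not in df.columns:
        raise ValueError(f"no patient id column {pid_col!r}")
    out = pd.DataFrame(index=pd.Index(df[pid_col].astype(str), name="patient_id"))
    for canon in CLINICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            out[canon] = df[src].to_numpy()
        else:
            out[canon] = "missing" if canon in _CATEGORICAL else np.nan
    if event_recode:
        out["dss_event"] = out["dss_event"].map(
            lambda v: event_recode.get(v, v) if isinstance(v, str) else v)
    out["dss_time"] = pd.to_numeric(out["dss_time"], errors="coerce")
    out["dss_event"] = pd.to_numeric(out["dss_event"], errors="coerce")
    bad = out["dss_event"].dropna()
    if not bad.isin([0, 1]).all():
        raise ValueError(f"dss_event values outside 0/1 after recoding: "
                         f"{sorted(bad[~bad.isin([0, 1])].unique())[:5]}")
    for canon in _CATEGORICAL:
        out[canon] = out[canon].astype(object).where(pd.notna(out[canon]), "missing")
    n_flagged = int((out["dss_time"].isna() | out["dss_event"].isna()).sum())
    if n_flagged:
        logger.info("%d patients lack DSS time or event; flagged unusable", n_flagged)
    return SurvivalCohort(out)


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    """Read a patient x immune-subset fraction table (first column patient id)."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)), index_col=0)
    arr = df.to_numpy(float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("immune fractions must lie in [0, 1]")
    return df


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), genes in the expression symbol namespace."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name!r}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene TAB gene ...).

    Duplicate set names are an error; genes repeated within a set are
    deduplicated (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, description, *genes = fields
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicated set name {name!r}")
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                logger.info("GMT set %s: %d duplicate genes removed",
                            name, len(genes) - len(uniq))
            if not uniq:
                raise ValueError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = uniq
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class AlignmentReport:
    """Partition of a query gene list into cohort-annotated and missing."""

    query_genes: list[str]
    annotated: list[str]
    missing: list[str]

    @property
    def n_annotated(self) -> int:
        return len(self.annotated)


def align_genes(
    query_genes: Sequence[str],
    gene_space: ExpressionMatrix | Iterable[str],
    case_fold: bool = False,
) -> AlignmentReport:
    """Partition ``query_genes`` by presence in a cohort's gene space.

    Matching is exact (case-sensitive) by default; with ``case_fold`` symbols
    are compared case-insensitively.
    """
    if isinstance(gene_space, ExpressionMatrix):
        space: Iterable[str] = gene_space.gene_ids
    else:
        space = gene_space
    if case_fold:
        lookup = {g.casefold() for g in space}
        present = [g for g in query_genes if g.casefold() in lookup]
    else:
        lookup = set(space)
        present = [g for g in query_genes if g in lookup]
    present_set = set(present)
    missing = [g for g in query_genes if g not in present_set]
    return AlignmentReport(list(query_genes), present, missing)
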