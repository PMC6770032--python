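"""Readers, writers and validation for the pipeline's plain-text formats.

Three inputs drive a run: a features x samples expression matrix
(tab-separated, log-scale intensities), a per-sample clinical table from which
the continuous age at diagnosis is derived, and a two-column miRNA -> gene
target table (as exported from a target-interaction aggregator such as
miRNET).  Everything is deliberately plain text so runs are diffable and
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TISSUES",
    "AGE_GROUPS",
    "DAYS_PER_YEAR",
    "ExpressionMatrix",
    "SampleRecord",
    "TargetTable",
    "compute_age_years",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_targets",
    "write_targets",
]

TISSUES = ("tumor", "normal")
AGE_GROUPS = ("PEDS", "AYA")

#: Age convention: (diagnosis date - birth date) in days, divided by the
#: constant 365.  Kept as the plain constant (no leap-year 365.25): the
#: difference only matters at day resolution and day-resolution ages are what
#: make the exact permutation p-values valid (no ties).
DAYS_PER_YEAR = 365

#: Boundary (in years) between the pediatric and the adolescent-and-young-adult
#: age groups (PEDS 0-14, AYA 15+).
AYA_MIN_AGE = 15.0


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with a feature-kind tag.

    ``data`` is a DataFrame whose index holds feature ids and whose columns
    hold sample ids; values are log-scale intensities.  ``kind`` is either
    ``"mirna"`` or ``"gene"``.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self):
        if self.kind not in ("mirna", "gene"):
            raise ValueError(f"kind must be 'mirna' or 'gene', got {self.kind!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float, copy=False)).all():
            i, j = np.argwhere(~np.isfinite(vals.astype(float)))[0]
            raise ValueError(
                f"non-finite value at feature {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def feature_ids(self):
        return self.data.index

    @property
    def sample_ids(self):
        return self.data.columns

    @property
    def shape(self):
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.kind)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample clinical metadata with the derived continuous age."""

    sample_id: str
    birth_date: date
    diagnosis_date: date
    tissue: str
    age_group: str = ""
    age_years: float = field(default=np.nan)

    @staticmethod
    def create(sample_id, birth_date, diagnosis_date, tissue, age_group=None):
        if tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue label {tissue!r} for sample {sample_id!r}; "
                f"accepted labels: {', '.join(TISSUES)}"
            )
        age = compute_age_years(birth_date, diagnosis_date)
        if age_group is None or age_group == "":
            age_group = "AYA" if age >= AYA_MIN_AGE else "PEDS"
        if age_group not in AGE_GROUPS:
            raise ValueError(
                f"unknown age group {age_group!r} for sample {sample_id!r}; "
                f"accepted: {', '.join(AGE_GROUPS)}"
            )
        return SampleRecord(
            sample_id=str(sample_id),
            birth_date=birth_date,
            diagnosis_date=diagnosis_date,
            tissue=tissue,
            age_group=age_group,
            age_years=age,
        )


def _to_date(value, what: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"unparseable {what} (expected ISO-8601): {value!r}") from exc


def compute_age_years(birth_date, diagnosis_date) -> float:
    """Continuous age at diagnosis in years: day difference / 365.

    The divisor is the plain constant 365 by convention; dates may be
    ``datetime.date`` or ISO-8601 strings.  Diagnosis before birth is
    rejected.
    """
    b = _to_date(birth_date, "birth date")
    d = _to_date(diagnosis_date, "diagnosis date")
    days = (d - b).days
    if days < 0:
        raise ValueError(
            f"diagnosis date {d.isoformat()} precedes birth date {b.isoformat()}"
        )
    return days / DAYS_PER_YEAR


def read_expression(path, kind: str) -> ExpressionMatrix:
    """Read a tab-separated features x samples matrix.

    First column: feature id; header row: sample ids; remaining cells numeric.
    Duplicated ids, ragged rows and non-numeric cells are rejected with the
    offending coordinates named.  Row and column order are preserved.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            n_fields = line.rstrip("\n").count("\t") + 1
            if n_fields != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({n_fields} fields, header has {width})"
                )
    sample_ids = header[1:]
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample id in header of {path}: {sorted(dup)[0]!r}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    raw.index.name = None
    raw.columns.name = None
    if raw.index.has_duplicates:
        dup_id = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate feature id in {path}: {dup_id!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell in {path} at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    return ExpressionMatrix(values.astype(float), kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


_SAMPLE_COLUMNS = ("sample_id", "birth_date", "diagnosis_date", "tissue")


def read_samples(path) -> list[SampleRecord]:
    """Read sample metadata (comma- or tab-separated) and derive ages.

    Required columns: sample_id, birth_date, diagnosis_date, tissue
    (``age_group`` optional; derived from age when absent).  Samples sharing
    an identical derived age trigger a warning — tied ages invalidate the
    exact permutation p-values downstream — but are returned.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {', '.join(missing)}")
    has_group = "age_group" in df.columns
    records = [
        SampleRecord.create(
            row["sample_id"],
            _to_date(row["birth_date"], "birth date"),
            _to_date(row["diagnosis_date"], "diagnosis date"),
            row["tissue"],
            row["age_group"] if has_group else None,
        )
        for _, row in df.iterrows()
    ]
    ages = [r.age_years for r in records]
    if len(set(ages)) < len(ages):
        warnings.warn(
            f"{path}: samples with identical derived ages found; exact "
            "Spearman p-values assume tie-free ages",
            stacklevel=2,
        )
    return records


def write_samples(records, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "birth_date": [r.birth_date.isoformat() for r in records],
            "diagnosis_date": [r.diagnosis_date.isoformat() for r in records],
            "tissue": [r.tissue for r in records],
            "age_group": [r.age_group for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TargetTable:
    """Many-to-many miRNA -> target-gene mapping (deduplicated pairs)."""

    targets: dict
    n_dropped: int = 0

    @staticmethod
    def from_pairs(pairs, gene_universe=None, n_dropped: int = 0) -> "TargetTable":
        universe = set(gene_universe) if gene_universe is not None else None
        mapping: dict[str, set] = {}
        dropped = n_dropped
        for mirna, gene in pairs:
            if not mirna or not gene:
                raise ValueError(f"empty id in target pair ({mirna!r}, {gene!r})")
            if mirna == gene:
                raise ValueError(f"self-pair in target table: {mirna!r}")
            if universe is not None and gene not in universe:
                dropped += 1
                continue
            mapping.setdefault(mirna, set()).add(gene)
        return TargetTable(
            {m: frozenset(g) for m, g in mapping.items()}, n_dropped=dropped
        )

    @property
    def pairs(self) -> frozenset:
        return frozenset(
            (m, g) for m, genes in self.targets.items() for g in genes
        )

    @property
    def n_pairs(self) -> int:
        return sum(len(g) for g in self.targets.values())

    def genes_for(self, mirna: str) -> frozenset:
        return self.targets.get(mirna, frozenset())

    def restrict(self, gene_universe) -> "TargetTable":
        return TargetTable.from_pairs(self.pairs, gene_universe=gene_universe)


def read_targets(path, gene_universe=None) -> TargetTable:
    """Read a two-column tab-separated miRNA/gene pair table.

    Pairs whose gene is absent from ``gene_universe`` (when given) are dropped
    and counted in ``n_dropped`` — only genes actually measured in the
    expression matrix can be integrated.  Duplicate pairs collapse to one.
    An empty table after filtering is an error: there is nothing to integrate.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            if lineno == 1 and [f.lower() for f in fields] == ["mirna", "gene"]:
                continue
            pairs.append((fields[0], fields[1]))
    table = TargetTable.from_pairs(pairs, gene_universe=gene_universe)
    if table.n_pairs == 0:
        raise ValueError(
            f"{path}: no target pairs left after filtering to the gene universe; "
            "nothing to integrate"
        )
    return table


def write_targets(table: TargetTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\n")
        for mirna in sorted(table.targets):
            for gene in sorted(table.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")
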