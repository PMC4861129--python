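"""Readers and writers for the pipeline's interchange formats.

All tables are UTF-8 TSV with ``NA`` for missing values.  The metabolite
dialect carries two metadata columns (``method``, ``is_standard``) between
the feature-id column and the sample columns; the expression dialect is a
plain feature-by-sample matrix.  Gene sets travel as Broad-dialect GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionCohort,
    GeneSetCollection,
    IntegratedSignature,
    MetaboliteGeneMap,
    MetaboliteMatrix,
    SampleAnnotation,
)
from .exceptions import FormatError

logger = logging.getLogger(__name__)

NA_REP = "NA"
_METAB_META_COLS = ("method", "is_standard")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[NA_REP], encoding="utf-8"
    )


def _to_float_matrix(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Parse string cells to floats, locating any non-numeric cell."""
    out = np.empty(df.shape, dtype=float)
    arr = df.to_numpy(dtype=object)
    for j, col in enumerate(df.columns):
        for i in range(arr.shape[0]):
            cell = arr[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row '{df.index[i]}', column '{col}'"
                ) from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_abundance_table(path: str | Path, dialect: str = "metabolite"):
    """Read a feature-by-sample abundance TSV.

    ``dialect='metabolite'`` expects columns
    ``feature_id, method, is_standard, <sample...>`` and returns a
    :class:`MetaboliteMatrix`; ``dialect='expression'`` expects
    ``feature_id, <sample...>`` and returns a plain float DataFrame.
    """
    if dialect not in ("metabolite", "expression"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a feature-id column plus data columns")
    feature_col = raw.columns[0]
    ids = raw[feature_col].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate feature id(s): {dup}")
    raw = raw.set_index(feature_col)
    raw.index.name = "feature_id"

    if dialect == "expression":
        return _to_float_matrix(raw, path)

    missing_meta = [c for c in _METAB_META_COLS if c not in raw.columns]
    if missing_meta:
        raise FormatError(f"{path}: metabolite dialect requires column(s) {missing_meta}")
    method = raw["method"].astype(str)
    is_std_raw = raw["is_standard"].astype(str).str.strip().str.lower()
    bad = sorted(set(is_std_raw) - {"0", "1", "true", "false"})
    if bad:
        raise FormatError(f"{path}: is_standard values must be 0/1/true/false, got {bad}")
    is_standard = is_std_raw.isin(["1", "true"])
    values = _to_float_matrix(raw.drop(columns=list(_METAB_META_COLS)), path)
    return MetaboliteMatrix(values=values, method=method, is_internal_standard=is_standard)


def write_abundance_table(path: str | Path, matrix, dialect: str = "metabolite") -> None:
    path = Path(path)
    if dialect == "expression":
        df = matrix.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.10g", encoding="utf-8")
        return
    m: MetaboliteMatrix = matrix
    out = m.values.copy()
    out.insert(0, "is_standard", m.is_internal_standard.astype(int).reindex(out.index))
    out.insert(0, "method", m.method.reindex(out.index))
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.10g", encoding="utf-8")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = _read_tsv(path)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: annotation requires columns {sorted(required)}")
    if "cohort" not in df.columns:
        df["cohort"] = "cohort1"
    table = df.set_index("sample_id")[["group", "cohort"]]
    return SampleAnnotation(table)


def write_sample_annotation(path: str | Path, annot: SampleAnnotation) -> None:
    out = annot.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_REP, encoding="utf-8")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Clinical TSV: specimen_id, time, event, group, cohort (group/cohort optional)."""
    df = _read_tsv(path)
    required = {"specimen_id", "time", "event"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: clinical table requires columns {sorted(required)}")
    if "group" not in df.columns:
        df["group"] = "tumor"
    if "cohort" not in df.columns:
        df["cohort"] = "cohort1"
    df = df.set_index("specimen_id")
    for col in ("time", "event"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in column '{col}': {exc}") from None
    times = df["time"].dropna()
    if (times < 0).any():
        raise FormatError(f"{path}: negative survival time")
    events = df["event"].dropna()
    if not set(events.unique()) <= {0.0, 1.0}:
        raise FormatError(f"{path}: event indicator must be 0 or 1")
    return df[["time", "event", "group", "cohort"]]


def write_clinical_table(path: str | Path, clinical: pd.DataFrame) -> None:
    out = clinical.copy()
    out.index.name = "specimen_id"
    out.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.10g", encoding="utf-8")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (set name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name '{name}'")
            sets[name] = members
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets=sets)


def write_gmt(path: str | Path, collection: GeneSetCollection, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_metabolite_gene_map(path: str | Path) -> MetaboliteGeneMap:
    """Two-column TSV: metabolite_id TAB gene_symbol, one pair per line."""
    entries: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'metabolite_id<TAB>gene_symbol'")
            metabolite, gene = fields[0].strip(), fields[1].strip()
            if not metabolite or not gene:
                raise FormatError(f"{path}:{lineno}: empty metabolite or gene field")
            entries.setdefault(metabolite, set()).add(gene.upper())
    return MetaboliteGeneMap(entries={m: frozenset(g) for m, g in entries.items()})


def write_metabolite_gene_map(path: str | Path, mapping: MetaboliteGeneMap) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for metabolite in sorted(mapping.entries):
            for gene in sorted(mapping.entries[metabolite]):
                fh.write(f"{metabolite}\t{gene}\n")


def read_signature(path: str | Path) -> IntegratedSignature:
    """Signature TSV: gene_symbol TAB log2_fc."""
    df = _read_tsv(path)
    if not {"gene_symbol", "log2_fc"} <= set(df.columns):
        raise FormatError(f"{path}: signature requires columns gene_symbol, log2_fc")
    try:
        fc = df.set_index("gene_symbol")["log2_fc"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric log2_fc: {exc}") from None
    return IntegratedSignature.from_fold_changes(fc)


def write_signature(path: str | Path, signature: IntegratedSignature) -> None:
    out = signature.entries[["log2_fc"]].copy()
    out.index.name = "gene_symbol"
    out.to_csv(path, sep="\t", float_format="%.10g", encoding="utf-8")


def read_expression_cohort(
    expression_path: str | Path, clinical_path: str | Path, cohort_id: str = "cohort1"
) -> ExpressionCohort:
    expr = read_abundance_table(expression_path, dialect="expression")
    clinical = read_clinical_table(clinical_path)
    missing = set(clinical.index) - set(expr.columns)
    if missing:
        raise FormatError(
            f"clinical specimens absent from expression matrix: {sorted(missing)[:5]}"
        )
    return ExpressionCohort(cohort_id=cohort_id, expression=expr, clinical=clinical)
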