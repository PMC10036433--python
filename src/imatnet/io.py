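"""Readers and writers for every table the pipeline consumes or emits.

Clinical, Ct and result tables travel as RFC-4180 CSV (UTF-8, header row);
expression matrices as TSV with genes in rows and the gene identifier in the
first column. Every writer drops a JSON provenance sidecar next to the data
file recording the package version, the seed in force and a timestamp; the
sidecar is advisory and never read back by the analysis.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .datatypes import ClinicalTable, ExpressionMatrix
from .errors import ParseError, ValidationError

log = logging.getLogger("imatnet.io")

_FLOAT_FMT = "%.12g"  # round-trip stable to 12 significant digits


def _write_sidecar(path: Path, seed=None) -> None:
    record = {
        "file": path.name,
        "package": "imatnet",
        "version": __version__,
        "seed": seed,
        "written": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(str(path) + ".prov.json").write_text(json.dumps(record, indent=1))


def read_clinical_table(path, dialect: str = "csv") -> ClinicalTable:
    """Read and validate a participant-level clinical CSV."""
    path = Path(path)
    sep = "\t" if dialect == "tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if "participant_id" not in frame.columns:
        raise ParseError(f"{path}: missing 'participant_id' header")
    reserved = {"participant_id", "group", "sex"}
    for col in frame.columns:
        if col in reserved:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            row = bad[0]
            raise ParseError(
                f"{path}: non-numeric value {frame.loc[row, col]!r} "
                f"in column '{col}', row {row + 2}"
            )
        frame[col] = coerced
    table = ClinicalTable(frame)
    log.info("read clinical table %s: %d participants, groups %s",
             path.name, len(table), table.group_counts())
    return table


def write_clinical_table(table: ClinicalTable, path, seed=None) -> None:
    path = Path(path)
    table.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _write_sidecar(path, seed)


def read_expression_matrix(path, tissue: str) -> ExpressionMatrix:
    """Read a genes-x-participants TSV (first column = gene identifier)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if frame.isna().all(axis=None):
        raise ParseError(f"{path}: no expression values parsed")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id '{dup}'")
    mat = ExpressionMatrix(tissue, frame.astype(float))
    log.info("read %s expression matrix %s: %d genes x %d participants",
             tissue, path.name, *mat.shape)
    return mat


def write_expression_matrix(mat: ExpressionMatrix, path, seed=None) -> None:
    path = Path(path)
    mat.values.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)
    _write_sidecar(path, seed)


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR table: participant, timepoint, gene, Ct."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"participant_id": str, "gene": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    required = {"participant_id", "timepoint", "gene", "Ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_tp = set(frame["timepoint"].unique()) - {"pre", "post"}
    if bad_tp:
        raise ValidationError(f"{path}: unknown timepoints {sorted(bad_tp)}")
    frame["Ct"] = pd.to_numeric(frame["Ct"])
    return frame


def write_table(frame: pd.DataFrame, path, seed=None, index: bool = False) -> None:
    """Write any result table as CSV with a provenance sidecar."""
    path = Path(path)
    frame.to_csv(path, index=index, float_format=_FLOAT_FMT)
    _write_sidecar(path, seed)
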