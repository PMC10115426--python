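"""Reading and writing the pipeline's tab-separated file formats.

Expression matrices are probes x samples TSV, optionally in the GEO
series-matrix table dialect: metadata lines prefixed with ``!`` are skipped
and double-quoted fields are unquoted.  Sample annotations are TSV keyed by
sample id with the columns the cohort statistics expect (``group``,
``patient_id``, ``timepoint``, ``response``; extras pass through).
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionData",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "read_pas_matrix",
    "write_pas_matrix",
]


class ExpressionData(NamedTuple):
    """An expression matrix (probes x samples) with optional annotations."""

    expression: pd.DataFrame
    annotations: pd.DataFrame | None


def _unquote(field: str) -> str:
    if len(field) >= 2 and field[0] == '"' and field[-1] == '"':
        return field[1:-1]
    return field


def read_expression_matrix(path: str | Path,
                           annotation_path: str | Path | None = None) -> ExpressionData:
    """Parse a probes x samples log2-intensity TSV.

    Handles the GEO series-matrix dialect (``!``-prefixed metadata lines,
    including the ``!series_matrix_table_begin``/``_end`` sentinels, and
    quoted identifiers).  Errors on ragged rows (with line number) and on
    duplicate sample or probe ids.  Empty cells become NaN, which the QC
    stage treats as non-positive linear readings.
    """
    path = Path(path)
    header: list[str] | None = None
    probes: list[str] = []
    rows: list[list[float]] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = [_unquote(f) for f in line.split("\t")]
            if header is None:
                header = fields[1:]
                if len(set(header)) != len(header):
                    raise ValueError(f"{path}: duplicate sample ids in header")
                continue
            if len(fields) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(header) + 1})"
                )
            probes.append(fields[0])
            rows.append([float(f) if f not in ("", "NA", "null") else np.nan
                         for f in fields[1:]])
    if header is None:
        raise ValueError(f"{path}: no table found")
    if len(set(probes)) != len(probes):
        raise ValueError(f"{path}: duplicate probe ids")
    expr = pd.DataFrame(rows, index=probes, columns=header, dtype=float)
    expr.index.name = "probe_id"
    annotations = None
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
        unknown = set(annotations.index) - set(expr.columns)
        if unknown:
            raise ValueError(
                f"annotation sample ids not in matrix: {sorted(unknown)}"
            )
    return ExpressionData(expr, annotations)


def write_expression_matrix(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation TSV (first column = sample id)."""
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if ann.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in annotations")
    ann.index.name = "sample_id"
    return ann


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_pas_matrix(path: str | Path) -> pd.DataFrame:
    """Read a pathways x samples PAS TSV (log2-odds units)."""
    pas = pd.read_csv(path, sep="\t", index_col=0)
    pas.index.name = "pathway"
    pas.columns.name = "sample"
    return pas.astype(float)


def write_pas_matrix(pas: pd.DataFrame, path: str | Path) -> None:
    pas.to_csv(path, sep="\t", index_label="pathway", float_format="%.10g")
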