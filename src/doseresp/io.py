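"""Spreadsheet ingest and result-table output.

Input is a long-format sheet (.csv or .xlsx, first sheet by default): one
row per (sample, drug, concentration) with one or more replicate response
columns.  Response columns are auto-detected as all headers starting with
the configured prefix (``response`` by default, case-insensitive), falling
back to every remaining numeric column.  All responses are converted to
percent inhibition on the way in.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conventions import PERCENT_INHIBITION, ResponseConvention, _convert_array
from .series import DoseResponseSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSchema",
    "SchemaError",
    "read_batch",
    "read_table",
    "series_from_frame",
    "write_results",
]


class SchemaError(ValueError):
    """The input sheet does not match the expected column layout."""


@dataclass(frozen=True)
class ColumnSchema:
    """Column names of the input sheet; override to map custom layouts."""

    sample: str = "sample"
    drug: str = "drug"
    concentration: str = "concentration"
    response_prefix: str = "response"


def read_table(path, sheet=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xls", ".xlsm"}:
        return pd.read_excel(path, sheet_name=sheet)
    return pd.read_csv(path)


def _find_column(df: pd.DataFrame, name: str) -> str:
    matches = [c for c in df.columns if str(c).strip().lower() == name.lower()]
    if not matches:
        raise SchemaError(f"missing required column '{name}'")
    return matches[0]


def _response_columns(df: pd.DataFrame, used: list, prefix: str) -> list:
    rest = [c for c in df.columns if c not in used]
    by_prefix = [c for c in rest if str(c).strip().lower().startswith(prefix.lower())]
    if by_prefix:
        return by_prefix
    numeric = [c for c in rest if pd.api.types.is_numeric_dtype(df[c])]
    if not numeric:
        raise SchemaError(
            f"no response columns found (no '{prefix}*' headers and no spare numeric columns)"
        )
    return numeric


def series_from_frame(
    df: pd.DataFrame,
    convention: ResponseConvention | None = None,
    schema: ColumnSchema | None = None,
) -> list:
    """Split a long-format frame into one series per (sample, drug) pair.

    Concentrations must be numeric, positive and unique within a series
    (duplicates would make the replicate structure ragged); responses are
    converted to percent inhibition, blank cells staying NaN.
    """
    convention = convention or PERCENT_INHIBITION
    schema = schema or ColumnSchema()
    col_sample = _find_column(df, schema.sample)
    col_drug = _find_column(df, schema.drug)
    col_conc = _find_column(df, schema.concentration)
    resp_cols = _response_columns(df, [col_sample, col_drug, col_conc], schema.response_prefix)

    conc = pd.to_numeric(df[col_conc], errors="coerce")
    bad = df.index[conc.isna() | (conc <= 0)]
    if len(bad) > 0:
        raise ValueError(
            f"non-positive or non-numeric concentration at row(s) {list(bad[:10])}"
        )

    resp = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float) for c in resp_cols]
    )
    resp = _convert_array(resp, convention)

    out = []
    for (sample, drug), idx in df.groupby([col_sample, col_drug], sort=True).groups.items():
        idx = np.asarray(idx)
        c = conc.loc[idx].to_numpy(dtype=float)
        if np.unique(c).size != c.size:
            raise ValueError(
                f"duplicate concentrations in series ({sample}, {drug}): "
                "replicates must be columns, not repeated rows"
            )
        pos = df.index.get_indexer(idx)
        out.append(
            DoseResponseSeries(
                sample_id=str(sample),
                drug_id=str(drug),
                concentrations=c,
                responses=resp[pos],
            )
        )
    return out


def read_batch(
    path,
    convention: ResponseConvention | None = None,
    schema: ColumnSchema | None = None,
    sheet=0,
) -> list:
    """Read a batch spreadsheet into dose-response series (percent inhibition)."""
    df = read_table(path, sheet=sheet)
    series = series_from_frame(df, convention=convention, schema=schema)
    logger.info("read %d series from %s", len(series), path)
    return series


RESULT_COLUMNS = [
    "sample",
    "drug",
    "status",
    "reason",
    "n_points",
    "n_replicates",
    "response_min",
    "response_max",
    "hillslope",
    "log10_ic50",
    "sse",
    "ic50_M",
    "neg_log10_ic50",
    "ic50_interp_M",
    "auc",
    "dss1",
    "dss2",
    "dss3",
    "xepto50",
    "r2",
    "adj_r2",
    "sy_x",
    "rmse",
    "shapiro_p",
    "explained_variance",
    "max_residual",
    "rmae",
    "mae",
    "mape",
    "low_quality",
]


def results_frame(records) -> pd.DataFrame:
    """One row per analysed series; non-convergent fits keep empty metric cells."""
    rows = []
    for rec in records:
        row = dict.fromkeys(RESULT_COLUMNS)
        row.update(
            sample=rec.series.sample_id,
            drug=rec.series.drug_id,
            status="ok" if rec.fit is not None and rec.fit.converged else "no_fit",
            reason=(rec.fit.reason if rec.fit is not None else rec.error) or "",
            n_points=rec.fit.n_points if rec.fit is not None else len(rec.series.concentrations),
            n_replicates=rec.series.n_replicates,
        )
        if rec.fit is not None and rec.fit.converged:
            row.update(
                response_min=rec.fit.response_min,
                response_max=rec.fit.response_max,
                hillslope=rec.fit.hillslope,
                log10_ic50=rec.fit.log10_ic50,
                sse=rec.fit.sse,
            )
            if rec.metrics is not None:
                row.update(rec.metrics.as_dict())
            if rec.quality is not None:
                row.update(rec.quality.as_dict())
            row["low_quality"] = rec.low_quality
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(records_or_frame, path) -> Path:
    """Write the result table as .csv or .xlsx (UTF-8)."""
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame
    else:
        df = results_frame(records_or_frame)
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, encoding="utf-8")
    return path
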