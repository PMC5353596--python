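"""Readers and writers for all on-disk artifacts.

Everything is plain text: TSV for matrices and tables (UTF-8, Unix
newlines, non-detects encoded as ``NA``), JSON for the manifest and
reports, YAML for configuration.  Every numeric output can carry a sidecar
``<name>.meta.json`` recording the parameters and seed that produced it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .ocr import SensorTrace, WellGeometry

TRACE_COLUMNS = ("time_min", "sensor_intensity", "reference_intensity")


# -- expression matrix --------------------------------------------------------


def read_expression_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x cells TSV; returns (matrix with NaN, non-detect mask).

    ``NA`` entries are non-detects.  Ragged rows and duplicate gene or cell
    ids are rejected with the offending line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    n_fields = len(lines[0].split("\t"))
    for ln, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != n_fields:
            raise DataError(f"{path}: ragged row at line {ln}")
    header = lines[0].split("\t")[1:]
    dup_cells = {c for c in header if header.count(c) > 1}
    if dup_cells:
        raise DataError(f"{path}: duplicated cell column(s) {sorted(dup_cells)} at line 1")
    seen: dict[str, int] = {}
    for ln, line in enumerate(lines[1:], start=2):
        gene = line.split("\t", 1)[0]
        if gene in seen:
            raise DataError(
                f"{path}: duplicated gene id {gene!r} at line {ln} (first at line {seen[gene]})"
            )
        seen[gene] = ln
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    df.index.name = "gene"
    mask = df.isna()
    return df, mask


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a genes x cells matrix as TSV with NaN encoded as ``NA``."""
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", lineterminator="\n")


# -- manifest -----------------------------------------------------------------


def read_manifest(path) -> pd.DataFrame:
    """Read a cell manifest JSON into a DataFrame (one row per cell)."""
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    df = pd.DataFrame(records)
    if "cell_id" not in df.columns:
        raise DataError(f"{path}: manifest records lack 'cell_id'")
    if df["cell_id"].duplicated().any():
        dups = df["cell_id"][df["cell_id"].duplicated()].tolist()
        raise DataError(f"{path}: duplicate cell ids {dups}")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    records = []
    for _, row in manifest.iterrows():
        rec = {}
        for key, val in row.items():
            if isinstance(val, (np.integer,)):
                val = int(val)
            elif isinstance(val, (np.floating,)):
                val = float(val)
            rec[key] = val
        records.append(rec)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- sensor traces ------------------------------------------------------------


def write_trace(trace: SensorTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_min": trace.times,
            "sensor_intensity": trace.sensor,
            "reference_intensity": trace.reference,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def read_trace(path, cell_id: str, well: WellGeometry | None = None) -> SensorTrace:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    return SensorTrace(
        cell_id=cell_id,
        times=df["time_min"].to_numpy(dtype=float),
        sensor=df["sensor_intensity"].to_numpy(dtype=float),
        reference=df["reference_intensity"].to_numpy(dtype=float),
        well=well or WellGeometry(),
    )


def read_traces(
    traces_dir, manifest: pd.DataFrame, well: WellGeometry | None = None
) -> tuple[list[SensorTrace], list[dict]]:
    """Load every manifest trace; per-file failures go to a QC report.

    Returns (traces, qc_report); a corrupted or missing file yields one QC
    entry instead of aborting the batch.  An empty directory returns an
    empty list with a warning.
    """
    traces_dir = Path(traces_dir)
    traces: list[SensorTrace] = []
    qc: list[dict] = []
    if "well_file" not in manifest.columns:
        raise DataError("manifest lacks a 'well_file' column")
    for _, row in manifest.iterrows():
        fp = traces_dir / row["well_file"]
        try:
            traces.append(read_trace(fp, cell_id=row["cell_id"], well=well))
        except (OSError, DataError, ValueError) as exc:
            qc.append({"cell_id": row["cell_id"], "file": str(fp), "error": str(exc)})
    if not traces:
        warnings.warn(f"no traces loaded from {traces_dir}", stacklevel=2)
    return traces, qc


# -- OCR table ----------------------------------------------------------------

OCR_TABLE_COLUMNS = (
    "cell_id",
    "cell_type",
    "strain",
    "ocr_fmol_min",
    "slope_uM_min",
    "r_squared",
    "respirer_class",
    "sealed",
)


def write_ocr_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_ocr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_id", "ocr_fmol_min", "respirer_class"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: OCR table missing column(s) {sorted(missing)}")
    return df


# -- generic helpers ----------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")


def write_sidecar(data_path, params: dict) -> Path:
    """Write ``<data_path>.meta.json`` recording provenance parameters."""
    meta_path = Path(str(data_path) + ".meta.json")
    write_json(params, meta_path)
    return meta_path
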