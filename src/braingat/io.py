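"""Reading and writing the pipeline's plain-text formats.

Time series are TSV/CSV with time on rows and ROIs on columns (an optional
header row names the ROIs); cohort manifests are CSV with columns
``subject_id, path, label, site``.  Square matrices (FC, adjacency) travel as
TSV with an ROI header plus a JSON sidecar recording provenance.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BoldTimeSeries
from .connectivity import AdjacencyMatrix

__all__ = ["load_timeseries", "load_manifest", "load_cohort",
           "write_matrix_tsv", "read_matrix_tsv", "write_adjacency",
           "read_adjacency"]


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_timeseries(path: str | Path, subject_id: str | None = None,
                    label: int | None = None, site: str = "",
                    transpose: bool = False) -> BoldTimeSeries:
    """Load one subject's T x N_roi matrix from TSV/CSV.

    The delimiter is sniffed from the extension (.csv -> comma, else tab).
    A first row that fails numeric parsing is treated as the header.  Ragged
    rows, non-numeric cells and empty files raise errors naming the offending
    line (1-based, header included).
    """
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim)]
    rows = [row for row in rows if any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: file is empty")
    start = 0
    try:
        [float(c) for c in rows[0]]
    except ValueError:
        start = 1   # header row
    if start == len(rows):
        raise ValueError(f"{path}: no data rows below the header")
    width = len(rows[start])
    data = []
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) != width:
            raise ValueError(
                f"{path}: line {lineno} has {len(row)} cells, expected {width}")
        try:
            data.append([float(c) for c in row])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell on line {lineno}") from exc
    values = np.asarray(data)
    if transpose:
        values = values.T
    return BoldTimeSeries(values=values,
                          subject_id=subject_id or path.stem,
                          label=label, site=site)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Validated cohort manifest: unique subject ids, existing files,
    binary labels."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "path", "label", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: labels must be 0 (TD) or 1 (ASD)")
    for p in df["path"]:
        full = Path(p) if Path(p).is_absolute() else path.parent / p
        if not full.exists():
            raise FileNotFoundError(f"{path}: referenced file {p} not found")
    return df


def load_cohort(manifest_path: str | Path,
                transpose: bool = False) -> list[BoldTimeSeries]:
    manifest_path = Path(manifest_path)
    df = load_manifest(manifest_path)
    cohort = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        cohort.append(load_timeseries(p, subject_id=row["subject_id"],
                                      label=int(row["label"]),
                                      site=str(row["site"]),
                                      transpose=transpose))
    return cohort


def write_matrix_tsv(values: np.ndarray, path: str | Path) -> None:
    n = values.shape[0]
    header = [f"roi_{i + 1:04d}" for i in range(n)]
    pd.DataFrame(values, columns=header).to_csv(path, sep="\t", index=False,
                                                float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_adjacency(adj: AdjacencyMatrix, path: str | Path,
                    extra: dict | None = None) -> None:
    """Adjacency TSV plus a `.json` sidecar with the threshold."""
    path = Path(path)
    write_matrix_tsv(adj.values, path)
    sidecar = {"threshold": adj.threshold, "n_roi": adj.n_roi,
               **(extra or {})}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_adjacency(path: str | Path) -> AdjacencyMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return AdjacencyMatrix(values=read_matrix_tsv(path),
                           threshold=float(sidecar["threshold"]))
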