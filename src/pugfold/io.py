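"""Table, FASTA and report I/O for the analysis pipeline.

Numeric series travel as two-column CSV/TSV files (delimiter by extension:
``.tsv`` tab, otherwise comma) with explicit headers per data type:
``wavelength_nm,theta_mdeg`` for CD scans, ``time_min,signal`` for folding
traces, ``time_h,integral`` for HDX, ``temp_C,signal`` for melts.
Structured results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class TableError(ValueError):
    """Raised for malformed or empty input tables."""


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a numeric table, validating header and values.

    The header must match ``columns`` exactly; rows with non-numeric or
    missing values are reported with their 1-based file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=_sep(path), dtype=str)
    except pd.errors.EmptyDataError:
        raise TableError(f"{path}: file is empty") from None
    if list(raw.columns) != list(columns):
        raise TableError(
            f"{path}: expected columns {list(columns)}, found {list(raw.columns)}")
    if raw.empty:
        raise TableError(f"{path}: no data rows")
    df = raw.apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header is line 1
        raise TableError(f"{path}: malformed rows at lines {lines}")
    return df.astype(float)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=False)


def jsonify(obj):
    """Recursively convert numpy scalars/arrays and dataclass-like objects
    into plain JSON-serializable Python values."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: jsonify(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj


def write_report(bundle: dict, path: str | Path) -> None:
    """Write a result bundle as stable, human-diffable JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(jsonify(bundle), indent=2, sort_keys=True) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(record_id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise TableError(f"{path}: no FASTA records")
    return records
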