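"""TSV readers and writers for the pipeline's on-disk formats.

All matrices travel as tab-separated text: first column ``gene_id``,
remaining columns sample IDs, gene-major (one row per gene).  Missing
values are encoded as ``NA``.  Writers prepend ``#``-comment header
lines carrying the tool version, seed and parameters so a run can be
reproduced from its outputs alone; readers skip such lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import InputError

NA_TOKEN = "NA"


def _metadata_header(metadata: dict | None) -> str:
    lines = [f"# emtscreen {__version__}"]
    for key, value in (metadata or {}).items():
        if isinstance(value, (dict, list, tuple)):
            value = json.dumps(value)
        lines.append(f"# {key}: {value}")
    return "".join(line + "\n" for line in lines)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples expression matrix.

    Returns a DataFrame indexed by ``gene_id`` with sample IDs as
    columns.  Duplicate gene IDs and non-numeric cells are rejected
    with messages naming the offenders.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if frame.shape[1] < 2 or frame.columns[0] != "gene_id":
        raise InputError(
            f"{path}: expected a header row starting with 'gene_id', "
            f"got columns {list(frame.columns[:3])}"
        )
    frame = frame.set_index("gene_id")
    dup = frame.index[frame.index.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"{path}: duplicate gene_id rows: {dup}")
    dup_cols = frame.columns[frame.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise InputError(f"{path}: duplicate sample columns: {dup_cols}")
    values = frame.replace(NA_TOKEN, np.nan)
    try:
        values = values.astype(float)
    except ValueError:
        # locate the first offending cell for the error message
        for col in values.columns:
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = values[col].notna() & coerced.isna()
            if bad.any():
                gene = values.index[bad.argmax()]
                raise InputError(
                    f"{path}: non-numeric value {values.at[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    return values


def write_expression_tsv(
    matrix: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(_metadata_header(metadata))
        out = matrix.copy()
        out.index.name = "gene_id"
        out.to_csv(handle, sep="\t", na_rep=NA_TOKEN)


def read_table_tsv(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    """Read a generic TSV table (survival, clinical, gene vector)."""
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN])
    if index_col is not None:
        if index_col not in frame.columns:
            raise InputError(f"{path}: missing required column {index_col!r}")
        frame = frame.set_index(index_col)
    return frame


def write_table_tsv(
    table: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(_metadata_header(metadata))
        table.to_csv(handle, sep="\t", na_rep=NA_TOKEN, index=index)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Read a survival table (``sample_id``, ``time``, ``event`` + covariates)."""
    frame = read_table_tsv(path, index_col="sample_id")
    for col in ("time", "event"):
        if col not in frame.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    return frame
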