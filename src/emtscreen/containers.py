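"""Shared in-memory containers.

Expression matrices are plain pandas DataFrames (genes as rows, samples
as columns); :func:`validate_expression_matrix` enforces the structural
invariants every stage assumes.  :class:`MicrodissectionSet` bundles the
paired micro-dissected epithelium and stroma compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError


def validate_expression_matrix(matrix: pd.DataFrame, name: str = "matrix") -> None:
    """Check uniqueness of gene/sample IDs and finiteness of values."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise InputError(f"{name}: duplicate gene IDs {dup}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise InputError(f"{name}: duplicate sample IDs {dup}")
    values = matrix.to_numpy(dtype=float, copy=False)
    if not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise InputError(f"{name}: {n_bad} non-finite values")


@dataclass
class MicrodissectionSet:
    """Paired epithelium and stroma expression from micro-dissected tumors.

    Both matrices share one gene universe; ``pairing`` lists the
    (epithelium sample, stroma sample) columns originating from the same
    specimen.  ``log2`` declares the scale of the stored values.
    """

    epithelium: pd.DataFrame
    stroma: pd.DataFrame
    pairing: list[tuple[str, str]] = field(default_factory=list)
    log2: bool = True

    def __post_init__(self) -> None:
        validate_expression_matrix(self.epithelium, "epithelium")
        validate_expression_matrix(self.stroma, "stroma")
        for epi, stro in self.pairing:
            if epi not in self.epithelium.columns:
                raise InputError(f"pairing references unknown epithelium sample {epi!r}")
            if stro not in self.stroma.columns:
                raise InputError(f"pairing references unknown stroma sample {stro!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def common_genes(self) -> pd.Index:
        return self.epithelium.index.intersection(self.stroma.index)
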