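"""Clinical association statistics and the table-one builder.

Categorical associations use the chi-square test in its
likelihood-ratio (G-test) form by default, without continuity
correction: 2 * sum O * ln(O / E), with 0 * ln(0) = 0 for empty cells.
Continuous variables use the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InputError

CHI2_METHODS = ("likelihood_ratio", "pearson")

#: Above this product of group sizes the Mann-Whitney p-value switches
#: from exact enumeration to the tie-corrected normal approximation.
MW_EXACT_LIMIT = 400


class Chi2Result(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def chi2_independence(table, method: str = "likelihood_ratio") -> Chi2Result:
    """Chi-square test of independence on an r x c contingency table.

    ``likelihood_ratio`` computes G = 2 * sum O * ln(O/E);
    ``pearson`` computes sum (O-E)^2 / E.  No continuity correction.
    """
    if method not in CHI2_METHODS:
        raise InputError(f"method must be one of {CHI2_METHODS}, got {method!r}")
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError(f"need an r x c table with r, c >= 2, got shape {counts.shape}")
    if (counts < 0).any() or counts.sum() <= 0:
        raise InputError("counts must be nonnegative with a positive total")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateInputError("zero row or column margin")
    lambda_ = "log-likelihood" if method == "likelihood_ratio" else "pearson"
    res = stats.chi2_contingency(counts, correction=False, lambda_=lambda_)
    return Chi2Result(float(res.statistic), int(res.dof), float(res.pvalue))


class MannWhitneyResult(NamedTuple):
    statistic: float
    pvalue: float


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p-value when the group-size product is small and the pooled
    data has no ties; tie-corrected normal approximation (no continuity
    correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= MW_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (64.25 -> 64.3), as printed tables use."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class TableOneReport:
    """Formatted per-variable comparison against a binary marker."""

    rows: pd.DataFrame
    marker_column: str
    n_negative: int
    n_positive: int
    chi2_method: str

    def to_markdown(self) -> str:
        header = (
            f"| Variable | {self.marker_column}-negative (n = {self.n_negative}) "
            f"| {self.marker_column}-positive (n = {self.n_positive}) | p value |\n"
            "|---|---|---|---|\n"
        )
        lines = []
        for _, row in self.rows.iterrows():
            p = "" if row["p_formatted"] is None else row["p_formatted"]
            lines.append(
                f"| {row['variable']}{': ' + row['level'] if row['level'] else ''} "
                f"| {row['negative']} | {row['positive']} | {p} |"
            )
        return header + "\n".join(lines)


def build_table_one(
    clinical: pd.DataFrame,
    marker: str,
    variables: Sequence[tuple[str, str]],
    chi2_method: str = "likelihood_ratio",
) -> TableOneReport:
    """Build a table-one: per variable, counts with row percentages and a
    chi-square p (categorical) or mean +- SD and a Mann-Whitney p
    (continuous), against binary marker status.

    ``variables`` is a list of (column, kind) with kind 'categorical' or
    'continuous'.  Percentages are half-up rounded to one decimal and p
    to three decimals in the formatted column; raw p is kept alongside.
    """
    if marker not in clinical.columns:
        raise InputError(f"marker column {marker!r} not in table")
    status = clinical[marker]
    levels = pd.unique(status.dropna())
    if len(levels) != 2:
        raise InputError(f"marker must be binary, found levels {list(levels)}")
    neg_level, pos_level = sorted(levels)
    negative = clinical[status == neg_level]
    positive = clinical[status == pos_level]

    rows = []
    for name, kind in variables:
        if name not in clinical.columns:
            raise InputError(f"variable {name!r} not in table")
        if kind == "continuous":
            p = mann_whitney(
                negative[name].dropna().to_numpy(), positive[name].dropna().to_numpy()
            ).pvalue
            rows.append(
                {
                    "variable": name,
                    "level": "",
                    "negative": f"{negative[name].mean():.1f} ± {negative[name].std():.1f}",
                    "positive": f"{positive[name].mean():.1f} ± {positive[name].std():.1f}",
                    "p_raw": p,
                    "p_formatted": f"{round_half_up(p, 3):.3f}",
                }
            )
        elif kind == "categorical":
            counts = pd.crosstab(clinical[name], status)
            counts = counts.reindex(columns=[neg_level, pos_level], fill_value=0)
            if counts.shape[0] < 2:
                p, p_fmt = np.nan, "NA"
            else:
                p = chi2_independence(counts.to_numpy(), chi2_method).pvalue
                p_fmt = f"{round_half_up(p, 3):.3f}"
            first = True
            for level, level_counts in counts.iterrows():
                total = int(level_counts.sum())
                cells = {}
                for col, key in ((neg_level, "negative"), (pos_level, "positive")):
                    n = int(level_counts[col])
                    pct = round_half_up(100.0 * n / total, 1) if total else 0.0
                    cells[key] = f"{n} ({pct:.1f})"
                rows.append(
                    {
                        "variable": name,
                        "level": str(level),
                        "negative": cells["negative"],
                        "positive": cells["positive"],
                        "p_raw": p if first else np.nan,
                        "p_formatted": p_fmt if first else None,
                    }
                )
                first = False
        else:
            raise InputError(f"variable kind must be categorical/continuous, got {kind!r}")
    return TableOneReport(
        rows=pd.DataFrame(rows),
        marker_column=marker,
        n_negative=len(negative),
        n_positive=len(positive),
        chi2_method=chi2_method,
    )


@dataclass
class InclusionAudit:
    """Cohort inclusion arithmetic with an audit trail."""

    total: int
    included: int
    exclusions: list[tuple[str, int]]

    def summary(self) -> str:
        lines = [f"total screened: {self.total}"]
        lines += [f"  excluded ({reason}): {count}" for reason, count in self.exclusions]
        lines.append(f"included: {self.included}")
        return "\n".join(lines)


def inclusion_filter(total: int, exclusions) -> InclusionAudit:
    """Included cohort size after subtracting each exclusion count.

    ``exclusions`` is a mapping reason -> count or a sequence of counts.
    """
    if isinstance(exclusions, dict):
        items = [(str(k), int(v)) for k, v in exclusions.items()]
    else:
        items = [(f"criterion {i + 1}", int(v)) for i, v in enumerate(exclusions)]
    if any(count < 0 for _, count in items):
        raise InputError("exclusion counts must be nonnegative")
    included = int(total) - sum(count for _, count in items)
    if included < 0:
        raise InputError(f"exclusions exceed the total cohort of {total}")
    return InclusionAudit(total=int(total), included=included, exclusions=items)
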