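"""Genome-wide prognostic screening and candidate selection.

Each gene's bulk expression is fitted in a univariable Cox model; the
Wald z-score (positive = adverse prognosis) joins the mesenchymal score
``MS`` and the stroma:epithelium log2 ratio ``L`` in the joint selection
rule for putative epithelium-expressed EMT mediators:

    MS > 0.3  and  L < 0  and  z > 1.96   (strict inequalities).

No multiple-testing adjustment is applied by default — the screen uses
the raw z > 1.96 rule — but a Benjamini-Hochberg mode is available for
users who want FDR control instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import validate_expression_matrix
from .exceptions import ConfigError, DegenerateInputError, InputError
from .survival import PartialLikelihood

TRANSFORMS = ("raw", "log2p1", "zscore")


@dataclass(frozen=True)
class SelectionThresholds:
    """Joint thresholds of the candidate-selection rule."""

    ms_min: float = 0.3
    log_ratio_max: float = 0.0
    z_min: float = 1.96

    def __post_init__(self) -> None:
        if not -1.0 < self.ms_min < 1.0:
            raise ConfigError(f"ms_min must lie in (-1, 1), got {self.ms_min}")


def prognostic_z_all(
    bulk: pd.DataFrame,
    survival: pd.DataFrame,
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Univariable Cox Wald z-score for every gene.

    ``transform`` is applied to each gene's expression before the fit
    (``log2p1`` = log2(x + 1) on linear-scale input; ``zscore``
    standardizes, which changes beta but not z).  Failed or degenerate
    fits are flagged in ``status``, never fatal.

    Returns a ZTable with columns ``beta``, ``se``, ``z``, ``status``.
    """
    validate_expression_matrix(bulk, "bulk")
    if transform not in TRANSFORMS:
        raise InputError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    missing = bulk.columns.difference(survival.index)
    if len(missing) == len(bulk.columns):
        raise InputError("no bulk samples present in survival table")
    if len(missing):
        raise InputError(f"bulk samples missing from survival table: {list(missing[:5])}")
    surv = survival.loc[bulk.columns]
    pl = PartialLikelihood(surv["time"].to_numpy(), surv["event"].to_numpy())

    values = bulk.to_numpy(dtype=float)
    if transform == "log2p1":
        if (values < 0).any():
            raise InputError("log2p1 transform requires nonnegative expression")
        values = np.log2(values + 1.0)
    elif transform == "zscore":
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=1, keepdims=True)) / sd

    values = values[:, pl.order]
    n_genes = values.shape[0]
    beta = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    status = np.full(n_genes, "ok", dtype=object)
    for i in range(n_genes):
        x = values[i]
        if np.ptp(x) == 0:
            status[i] = "constant"
            continue
        try:
            b, cov, _, _, _ = pl.fit(x)
        except DegenerateInputError:
            status[i] = "constant"
        except Exception as exc:  # noqa: BLE001 - per-gene fits must not abort the batch
            status[i] = f"failed:{type(exc).__name__}"
        else:
            beta[i], se[i] = b[0], np.sqrt(cov[0, 0])
    table = pd.DataFrame(
        {"beta": beta, "se": se, "z": beta / se, "status": status}, index=bulk.index
    )
    table.attrs["transform"] = transform
    table.attrs["n_events"] = pl.n_events
    return table


@dataclass
class CandidateGeneSet:
    """Genes passing the joint selection rule, with their metric triplets."""

    table: pd.DataFrame  # index gene_id; columns mesenchymal_score, log2_stroma_epi, cox_z
    thresholds: SelectionThresholds
    n_scored: int
    n_missing_metric: int
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)

    def summary(self) -> str:
        t = self.thresholds
        return (
            f"{len(self)} candidate genes of {self.n_scored} scored "
            f"(MS > {t.ms_min}, log2 stroma:epithelium < {t.log_ratio_max}, "
            f"Cox z > {t.z_min}; {self.n_missing_metric} genes lacked a metric)"
        )


def select_candidates(
    scores: pd.DataFrame,
    z_table: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
    fdr: float | None = None,
) -> CandidateGeneSet:
    """Apply the joint selection rule to the score and z tables.

    All three inequalities are strict; genes with any missing metric are
    excluded and counted.  With ``fdr`` set, the z criterion is replaced
    by Benjamini-Hochberg significance at that level (off by default).
    """
    common = scores.index.intersection(z_table.index)
    if len(common) == 0:
        raise InputError("score table and z table share no genes")
    ms = scores.loc[common, "mesenchymal_score"]
    length = scores.loc[common, "log2_stroma_epi"]
    z = z_table.loc[common, "z"]
    metrics = pd.DataFrame(
        {"mesenchymal_score": ms, "log2_stroma_epi": length, "cox_z": z}
    )
    usable = metrics.notna().all(axis=1)
    n_missing = int((~usable).sum())
    met = metrics[usable]
    if fdr is None:
        z_pass = met["cox_z"] > thresholds.z_min
    else:
        # one-sided adverse-prognosis p-values, BH-adjusted
        pvals = stats.norm.sf(met["cox_z"].to_numpy())
        z_pass = pd.Series(
            _benjamini_hochberg(pvals) < fdr, index=met.index
        )
    selected = (
        (met["mesenchymal_score"] > thresholds.ms_min)
        & (met["log2_stroma_epi"] < thresholds.log_ratio_max)
        & z_pass
    )
    return CandidateGeneSet(
        table=met[selected].copy(),
        thresholds=thresholds,
        n_scored=int(usable.sum()),
        n_missing_metric=n_missing,
        provenance={"fdr": fdr},
    )


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adjusted = np.empty(m)
    adjusted[order] = np.minimum.accumulate(
        (pvals[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    return np.minimum(adjusted, 1.0)


class ScoreZCorrelation(NamedTuple):
    r: float
    pvalue: float
    n: int


def score_prognosis_correlation(
    scores: pd.DataFrame, z_table: pd.DataFrame
) -> ScoreZCorrelation:
    """Pearson correlation between mesenchymal score and prognostic z
    across genes (the two-dimensional score-vs-prognosis summary)."""
    common = scores.index.intersection(z_table.index)
    ms = scores.loc[common, "mesenchymal_score"].to_numpy(dtype=float)
    z = z_table.loc[common, "z"].to_numpy(dtype=float)
    mask = np.isfinite(ms) & np.isfinite(z)
    if mask.sum() < 3:
        raise InputError("need >= 3 genes with both metrics")
    if np.ptp(ms[mask]) == 0 or np.ptp(z[mask]) == 0:
        raise DegenerateInputError("constant metric in score-prognosis correlation")
    result = stats.pearsonr(ms[mask], z[mask])
    return ScoreZCorrelation(float(result.statistic), float(result.pvalue), int(mask.sum()))


@dataclass
class RecoveryMetrics:
    """Confusion-matrix summary of candidate recovery against ground truth.

    Sensitivity = selected mediators / all planted mediators;
    precision = selected mediators / all selected (NaN when nothing is
    selected); specificity = non-selected non-mediators / all
    non-mediators, over the truth's gene universe.
    """

    sensitivity: float
    precision: float
    specificity: float
    n_true: int
    n_selected: int
    n_true_positive: int


def recovery_metrics(candidates: CandidateGeneSet, truth) -> RecoveryMetrics:
    """Compare a candidate set against the simulator's planted mediators."""
    selected = set(candidates.genes)
    true_set = set(truth.mediators)
    universe = set(truth.gene_role.index)
    if not selected <= universe:
        raise InputError("candidate genes not covered by truth")
    tp = len(selected & true_set)
    fp = len(selected - true_set)
    fn = len(true_set - selected)
    tn = len(universe) - tp - fp - fn
    return RecoveryMetrics(
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        precision=tp / (tp + fp) if (tp + fp) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        n_true=len(true_set),
        n_selected=len(selected),
        n_true_positive=tp,
    )
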