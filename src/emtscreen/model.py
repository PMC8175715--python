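"""Model-style front door for the whole screen.

:class:`EMTScreen` bundles the three datasets the method needs — a bulk
tumor expression matrix, paired micro-dissected epithelium/stroma
profiles, and per-sample survival — and :meth:`EMTScreen.fit` runs the
full procedure: stroma:epithelium log-ratio, genome-wide mesenchymal
scores, per-gene prognostic Cox z-scores, and the joint candidate
selection.  The returned :class:`EMTScreenResults` carries the per-gene
estimates and the downstream comparisons (marker-vs-random score test,
score-prognosis correlation, recovery against simulator truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MicrodissectionSet, validate_expression_matrix
from .exceptions import InputError
from .score import (
    GeneSetComparison,
    compare_gene_set_scores,
    mesenchymal_score,
    mesenchymal_score_all,
    stroma_epithelium_logfc,
)
from .screen import (
    CandidateGeneSet,
    RecoveryMetrics,
    ScoreZCorrelation,
    SelectionThresholds,
    prognostic_z_all,
    recovery_metrics,
    score_prognosis_correlation,
    select_candidates,
)


class EMTScreen:
    """Mesenchymal-score screen for epithelium-expressed EMT mediators.

    Parameters
    ----------
    bulk : DataFrame
        Genes x samples bulk tumor expression.  ``bulk_log2`` declares
        its scale; correlations are computed on log2(x + 1) values by
        default because expression correlations on the raw linear scale
        are dominated by the few highest-expressed genes.
    microdissection : MicrodissectionSet
        Paired pure epithelium / pure stroma profiles.
    survival : DataFrame
        ``time``/``event`` per bulk sample.
    """

    def __init__(
        self,
        bulk: pd.DataFrame,
        microdissection: MicrodissectionSet,
        survival: pd.DataFrame,
        bulk_log2: bool = True,
    ):
        validate_expression_matrix(bulk, "bulk")
        if not set(bulk.columns) <= set(survival.index):
            raise InputError("every bulk sample needs a survival row")
        self.bulk = bulk
        self.microdissection = microdissection
        self.survival = survival
        self.bulk_log2 = bulk_log2

    @classmethod
    def from_tsv(cls, bulk_path, epithelium_path, stroma_path, survival_path,
                 bulk_log2: bool = True) -> "EMTScreen":
        from .io import read_expression_tsv, read_survival_tsv

        epithelium = read_expression_tsv(epithelium_path)
        stroma = read_expression_tsv(stroma_path)
        micro = MicrodissectionSet(
            epithelium=epithelium,
            stroma=stroma,
            pairing=list(zip(epithelium.columns, stroma.columns)),
            log2=bulk_log2,
        )
        return cls(
            read_expression_tsv(bulk_path), micro, read_survival_tsv(survival_path),
            bulk_log2=bulk_log2,
        )

    def _correlation_matrix_input(self) -> pd.DataFrame:
        """Bulk values on the scale used for all correlation work."""
        if self.bulk_log2:
            return self.bulk
        return pd.DataFrame(
            np.log2(self.bulk.to_numpy(dtype=float) + 1.0),
            index=self.bulk.index,
            columns=self.bulk.columns,
        )

    def fit(
        self,
        pseudocount: float = 1.0,
        aggregation: str = "ratio_of_means",
        exclude_self: bool = True,
        transform: str = "log2p1",
        thresholds: SelectionThresholds = SelectionThresholds(),
    ) -> "EMTScreenResults":
        log_ratio = stroma_epithelium_logfc(
            self.microdissection, pseudocount=pseudocount, aggregation=aggregation
        )
        bulk_log = self._correlation_matrix_input()
        scores = mesenchymal_score_all(bulk_log, log_ratio, exclude_self=exclude_self)
        if self.bulk_log2 and transform == "log2p1":
            # bulk already on the log2 scale: a second log would distort it
            transform = "raw"
        z_table = prognostic_z_all(self.bulk, self.survival, transform=transform)
        candidates = select_candidates(scores, z_table, thresholds)
        return EMTScreenResults(
            model=self,
            log_ratio=log_ratio,
            scores=scores,
            z_table=z_table,
            candidates=candidates,
            thresholds=thresholds,
            params={
                "pseudocount": pseudocount,
                "aggregation": aggregation,
                "exclude_self": exclude_self,
                "transform": transform,
            },
        )

    def score_single(self, target_gene: str, pseudocount: float = 1.0,
                     aggregation: str = "ratio_of_means", exclude_self: bool = True):
        """Mesenchymal score of one gene (convenience wrapper)."""
        log_ratio = stroma_epithelium_logfc(
            self.microdissection, pseudocount=pseudocount, aggregation=aggregation
        )
        return mesenchymal_score(
            self._correlation_matrix_input(), log_ratio, target_gene,
            exclude_self=exclude_self,
        )


@dataclass
class EMTScreenResults:
    """Per-gene estimates and candidate set from a fitted screen."""

    model: EMTScreen
    log_ratio: pd.Series
    scores: pd.DataFrame
    z_table: pd.DataFrame
    candidates: CandidateGeneSet
    thresholds: SelectionThresholds
    params: dict = field(default_factory=dict)

    def gene_table(self) -> pd.DataFrame:
        """One row per gene: MS, L, Cox beta/se/z, selection flag."""
        table = self.scores.join(self.z_table[["beta", "se", "z", "status"]])
        table["selected"] = table.index.isin(self.candidates.table.index)
        return table

    def score_prognosis_correlation(self) -> ScoreZCorrelation:
        return score_prognosis_correlation(self.scores, self.z_table)

    def compare_marker_scores(
        self, marker_genes, k: int | None = None, n_rep: int = 20, seed=0
    ) -> GeneSetComparison:
        """Marker-set vs random-set mesenchymal-score comparison."""
        markers = [g for g in marker_genes if g in self.scores.index]
        if not markers:
            raise InputError("none of the marker genes are scored")
        return compare_gene_set_scores(
            self.scores, markers, k=k or len(markers), n_rep=n_rep, seed=seed
        )

    def recovery(self, truth) -> RecoveryMetrics:
        return recovery_metrics(self.candidates, truth)

    def plot_score_vs_prognosis(self, ax=None):
        """Scatter of prognostic z against mesenchymal score, candidates
        highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        table = self.gene_table().dropna(subset=["mesenchymal_score", "z"])
        ax.scatter(table["mesenchymal_score"], table["z"], s=6, c="grey", alpha=0.5,
                   label="all genes")
        sel = table[table["selected"]]
        ax.scatter(sel["mesenchymal_score"], sel["z"], s=12, c="crimson",
                   label="candidates")
        ax.axhline(self.thresholds.z_min, ls="--", lw=0.8, c="k")
        ax.axvline(self.thresholds.ms_min, ls="--", lw=0.8, c="k")
        ax.set_xlabel("mesenchymal score")
        ax.set_ylabel("prognostic z")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        corr = self.score_prognosis_correlation()
        n_genes = len(self.scores)
        n_scored = int(self.scores["mesenchymal_score"].notna().sum())
        lines = [
            "EMT mediator screen",
            "===================",
            f"genes: {n_genes} ({n_scored} scored), "
            f"bulk samples: {self.model.bulk.shape[1]}, "
            f"microdissection pairs: {self.model.microdissection.n_pairs}",
            f"log-ratio aggregation: {self.params.get('aggregation')}, "
            f"pseudocount: {self.params.get('pseudocount')}, "
            f"Cox transform: {self.params.get('transform')}",
            f"score-prognosis correlation: r = {corr.r:.3f} "
            f"(p = {corr.pvalue:.3g}, n = {corr.n})",
            self.candidates.summary(),
        ]
        top = self.candidates.table.sort_values("mesenchymal_score", ascending=False)
        if len(top):
            lines.append("top candidates:")
            lines.append(
                top.head(10).to_string(float_format=lambda v: f"{v:.3f}")
            )
        return "\n".join(lines)
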