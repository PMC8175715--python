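"""Mesenchymal-score computation.

The score of a target gene *g* measures how much its genome-wide bulk
co-expression profile looks like the stromal signature:

1. ``L(x)`` — log2 fold change of each gene *x* between micro-dissected
   cancer stroma and epithelium (the stromal signature axis).
2. ``r_g(x)`` — Pearson correlation, across bulk tumor samples, between
   the target gene *g* and every other gene *x* (the co-expression axis).
3. ``MS(g)`` — Pearson correlation, across genes *x*, between ``r_g(x)``
   and ``L(x)``.

A gene whose bulk neighbours are stroma-enriched genes scores high; a
gene that is itself epithelium-enriched (``L(g) < 0``) but still scores
high is the profile of an epithelium-expressed EMT mediator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MicrodissectionSet, validate_expression_matrix
from .exceptions import DegenerateInputError, InputError, InsufficientDataError

#: Known mesenchymal markers used for the marker-vs-random comparison.
KNOWN_MESENCHYMAL_MARKERS = (
    "VIM",
    "SNAI2",
    "ZEB1",
    "ZEB2",
    "TWIST1",
    "CDH2",
    "TGFB1",
    "FOXC2",
)


class ScoreResult(NamedTuple):
    score: float
    n_genes_used: int


def stroma_epithelium_logfc(
    micro: MicrodissectionSet,
    pseudocount: float = 1.0,
    aggregation: str = "ratio_of_means",
) -> pd.Series:
    """Per-gene log2 stroma : epithelium expression ratio ``L``.

    Ratios are formed on the linear scale (matrices declared log2 are
    un-logged first) after adding ``pseudocount``.  ``ratio_of_means``
    takes log2 of (mean stroma / mean epithelium); ``mean_of_ratios``
    averages the per-pair log2 ratios.  Genes with zero expression in
    both compartments (at pseudocount 0) come back as NaN.
    """
    if aggregation not in ("ratio_of_means", "mean_of_ratios"):
        raise InputError(f"unknown aggregation {aggregation!r}")
    if pseudocount < 0:
        raise InputError(f"pseudocount must be >= 0, got {pseudocount}")
    genes = micro.common_genes()
    if len(genes) == 0:
        raise InputError("epithelium and stroma share no genes")
    epi = micro.epithelium.loc[genes].to_numpy(dtype=float)
    stro = micro.stroma.loc[genes].to_numpy(dtype=float)
    if micro.log2:
        epi, stro = np.exp2(epi), np.exp2(stro)
    if (epi < 0).any() or (stro < 0).any():
        raise InputError("negative linear-scale expression values")
    with np.errstate(divide="ignore", invalid="ignore"):
        if aggregation == "ratio_of_means":
            values = np.log2(stro.mean(axis=1) + pseudocount) - np.log2(
                epi.mean(axis=1) + pseudocount
            )
        else:
            if micro.n_pairs == 0:
                raise InputError("mean_of_ratios requires an explicit pairing")
            epi_cols = [micro.epithelium.columns.get_loc(e) for e, _ in micro.pairing]
            stro_cols = [micro.stroma.columns.get_loc(s) for _, s in micro.pairing]
            ratios = np.log2(stro[:, stro_cols] + pseudocount) - np.log2(
                epi[:, epi_cols] + pseudocount
            )
            values = ratios.mean(axis=1)
    values = np.where(np.isfinite(values), values, np.nan)
    out = pd.Series(values, index=genes, name="log2_stroma_epi")
    out.attrs["aggregation"] = aggregation
    out.attrs["pseudocount"] = pseudocount
    return out


def _standardized_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize (mean 0, unit norm); returns (Z, constant_mask)."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    return centered / norms[:, None], constant


def correlation_profile(bulk: pd.DataFrame, target_gene: str) -> pd.Series:
    """Pearson correlation of ``target_gene`` with every gene across samples.

    Constant genes yield NaN; the target's self-correlation is returned
    as exactly 1.0 (callers decide whether to drop it).
    """
    validate_expression_matrix(bulk, "bulk")
    if target_gene not in bulk.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    if bulk.shape[1] < 3:
        raise InsufficientDataError("need >= 3 samples for correlation")
    values = bulk.to_numpy(dtype=float)
    z, constant = _standardized_rows(values)
    g = bulk.index.get_loc(target_gene)
    if constant[g]:
        raise DegenerateInputError(
            f"target gene {target_gene!r} is constant across samples"
        )
    r = z @ z[g]
    r = np.clip(r, -1.0, 1.0)
    r[constant] = np.nan
    r[g] = 1.0
    return pd.Series(r, index=bulk.index, name=f"r_{target_gene}")


def _score_from_vectors(r: np.ndarray, length: np.ndarray) -> ScoreResult:
    mask = np.isfinite(r) & np.isfinite(length)
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(f"only {n} usable gene pairs (< 2)")
    rr, ll = r[mask], length[mask]
    if np.ptp(ll) == 0:
        raise DegenerateInputError("log-ratio vector is constant on common genes")
    if np.ptp(rr) == 0:
        raise DegenerateInputError("correlation profile is constant on common genes")
    score = float(stats.pearsonr(rr, ll).statistic)
    return ScoreResult(score, n)


def mesenchymal_score(
    bulk: pd.DataFrame,
    log_ratio: pd.Series,
    target_gene: str,
    exclude_self: bool = True,
) -> ScoreResult:
    """Mesenchymal score of one target gene.

    Pearson correlation, across the genes common to ``bulk`` and the
    log-ratio vector, between the target's bulk co-expression profile
    and the stroma:epithelium log2 fold change.  With ``exclude_self``
    (default) the degenerate self pair ``(r=1, L(g))`` is omitted.
    """
    r = correlation_profile(bulk, target_gene)
    common = r.index.intersection(log_ratio.index)
    if len(common) == 0:
        raise InputError("bulk matrix and log-ratio vector share no genes")
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} genes common to bulk and log-ratio (< 3)"
        )
    r = r.loc[common]
    length = log_ratio.loc[common]
    if exclude_self and target_gene in common:
        keep = common != target_gene
        r, length = r[keep], length[keep]
    return _score_from_vectors(r.to_numpy(dtype=float), length.to_numpy(dtype=float))


def mesenchymal_score_all(
    bulk: pd.DataFrame,
    log_ratio: pd.Series,
    exclude_self: bool = True,
    block_size: int = 512,
) -> pd.DataFrame:
    """Mesenchymal score of every gene in the bulk matrix.

    Implemented as a standardized-matrix product (the full gene-gene
    correlation matrix in blocks, then a closed-form Pearson correlation
    of each row with ``L``), numerically equal to per-gene
    :func:`mesenchymal_score` calls.  Per-gene degeneracies are reported
    in the ``flags`` column rather than aborting the batch.

    Returns a ScoreTable: ``mesenchymal_score``, ``n_genes_used``,
    ``log2_stroma_epi`` and ``flags`` per bulk gene.
    """
    validate_expression_matrix(bulk, "bulk")
    if bulk.shape[1] < 3:
        raise InsufficientDataError("need >= 3 samples for correlation")
    genes = bulk.index
    common = genes.intersection(log_ratio.index)
    if len(common) == 0:
        raise InputError("bulk matrix and log-ratio vector share no genes")

    values = bulk.to_numpy(dtype=float)
    z, constant = _standardized_rows(values)

    flags = pd.Series("", index=genes, dtype=object)
    flags[constant] = "dropped_constant"
    in_l = genes.isin(log_ratio.index)
    flags[~in_l] += np.where(flags[~in_l] == "", "", ";") + "missing_in_logratio"

    # usable correlation columns: non-constant bulk genes with finite L
    length_full = log_ratio.reindex(genes).to_numpy(dtype=float)
    usable = (~constant) & np.isfinite(length_full)
    idx_usable = np.flatnonzero(usable)
    m = idx_usable.size
    length = length_full[idx_usable]
    s_l, s_ll = length.sum(), (length**2).sum()

    n_genes = len(genes)
    ms = np.full(n_genes, np.nan)
    n_used = np.zeros(n_genes, dtype=int)
    z_usable = z[idx_usable]
    pos_in_usable = np.full(n_genes, -1)
    pos_in_usable[idx_usable] = np.arange(m)

    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        rows = np.arange(start, stop)
        r_block = z[rows] @ z_usable.T  # correlations with usable genes
        np.clip(r_block, -1.0, 1.0, out=r_block)
        # exact self-correlation to mirror the single-gene path
        for j, g in enumerate(rows):
            p = pos_in_usable[g]
            if p >= 0:
                r_block[j, p] = 1.0
        s_r = r_block.sum(axis=1)
        s_rr = (r_block**2).sum(axis=1)
        s_rl = r_block @ length
        n_eff = np.full(rows.shape, float(m))
        bs_l, bs_ll = np.full(rows.shape, s_l), np.full(rows.shape, s_ll)
        if exclude_self:
            p = pos_in_usable[rows]
            has_self = p >= 0
            if has_self.any():
                self_l = length[p[has_self]]
                n_eff[has_self] -= 1
                s_r[has_self] -= 1.0
                s_rr[has_self] -= 1.0
                s_rl[has_self] -= self_l
                bs_l[has_self] -= self_l
                bs_ll[has_self] -= self_l**2
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n_eff * s_rl - s_r * bs_l
            var_r = n_eff * s_rr - s_r**2
            var_l = n_eff * bs_ll - bs_l**2
            block_ms = cov / np.sqrt(var_r * var_l)
        ok = (n_eff >= 2) & (var_r > 1e-300) & (var_l > 1e-300) & (~constant[rows])
        block_ms[~ok] = np.nan
        ms[rows] = np.clip(block_ms, -1.0, 1.0)
        n_used[rows] = np.where(ok, n_eff.astype(int), 0)

    table = pd.DataFrame(
        {
            "mesenchymal_score": ms,
            "n_genes_used": n_used,
            "log2_stroma_epi": length_full,
            "flags": flags,
        },
        index=genes,
    )
    table.attrs["exclude_self"] = exclude_self
    return table


@dataclass
class GeneSetComparison:
    """Result of comparing one gene set's scores against random draws."""

    per_rep_p: np.ndarray
    per_rep_genes: list[list[str]]
    fraction_significant: float
    median_p: float
    set_a: list[str]
    k: int

    def summary(self) -> str:
        return (
            f"{len(self.set_a)} marker genes vs {self.k} random genes, "
            f"{len(self.per_rep_p)} repetitions: median p = {self.median_p:.3g}, "
            f"fraction of repetitions with p < 0.05 = {self.fraction_significant:.2f}"
        )


def compare_gene_set_scores(
    scores: pd.DataFrame,
    set_a: Sequence[str],
    k: int = 8,
    n_rep: int = 20,
    seed: int | np.random.Generator = 0,
) -> GeneSetComparison:
    """Compare mesenchymal scores of a gene set against random gene sets.

    For each repetition, draws ``k`` genes uniformly without replacement
    from the scored genes outside ``set_a`` and applies a two-sided
    Mann-Whitney U test (exact for small draws) between the set's scores
    and the drawn scores.
    """
    from .clinical import mann_whitney

    if k < 1 or n_rep < 1:
        raise InputError("k and n_rep must be >= 1")
    scored = scores["mesenchymal_score"].dropna()
    set_a = list(set_a)
    missing = [g for g in set_a if g not in scored.index]
    if missing:
        raise InputError(f"set_a genes without scores: {missing}")
    pool = scored.index.difference(set_a)
    if k > len(pool):
        raise InputError(f"k={k} exceeds available pool of {len(pool)} genes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a_scores = scored.loc[set_a].to_numpy()
    p_values = np.empty(n_rep)
    drawn_sets: list[list[str]] = []
    for rep in range(n_rep):
        drawn = rng.choice(pool.to_numpy(), size=k, replace=False)
        drawn_sets.append(list(drawn))
        _, p_values[rep] = mann_whitney(a_scores, scored.loc[drawn].to_numpy())
    return GeneSetComparison(
        per_rep_p=p_values,
        per_rep_genes=drawn_sets,
        fraction_significant=float((p_values < 0.05).mean()),
        median_p=float(np.median(p_values)),
        set_a=set_a,
        k=k,
    )
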