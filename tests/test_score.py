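"""Mesenchymal-score operations against independent brute-force oracles
and on the synthetic cohort."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import emtscreen as es
from emtscreen.exceptions import (
    DegenerateInputError,
    InputError,
    InsufficientDataError,
)


def naive_pearson(x, y):
    """Textbook Pearson correlation, plain loops (oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def naive_mesenchymal_score(bulk, log_ratio, target, exclude_self=True):
    """Double-loop reference implementation of the score (oracle)."""
    rs, ls = [], []
    for gene in bulk.index:
        if exclude_self and gene == target:
            continue
        if gene not in log_ratio.index or not np.isfinite(log_ratio[gene]):
            continue
        x = bulk.loc[gene].tolist()
        if len(set(x)) == 1:
            continue
        rs.append(naive_pearson(bulk.loc[target].tolist(), x))
        ls.append(float(log_ratio[gene]))
    return naive_pearson(rs, ls), len(rs)


class TestLogfc:
    def test_identical_compartments_give_zero(self, micro_fixture):
        micro = es.MicrodissectionSet(
            micro_fixture.epithelium,
            micro_fixture.epithelium.rename(
                columns=dict(zip(micro_fixture.epithelium.columns, ["T1", "T2", "T3"]))
            ),
            micro_fixture.pairing,
            log2=False,
        )
        for agg in ("ratio_of_means", "mean_of_ratios"):
            log_ratio = es.stroma_epithelium_logfc(micro, pseudocount=0.0, aggregation=agg)
            np.testing.assert_allclose(log_ratio.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_stroma_gives_plus_one(self, micro_fixture):
        doubled = es.MicrodissectionSet(
            micro_fixture.epithelium,
            (2.0 * micro_fixture.epithelium).rename(
                columns=dict(zip(micro_fixture.epithelium.columns, ["T1", "T2", "T3"]))
            ),
            micro_fixture.pairing,
            log2=False,
        )
        for agg in ("ratio_of_means", "mean_of_ratios"):
            log_ratio = es.stroma_epithelium_logfc(doubled, pseudocount=0.0, aggregation=agg)
            np.testing.assert_allclose(log_ratio.to_numpy(), 1.0, atol=1e-12)

    def test_integer_fixture_matches_hand_calculation(self, micro_fixture):
        """4 genes x 3 pairs with pseudocount 1, both aggregation modes,
        against a spreadsheet-style reference computation."""
        epi = micro_fixture.epithelium.to_numpy()
        stro = micro_fixture.stroma.to_numpy()
        expected_rom = [
            math.log2((sum(s) / 3 + 1) / (sum(e) / 3 + 1))
            for e, s in zip(epi.tolist(), stro.tolist())
        ]
        expected_mor = [
            sum(math.log2((s + 1) / (e + 1)) for e, s in zip(erow, srow)) / 3
            for erow, srow in zip(epi.tolist(), stro.tolist())
        ]
        rom = es.stroma_epithelium_logfc(micro_fixture, 1.0, "ratio_of_means")
        mor = es.stroma_epithelium_logfc(micro_fixture, 1.0, "mean_of_ratios")
        np.testing.assert_allclose(rom.to_numpy(), expected_rom, atol=1e-12)
        np.testing.assert_allclose(mor.to_numpy(), expected_mor, atol=1e-12)

    def test_zero_in_both_compartments_flagged_missing(self):
        genes = ["G1", "G2"]
        epi = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=genes, columns=["E1", "E2"])
        stro = pd.DataFrame([[0.0, 0.0], [2.0, 4.0]], index=genes, columns=["T1", "T2"])
        micro = es.MicrodissectionSet(epi, stro, [("E1", "T1"), ("E2", "T2")], log2=False)
        log_ratio = es.stroma_epithelium_logfc(micro, pseudocount=0.0)
        assert np.isnan(log_ratio["G1"]) and np.isfinite(log_ratio["G2"])

    def test_disjoint_gene_universes_rejected(self, micro_fixture):
        other = micro_fixture.stroma.rename(index=lambda g: g + "_x")
        micro = es.MicrodissectionSet(micro_fixture.epithelium, other, [], log2=False)
        with pytest.raises(InputError):
            es.stroma_epithelium_logfc(micro)


class TestCorrelationProfile:
    def test_self_and_negated_gene(self, fixture_a):
        mat = fixture_a.copy()
        mat.loc["G6"] = -mat.loc["G1"]
        r = es.correlation_profile(mat, "G1")
        assert r["G1"] == 1.0
        assert abs(r["G6"] + 1.0) < 1e-12

    def test_matches_naive_loop(self, fixture_a):
        r = es.correlation_profile(fixture_a, "G1")
        for gene in fixture_a.index:
            expected = naive_pearson(
                fixture_a.loc["G1"].tolist(), fixture_a.loc[gene].tolist()
            )
            assert abs(r[gene] - expected) < 1e-12

    def test_independent_genes_decorrelated(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(
            rng.standard_normal((2, 10000)), index=["G1", "G2"],
            columns=[f"S{i}" for i in range(10000)],
        )
        assert abs(es.correlation_profile(mat, "G1")["G2"]) < 0.05

    def test_constant_target_rejected(self, fixture_a):
        mat = fixture_a.copy()
        mat.loc["G1"] = 5.0
        with pytest.raises(DegenerateInputError):
            es.correlation_profile(mat, "G1")

    def test_unknown_gene_raises_key_error(self, fixture_a):
        with pytest.raises(KeyError):
            es.correlation_profile(fixture_a, "NOPE")


class TestMesenchymalScore:
    def test_two_point_score_is_exactly_one(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.standard_normal((3, 8)),
            index=["G1", "G2", "G3"],
            columns=[f"S{i}" for i in range(8)],
        )
        r = es.correlation_profile(mat, "G1")
        # choose L increasing with r(G2), r(G3): two points -> Pearson +1
        lo, hi = sorted([("G2", r["G2"]), ("G3", r["G3"])], key=lambda kv: kv[1])
        log_ratio = pd.Series({lo[0]: -1.0, hi[0]: 2.0, "G1": 0.0})
        result = es.mesenchymal_score(mat, log_ratio, "G1")
        assert result.n_genes_used == 2
        assert abs(result.score - 1.0) < 1e-12

    def test_constant_logratio_rejected(self, fixture_a):
        log_ratio = pd.Series(0.5, index=fixture_a.index)
        with pytest.raises(DegenerateInputError):
            es.mesenchymal_score(fixture_a, log_ratio, "G1")

    def test_too_few_genes_rejected(self, fixture_a, fixture_a_logratio):
        with pytest.raises(InsufficientDataError):
            es.mesenchymal_score(fixture_a.iloc[:2], fixture_a_logratio.iloc[:2], "G1")

    @pytest.mark.parametrize("exclude_self", [True, False])
    def test_fixture_matches_naive_double_loop(
        self, fixture_a, fixture_a_logratio, exclude_self
    ):
        for target in fixture_a.index:
            got = es.mesenchymal_score(
                fixture_a, fixture_a_logratio, target, exclude_self=exclude_self
            )
            want, n = naive_mesenchymal_score(
                fixture_a, fixture_a_logratio, target, exclude_self=exclude_self
            )
            assert got.n_genes_used == n
            assert abs(got.score - want) < 1e-12


class TestMesenchymalScoreAll:
    @pytest.mark.parametrize("exclude_self", [True, False])
    def test_batch_equals_looped_single_calls(
        self, fixture_a, fixture_a_logratio, exclude_self
    ):
        table = es.mesenchymal_score_all(
            fixture_a, fixture_a_logratio, exclude_self=exclude_self
        )
        for gene in fixture_a.index:
            single = es.mesenchymal_score(
                fixture_a, fixture_a_logratio, gene, exclude_self=exclude_self
            )
            assert abs(table.loc[gene, "mesenchymal_score"] - single.score) < 1e-10
            assert table.loc[gene, "n_genes_used"] == single.n_genes_used

    def test_batch_equals_loop_on_synthetic(self, default_run):
        scores = default_run["scores"]
        bulk, log_ratio = default_run["bulk"], default_run["log_ratio"]
        rng = np.random.default_rng(1)
        for gene in rng.choice(bulk.index.to_numpy(), 15, replace=False):
            single = es.mesenchymal_score(bulk, log_ratio, gene)
            assert abs(scores.loc[gene, "mesenchymal_score"] - single.score) < 1e-10

    def test_scores_bounded(self, default_run):
        ms = default_run["scores"]["mesenchymal_score"].dropna()
        assert ms.between(-1.0, 1.0).all()

    def test_constant_gene_flagged_not_fatal(self, fixture_a, fixture_a_logratio):
        mat = fixture_a.copy()
        mat.loc["G2"] = 3.0
        table = es.mesenchymal_score_all(mat, fixture_a_logratio)
        assert np.isnan(table.loc["G2", "mesenchymal_score"])
        assert "dropped_constant" in table.loc["G2", "flags"]
        assert np.isfinite(table.loc["G1", "mesenchymal_score"])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        scale=st.floats(min_value=0.05, max_value=20.0),
        shift=st.floats(min_value=-50.0, max_value=50.0),
        row=st.integers(min_value=0, max_value=4),
    )
    def test_affine_rescaling_of_one_gene_is_invariant(self, scale, shift, row):
        """Positive affine rescaling of any single gene's bulk row leaves
        every mesenchymal score unchanged (Pearson invariance)."""
        from conftest import FIXTURE_A_L, FIXTURE_A_VALUES

        bulk = pd.DataFrame(
            FIXTURE_A_VALUES,
            index=[f"G{i}" for i in range(1, 6)],
            columns=[f"S{i}" for i in range(1, 7)],
        )
        log_ratio = FIXTURE_A_L
        base = es.mesenchymal_score_all(bulk, log_ratio)["mesenchymal_score"]
        rescaled = bulk.copy()
        rescaled.iloc[row] = scale * rescaled.iloc[row] + shift
        new = es.mesenchymal_score_all(rescaled, log_ratio)["mesenchymal_score"]
        np.testing.assert_allclose(new.to_numpy(), base.to_numpy(), atol=1e-10)

    def test_sample_reordering_is_invariant(self, fixture_a, fixture_a_logratio):
        base = es.mesenchymal_score_all(fixture_a, fixture_a_logratio)
        shuffled = fixture_a[["S4", "S1", "S6", "S2", "S5", "S3"]]
        new = es.mesenchymal_score_all(shuffled, fixture_a_logratio)
        np.testing.assert_allclose(
            new["mesenchymal_score"].to_numpy(),
            base["mesenchymal_score"].to_numpy(),
            atol=1e-12,
        )


def exact_mann_whitney_two_sided(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group-label
    assignments (oracle; feasible up to ~8 per group)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = pd.Series(pooled).rank().tolist()
    observed = sum(ranks[:n_a]) - n_a * (n_a + 1) / 2
    n_total = len(pooled)
    us = []
    for combo in itertools.combinations(range(n_total), n_a):
        u = sum(ranks[i] for i in combo) - n_a * (n_a + 1) / 2
        us.append(u)
    us = np.array(us)
    n_b = n_total - n_a
    lo = (us <= observed).mean()
    hi = (us >= observed).mean()
    return min(1.0, 2 * min(lo, hi))


class TestGeneSetComparison:
    def test_dominant_set_reaches_exact_minimal_p(self, default_run):
        """If the marker set's scores all exceed every other score, each
        repetition's p equals the exact minimal two-sided 8-vs-8 p."""
        scores = default_run["scores"].copy()
        markers = list(scores.index[:8])
        scores.loc[:, "mesenchymal_score"] = np.linspace(-0.5, 0.5, len(scores))
        scores.loc[markers, "mesenchymal_score"] = np.linspace(0.9, 0.99, 8)
        comp = es.compare_gene_set_scores(scores, markers, k=8, n_rep=5, seed=3)
        expected = exact_mann_whitney_two_sided(range(8), range(-8, 0))
        np.testing.assert_allclose(comp.per_rep_p, expected, atol=1e-12)
        assert abs(expected - 2.0 / math.comb(16, 8)) < 1e-12

    def test_null_set_false_positive_rate(self):
        """A marker set drawn fresh from the background each repetition is
        significant in ~5% of 500 repetitions (binomial tolerance).  The
        set must be redrawn per repetition: with a fixed set the
        repetitions share its sampling fluctuation and are correlated."""
        rng = np.random.default_rng(77)
        scores = pd.DataFrame(
            {"mesenchymal_score": rng.standard_normal(400)},
            index=[f"G{i}" for i in range(400)],
        )
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            set_a = list(rng.choice(scores.index.to_numpy(), 8, replace=False))
            comp = es.compare_gene_set_scores(scores, set_a, k=8, n_rep=1, seed=rng)
            hits += comp.per_rep_p[0] < 0.05
        assert 0.02 <= hits / n_rep <= 0.09

    def test_fixed_seed_reproducible_draw(self, default_run):
        scores = default_run["scores"]
        markers = default_run["truth"].archetypes[:8]
        a = es.compare_gene_set_scores(scores, markers, k=8, n_rep=1, seed=4)
        b = es.compare_gene_set_scores(scores, markers, k=8, n_rep=1, seed=4)
        assert a.per_rep_genes == b.per_rep_genes
        assert a.per_rep_p[0] == b.per_rep_p[0]

    def test_oversized_draw_rejected(self, fixture_a, fixture_a_logratio):
        scores = es.mesenchymal_score_all(fixture_a, fixture_a_logratio)
        with pytest.raises(InputError):
            es.compare_gene_set_scores(scores, ["G1"], k=10)


class TestSyntheticStructure:
    def test_stromal_and_mediator_scores_exceed_background(self, default_run):
        """Desk-scale analogue of the marker-vs-random comparison: planted
        mediators and stromal archetypes score far above background."""
        scores, truth = default_run["scores"], default_run["truth"]
        ms = scores["mesenchymal_score"]
        background = truth.genes_with_role("epithelial_background")
        assert ms[truth.archetypes].mean() > ms[background].mean()
        _, p = es.mann_whitney(
            ms[truth.mediators].dropna().to_numpy(), ms[background].dropna().to_numpy()
        )
        assert p < 1e-3
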