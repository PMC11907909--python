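"""Gene scoring: median pooling, KS oracles, BH, hit classes, ranks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen import (
    AnalysisConfig,
    LibraryDesign,
    aggregate_gene_scores,
    bh_adjust,
    gene_ks_pvalue,
    score_genes,
)
from poolscreen.genescore import filter_and_call, rank_significant, volcano_table


def _sgrna_table(entries):
    """entries: list of (guide, gene, replicate, logfc)."""
    return pd.DataFrame(entries, columns=["guide", "gene", "replicate", "logfc"])


class TestAggregation:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1.0, 2.0, 5.0], 2.0),
            ([1.0, 2.0, 3.0, 10.0], 2.5),
        ],
    )
    def test_median_conventions(self, values, expected):
        lib = LibraryDesign({f"g{i}": "A" for i in range(len(values))})
        tab = _sgrna_table([(f"g{i}", "A", "t1", v) for i, v in enumerate(values)])
        out = aggregate_gene_scores(tab, lib)
        assert out.loc["A", "crispr_score"] == pytest.approx(expected)
        assert out.loc["A", "n_guides"] == len(values)

    def test_pooling_across_replicates(self):
        lib = LibraryDesign({"g1": "A", "g2": "A"})
        tab = _sgrna_table(
            [("g1", "A", "t1", 0.5), ("g2", "A", "t1", 1.5), ("g1", "A", "t2", 2.5)]
        )
        out = aggregate_gene_scores(tab, lib)
        assert out.loc["A", "crispr_score"] == pytest.approx(1.5)
        assert out.loc["A", "n_guides"] == 3

    def test_order_and_replicate_label_invariance(self):
        lib = LibraryDesign({"g1": "A", "g2": "A", "g3": "A"})
        rows = [("g1", "A", "t1", 3.0), ("g2", "A", "t2", 1.0), ("g3", "A", "t1", 2.0)]
        a = aggregate_gene_scores(_sgrna_table(rows), lib)
        b = aggregate_gene_scores(_sgrna_table(rows[::-1]), lib)
        swapped = [(g, gene, {"t1": "t2", "t2": "t1"}[r], v) for g, gene, r, v in rows]
        c = aggregate_gene_scores(_sgrna_table(swapped), lib)
        assert a.loc["A", "crispr_score"] == b.loc["A", "crispr_score"] == c.loc["A", "crispr_score"]

    def test_gene_without_values_marked_for_filtering(self):
        lib = LibraryDesign({"g1": "A", "g2": "B"})
        tab = _sgrna_table([("g1", "A", "t1", 1.0)])
        out = aggregate_gene_scores(tab, lib)
        assert out.loc["B", "n_guides"] == 0
        assert np.isnan(out.loc["B", "crispr_score"])


def ks_enumeration_oracle(x, y):
    """Exact two-sided two-sample KS p by enumerating all label assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def ks_d(a, b):
        grid = np.sort(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    d_obs = ks_d(x, y)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        if ks_d(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestKsPvalue:
    def test_identical_samples_give_p_one(self):
        assert gene_ks_pvalue([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_fully_separated_triplets(self):
        # D = 1; 2 of the C(6,3)=20 assignments reach it -> p = 0.1
        p = gene_ks_pvalue([0.1, 0.2, 0.3], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert ks_enumeration_oracle([0.1, 0.2, 0.3], [10.0, 11.0, 12.0]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n,m,seed", [(3, 5, 0), (4, 6, 1), (5, 5, 2), (8, 7, 3)])
    def test_exact_p_matches_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(0.5, 1.2, size=m)
        assert gene_ks_pvalue(x, y) == pytest.approx(ks_enumeration_oracle(x, y), abs=1e-10)

    def test_asymptotic_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(0.3, 1.0, size=30)
        p_asymp = gene_ks_pvalue(x, y, exact_n_limit=10)
        # vectorized permutation oracle, 100,000 draws
        pooled = np.concatenate([x, y])
        order = np.argsort(pooled)
        v = pooled[order]
        n_perm = 100_000
        rand = rng.random((n_perm, 60))
        member = np.argsort(np.argsort(rand, axis=1), axis=1) < 30  # random 30-subsets
        member = member[:, np.argsort(order)][:, order]  # align to sorted values
        fa = np.cumsum(member, axis=1) / 30
        fb = np.cumsum(~member, axis=1) / 30
        d_perm = np.max(np.abs(fa - fb), axis=1)

        def ks_d(a, b):
            grid = np.sort(pooled)
            return np.max(
                np.abs(
                    np.searchsorted(np.sort(a), grid, side="right") / 30
                    - np.searchsorted(np.sort(b), grid, side="right") / 30
                )
            )

        d_obs = ks_d(x, y)
        p_perm = np.mean(d_perm >= d_obs - 1e-12)
        assert p_asymp == pytest.approx(p_perm, abs=0.02)

    def test_asymptotic_converges_to_exact(self):
        # the Kolmogorov limit differs from the exact p by ~0.05 at
        # n = m = 50 and the gap shrinks as n grows
        rng = np.random.default_rng(12)
        gaps = {}
        for n in (50, 400):
            x, y = rng.normal(size=n), rng.normal(size=n)
            p_exact = gene_ks_pvalue(x, y, exact_n_limit=10**6)
            p_asymp = gene_ks_pvalue(x, y, exact_n_limit=10)
            gaps[n] = abs(p_exact - p_asymp)
        assert gaps[50] <= 0.06
        assert gaps[400] <= 0.02


def bh_oracle(p):
    """Sorted-formula BH: q_i = min_{j>=i}(p_j m / j), back in input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBhAdjust:
    def test_direct_formula_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_sorted_formula_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(1000)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=50))
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all()
        i, j = np.argsort(p)[0], np.argsort(p)[-1]
        assert q[i] <= q[j] + 1e-15


def _gene_table(rows):
    df = pd.DataFrame(rows, columns=["gene", "n_guides", "crispr_score", "p_value"])
    return df.set_index("gene")


class TestFilterAndCall:
    CFG = AnalysisConfig()

    def test_low_guide_gene_filtered_and_out_of_bh(self):
        table = _gene_table(
            [("A", 2, 5.0, 0.001), ("B", 5, 1.0, 0.02), ("C", 5, 0.2, 0.04)]
        )
        out = filter_and_call(table, self.CFG)
        assert out.loc["A", "hit_class"] == "filtered"
        assert pd.isna(out.loc["A", "fdr"])
        # BH family has m=2: fdr_B = 0.02*2/1 = 0.04, fdr_C = 0.04*2/2 = 0.04
        assert out.loc["B", "fdr"] == pytest.approx(0.04)
        assert out.loc["C", "fdr"] == pytest.approx(0.04)

    @pytest.mark.parametrize(
        "cs,p,expected",
        [
            (2.0, 1e-4, "strong_enriched"),
            (0.8, 1e-4, "enriched"),
            (-1.0, 1e-4, "depleted_significant"),
            (8.0, 0.9, "not_significant"),
        ],
    )
    def test_hit_classes(self, cs, p, expected):
        table = _gene_table([("X", 5, cs, p), ("Y", 5, 0.0, 0.99)])
        out = filter_and_call(table, self.CFG)
        assert out.loc["X", "hit_class"] == expected

    def test_fdr_dominates_p_elementwise(self):
        rng = np.random.default_rng(4)
        rows = [(f"G{i}", 5, 0.0, p) for i, p in enumerate(rng.random(50))]
        out = filter_and_call(_gene_table(rows), self.CFG)
        assert (out["fdr"] >= out["p_value"] - 1e-15).all()


class TestRankSignificant:
    CFG = AnalysisConfig()

    def test_rank_by_cs_descending(self):
        table = _gene_table(
            [("A", 5, 5.0, 1e-5), ("B", 5, 3.0, 1e-5), ("C", 5, 1.0, 1e-5), ("D", 5, 9.0, 0.9)]
        )
        out = rank_significant(filter_and_call(table, self.CFG), self.CFG)
        assert list(out.loc[["A", "B", "C"], "rank"]) == [1, 2, 3]
        assert pd.isna(out.loc["D", "rank"])

    def test_tie_breaks_by_smaller_p_then_symbol(self):
        table = _gene_table(
            [("B", 5, 2.0, 0.01), ("A", 5, 2.0, 0.001), ("C", 5, 2.0, 0.01)]
        )
        out = rank_significant(filter_and_call(table, self.CFG), self.CFG)
        assert out.loc["A", "rank"] == 1  # smaller p wins
        assert out.loc["B", "rank"] == 2  # then lexicographic
        assert out.loc["C", "rank"] == 3

    def test_max_cs_gene_gets_rank_one(self):
        rng = np.random.default_rng(8)
        rows = [(f"G{i}", 5, cs, 1e-6) for i, cs in enumerate(rng.normal(size=20))]
        out = rank_significant(filter_and_call(_gene_table(rows), self.CFG), self.CFG)
        top = out["crispr_score"].idxmax()
        assert out.loc[top, "rank"] == 1


class TestScoreGenesEndToEnd:
    def test_shifted_gene_detected(self):
        rng = np.random.default_rng(5)
        lib = LibraryDesign(
            {f"g{i}_{k}": f"GENE{i}" for i in range(40) for k in range(5)}
        )
        rows = []
        for i in range(40):
            for k in range(5):
                for rep in ("t1", "t2"):
                    shift = 4.0 if i == 0 else 0.0
                    rows.append((f"g{i}_{k}", f"GENE{i}", rep, rng.normal(shift, 0.3)))
        out = score_genes(_sgrna_table(rows), lib)
        assert out.loc["GENE0", "hit_class"] == "strong_enriched"
        assert out.loc["GENE0", "rank"] == 1
        assert (out.drop("GENE0").fillna({"fdr": 1.0})["fdr"] > 0.05).all()

    def test_volcano_table_axes(self):
        rng = np.random.default_rng(6)
        lib = LibraryDesign({f"g{i}": f"GENE{i // 4}" for i in range(20)})
        rows = [
            (f"g{i}", f"GENE{i // 4}", "t1", rng.normal()) for i in range(20)
        ]
        out = score_genes(_sgrna_table(rows), lib)
        vt = volcano_table(out)
        assert set(vt.columns) == {"gene", "crispr_score", "neg_log10_fdr"}
        merged = vt.set_index("gene")["neg_log10_fdr"]
        np.testing.assert_allclose(
            merged, -np.log10(out.loc[merged.index, "fdr"]), atol=1e-12
        )
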