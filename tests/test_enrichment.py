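"""Hypergeometric overlap test, BH adjustment, tiers and display order."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact

from cernet.enrichment import (
    Background,
    EnrichmentTable,
    adjust_pvalues,
    enrichment_dotplot,
    hypergeom_overlap_p,
    module_display_order,
    module_enrichment,
    overlap_contingency,
    significance_tier,
)
from cernet.model import CoexpressionNetwork, ModulePartition

from conftest import bh_stepup, hypergeom_tail_enumerate, hypergeom_tail_exact


def _net(partition: dict, condition="c") -> CoexpressionNetwork:
    return CoexpressionNetwork({}, ModulePartition(partition, condition), condition)


class TestContingency:
    def test_basic_counts(self):
        bg = Background({f"g{i}" for i in range(10)})
        table = overlap_contingency({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, bg)
        assert table == (2, 1, 1, 6)

    def test_disjoint(self):
        bg = Background({f"g{i}" for i in range(10)})
        a = {"g0", "g1", "g2"}
        b = {"g3", "g4", "g5"}
        assert overlap_contingency(a, b, bg) == (0, 3, 3, 4)

    def test_full_overlap_degenerate(self):
        genes = {"g0", "g1", "g2", "g3"}
        assert overlap_contingency(genes, genes, Background(genes)) == (4, 0, 0, 0)

    def test_gene_outside_background_named(self):
        bg = Background({"g0", "g1"})
        with pytest.raises(ValueError, match="g9"):
            overlap_contingency({"g0", "g9"}, {"g1"}, bg)

    @given(
        st.integers(2, 20).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.sets(st.integers(0, 19).filter(lambda i: i < n), max_size=20),
                st.sets(st.integers(0, 19).filter(lambda i: i < n), max_size=20),
            )
        )
    )
    def test_entries_nonnegative_and_sum_to_n(self, case):
        n, ia, ib = case
        bg = Background({f"g{i}" for i in range(n)})
        a = {f"g{i}" for i in ia}
        b = {f"g{i}" for i in ib}
        table = overlap_contingency(a, b, bg)
        assert all(x >= 0 for x in table)
        assert sum(table) == n


class TestHypergeomP:
    def test_k_zero_is_one(self):
        assert hypergeom_overlap_p(0, 7, 4, 20) == 1.0

    def test_full_overlap_half_universe(self):
        """k=a=b=5 of N=10: only one favourable draw among C(10,5)."""
        p = hypergeom_overlap_p(5, 5, 5, 10)
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_worked_tail_sum(self):
        """k=3,a=4,b=5,N=20: [C(4,3)C(16,2)+C(4,4)C(16,1)]/C(20,5)."""
        p = hypergeom_overlap_p(3, 4, 5, 20)
        assert p == pytest.approx(496 / 15504, rel=1e-12)
        assert p == pytest.approx(3.20e-2, abs=5e-4)

    def test_matches_fisher_greater(self):
        """Equals Fisher's exact one-sided p on the 2x2 table."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = int(rng.integers(1, n + 1))
            b = int(rng.integers(1, n + 1))
            k = int(rng.integers(max(0, a + b - n), min(a, b) + 1))
            table = [[k, a - k], [b - k, n - a - b + k]]
            expected = fisher_exact(table, alternative="greater")[1]
            assert hypergeom_overlap_p(k, a, b, n) == pytest.approx(
                expected, rel=1e-9
            )

    def test_matches_literal_enumeration(self):
        """Exact over all C(N,b) draws for a small grid."""
        for n in (4, 6, 8, 10):
            for a in range(n + 1):
                for b in range(n + 1):
                    for k in range(min(a, b) + 1):
                        assert hypergeom_overlap_p(k, a, b, n) == pytest.approx(
                            hypergeom_tail_enumerate(k, a, b, n), abs=1e-12
                        )

    def test_symmetry_and_monotonicity(self):
        for (a, b, n) in [(4, 9, 20), (7, 7, 15), (3, 12, 25)]:
            prev = 1.0 + 1e-15
            for k in range(min(a, b) + 1):
                p = hypergeom_overlap_p(k, a, b, n)
                assert p == pytest.approx(hypergeom_overlap_p(k, b, a, n), rel=1e-12)
                assert p <= prev
                prev = p

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_p(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_overlap_p(1, 11, 5, 10)


class TestAdjustPvalues:
    def test_single_value_identity(self):
        assert adjust_pvalues([0.03]) == [pytest.approx(0.03)]

    def test_all_tied_by_stepup(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_two_values(self):
        assert adjust_pvalues([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80),
        st.randoms(use_true_random=False),
    )
    def test_matches_stepup_formula_and_invariants(self, p, rnd):
        """BH output equals the direct step-up formula; q in [p, 1];
        permutation-equivariant."""
        q = adjust_pvalues(p)
        expected = bh_stepup(p)
        assert q == pytest.approx(expected, rel=1e-12, abs=1e-15)
        for pi, qi in zip(p, q):
            assert pi - 1e-12 <= qi <= 1.0 + 1e-12
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = adjust_pvalues([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], rel=1e-12, abs=1e-15)


class TestTiers:
    @pytest.mark.parametrize(
        "q,tier,style",
        [
            (3.23e-7, "***", "green"),
            (0.005, "**", "gold"),
            (0.03, "*", "yellow"),
            (0.5, "NE", "+"),
            (0.001, "**", "gold"),  # strict inequality at the boundary
            (0.05, "NE", "+"),
        ],
    )
    def test_tier_mapping(self, q, tier, style):
        assert significance_tier(q) == (tier, style)


class TestDisplayOrder:
    def test_canonical_sequence(self):
        part = ModulePartition(
            {"g1": "red", "g2": "blue", "g3": "turquoise"}, "c"
        )
        assert module_display_order(part) == ["turquoise", "blue", "red"]

    def test_single_module(self):
        part = ModulePartition({"g1": "tan"}, "c")
        assert module_display_order(part) == ["tan"]

    def test_noncanonical_by_size_then_name(self):
        part = ModulePartition(
            {f"g{i}": "zebra" for i in range(10)}
            | {f"h{i}": "aqua" for i in range(5)},
            "c",
        )
        assert module_display_order(part) == ["zebra", "aqua"]

    def test_hyphenated_greenyellow_is_canonical(self):
        part = ModulePartition({"g1": "green-yellow", "g2": "tan"}, "c")
        assert module_display_order(part) == ["green-yellow", "tan"]


class TestModuleEnrichment:
    def test_identical_partitions_diagonal(self):
        """Identical 3x30 partitions: diagonal ***, off-diagonal k=0 NE."""
        assignment = {}
        for mi, label in enumerate(["turquoise", "blue", "brown"]):
            for i in range(30):
                assignment[f"AT1G{mi*30+i:05d}"] = label
        net_a = _net(assignment, "a")
        net_b = _net(dict(assignment), "b")
        table = module_enrichment(net_a, net_b)
        assert len(table.cells) == 9
        for c in table.cells:
            if c.module_a == c.module_b:
                assert c.overlap_k == 30
                assert c.tier == "***"
                # oracle: P(X >= 30) with a=b=30, N=90
                assert c.p_value == pytest.approx(
                    hypergeom_tail_exact(30, 30, 30, 90), rel=1e-9
                )
            else:
                assert c.overlap_k == 0
                assert c.tier == "NE"
                assert c.p_value == 1.0

    def test_disjoint_universes_all_null(self):
        net_a = _net({f"AT1G{i:05d}": "blue" for i in range(20)}, "a")
        net_b = _net({f"AT2G{i:05d}": "blue" for i in range(20)}, "b")
        table = module_enrichment(net_a, net_b)
        assert all(c.overlap_k == 0 and c.p_value == 1.0 for c in table.cells)

    def test_thirteen_by_thirteen_gives_169_cells(self):
        labels = [f"mod{i:02d}" for i in range(13)]
        a = {f"AT1G{i:05d}": labels[i % 13] for i in range(260)}
        b = {f"AT1G{i:05d}": labels[(i + 3) % 13] for i in range(260)}
        table = module_enrichment(_net(a, "a"), _net(b, "b"))
        assert len(table.cells) == 169

    def test_grey_excluded_by_default(self):
        a = {"g1": "blue", "g2": "grey"}
        b = {"g1": "blue", "g2": "grey"}
        table = module_enrichment(_net(a, "a"), _net(b, "b"))
        assert {c.module_a for c in table.cells} == {"blue"}
        table2 = module_enrichment(
            _net(a, "a"), _net(b, "b"), exclude_unassigned=False
        )
        assert {c.module_a for c in table2.cells} == {"blue", "grey"}

    def test_adjustment_is_one_family(self):
        """Adjusted values equal BH over the flattened cell p-values."""
        rng = np.random.default_rng(3)
        genes = [f"AT1G{i:05d}" for i in range(200)]
        a = {g: f"a{rng.integers(0, 4)}" for g in genes}
        b = {g: f"b{rng.integers(0, 4)}" for g in genes}
        table = module_enrichment(_net(a, "a"), _net(b, "b"))
        expected = bh_stepup([c.p_value for c in table.cells])
        assert [c.adjusted_p for c in table.cells] == pytest.approx(expected)


class TestNullCalibration:
    def test_rejection_rate_matches_discrete_attained_level(self):
        """Under independent random partitions the observed fraction of
        raw p < 0.05 matches the exact attained level of the discrete
        test, E[sum pmf(k) over k with P(X>=k) < 0.05], cell by cell."""
        from scipy.stats import hypergeom
        from cernet.model import CoexpressionNetwork
        from cernet.synthetic import random_partition

        rng = np.random.default_rng(314)
        genes = [f"AT1G{i:05d}" for i in range(1, 2001)]
        observed = expected = n_cells = 0
        for _ in range(50):
            part_a = random_partition(genes, rng, condition_name="a")
            part_b = random_partition(genes, rng, condition_name="b")
            table = module_enrichment(
                CoexpressionNetwork({}, part_a, "a"),
                CoexpressionNetwork({}, part_b, "b"),
            )
            for c in table.cells:
                n_cells += 1
                observed += c.p_value < 0.05
                ks = np.arange(0, min(c.size_a, c.size_b) + 1)
                sf = hypergeom.sf(ks - 1, c.background_n, c.size_a, c.size_b)
                pmf = hypergeom.pmf(ks, c.background_n, c.size_a, c.size_b)
                expected += pmf[sf < 0.05].sum()
        assert abs(observed / n_cells - expected / n_cells) < 0.02


class TestDotplot:
    def _table(self):
        a = {f"AT1G{i:05d}": ("turquoise" if i < 30 else "blue") for i in range(60)}
        return module_enrichment(_net(a, "a"), _net(dict(a), "b"))

    def test_tsv_in_display_order(self, tmp_path):
        table = self._table()
        png = tmp_path / "dot.png"
        tsv = tmp_path / "dot.tsv"
        df = enrichment_dotplot(table, png, tsv_path=tsv)
        assert png.exists() and tsv.exists()
        assert len(df) == 4
        assert list(df["module_a"]) == [
            "turquoise", "turquoise", "blue", "blue"
        ]
        assert list(df["module_b"]) == ["turquoise", "blue", "turquoise", "blue"]

    def test_empty_table_raises(self, tmp_path):
        table = EnrichmentTable(cells=[], row_order=[], col_order=[])
        with pytest.raises(ValueError):
            enrichment_dotplot(table, tmp_path / "x.png")
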