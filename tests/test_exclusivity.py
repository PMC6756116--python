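"""Pathway selection, Fisher exclusivity, pair backgrounds, and the network."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famdriver import (
    ContingencyTable,
    PathwayForest,
    PathwayNode,
    PositionKey,
    ShuffleSpec,
    build_contingency,
    build_network,
    cooccurrence_with_drivers,
    exclusivity_scan,
    fisher_exclusivity,
    map_catalog,
    network_to_edges,
    pair_background,
    select_pathways,
)


def _forest(*nodes, roots):
    return PathwayForest({n.pathway_id: n for n in nodes},
                         [n for n in nodes if n.pathway_id in roots])


def _node(pid, size, children=()):
    return PathwayNode(pid, pid, frozenset(f"{pid}_g{i}" for i in range(size)),
                       children=list(children))


class TestSelectPathways:
    def test_small_root_selected_directly(self):
        root = _node("R", 180)
        assert [n.pathway_id for n in select_pathways(_forest(root, roots={"R"}))] == ["R"]

    def test_large_root_descends_to_children(self):
        child = _node("C", 299)
        root = _node("R", 250, children=[child])
        selected = select_pathways(_forest(root, child, roots={"R"}))
        assert [n.pathway_id for n in selected] == ["C"]

    def test_recurses_through_oversized_child(self):
        grand = _node("GC", 100)
        child = _node("C", 350, children=[grand])
        root = _node("R", 250, children=[child])
        selected = select_pathways(_forest(root, child, grand, roots={"R"}))
        assert [n.pathway_id for n in selected] == ["GC"]

    def test_oversized_leaf_kept(self):
        root = _node("R", 500)
        assert [n.pathway_id for n in select_pathways(_forest(root, roots={"R"}))] == ["R"]


class TestContingency:
    def test_disjoint_sets(self):
        universe = {f"s{i}" for i in range(100)}
        a = {f"s{i}" for i in range(5)}
        b = {f"s{i}" for i in range(5, 10)}
        t = build_contingency(a, b, universe)
        assert (t.n_both, t.n_a_only, t.n_b_only, t.n_neither) == (0, 5, 5, 90)
        assert t.total == 100

    def test_identical_sets(self):
        a = {"s1", "s2"}
        t = build_contingency(a, a, {"s1", "s2", "s3"})
        assert (t.n_both, t.n_a_only, t.n_b_only) == (2, 0, 0)

    def test_universe_exactly_covered(self):
        t = build_contingency({"s1"}, {"s2"}, {"s1", "s2"})
        assert t.n_neither == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_contingency({"s1"}, {"s2"}, set())

    def test_cclass_mismatch_rejected(self):
        with pytest.raises(ValueError, match="class mismatch"):
            build_contingency({"s1"}, {"s2"}, {"s1", "s2"},
                              "conserved", "nonconserved")


def _hypergeom_tail_oracle(table):
    """Exact-integer enumeration of P(overlap <= n_both) given the margins."""
    N = table.total
    K = table.n_both + table.n_a_only
    n = table.n_both + table.n_b_only
    denom = math.comb(N, n)
    num = sum(math.comb(K, k) * math.comb(N - K, n - k)
              for k in range(0, table.n_both + 1) if n - k <= N - K)
    return num / denom


class TestFisher:
    def test_textbook_table(self):
        t = ContingencyTable(0, 5, 5, 90)
        expected = math.comb(95, 5) / math.comb(100, 5)
        assert fisher_exclusivity(t) == pytest.approx(expected, abs=1e-12)

    def test_full_tail_is_one(self):
        # overlap at its margin maximum: whole lower tail
        t = ContingencyTable(3, 0, 2, 5)
        assert fisher_exclusivity(t) == pytest.approx(1.0)

    def test_symmetry_under_swap(self):
        t = ContingencyTable(2, 7, 4, 30)
        swapped = ContingencyTable(2, 4, 7, 30)
        assert fisher_exclusivity(t) == pytest.approx(fisher_exclusivity(swapped))

    def test_oracle_agreement_small_tables(self):
        for N in range(1, 13):
            for a in range(N + 1):
                for b in range(N + 1 - a):
                    for c in range(N + 1 - a - b):
                        t = ContingencyTable(a, b, c, N - a - b - c)
                        assert fisher_exclusivity(t) == pytest.approx(
                            _hypergeom_tail_oracle(t), abs=1e-12)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(1, 8))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_probability_bounds(self, a, b, c, d):
        p = fisher_exclusivity(ContingencyTable(a, b, c, d))
        assert 0.0 < p <= 1.0


class TestPairBackground:
    def test_unmutated_pathway_is_null(self, planted_pair_data):
        _, dm, cols, cat, _, _ = planted_pair_data
        empty = PathwayNode("E", "empty", frozenset({"not_a_gene"}))
        key_a = PositionKey("F01", 10, "conserved")
        key_b = PositionKey("F02", 20, "conserved")
        p, obs, n = pair_background(key_a, key_b, empty, cat, dm, cols, ShuffleSpec())
        assert (p, obs, n) == (1.0, 0, 0)

    def test_planted_pair_is_extreme_and_deterministic(self, planted_pair_data):
        _, dm, cols, cat, _, forest = planted_pair_data
        pathway = forest["P01"]
        key_a = PositionKey("F01", 10, "conserved")
        key_b = PositionKey("F02", 20, "conserved")
        spec = ShuffleSpec(n_shuffles=50, seed=4)
        p1, obs, n = pair_background(key_a, key_b, pathway, cat, dm, cols, spec)
        p2, _, _ = pair_background(key_a, key_b, pathway, cat, dm, cols, spec)
        assert p1 == p2
        assert obs >= 60          # the planted alleles
        assert p1 < 1e-10


def _scan(planted_pair_data, universe_rule="same_class", enriched=None):
    from famdriver import enrich_positions, select_pathways as sel
    cfg, dm, cols, cat, truth, forest = planted_pair_data
    scope = cat.scopes()[0]
    if enriched is None:
        enriched = enrich_positions(cat, dm, cols, scope, ShuffleSpec(seed=cfg.seed))
    pathways = sel(forest)
    result = exclusivity_scan(cat, dm, cols, enriched, pathways, scope,
                              shuffle_spec=ShuffleSpec(seed=cfg.seed),
                              universe_rule=universe_rule)
    return scope, enriched, result


class TestScan:
    def test_planted_pair_retained(self, planted_pair_data):
        _, _, result = _scan(planted_pair_data)
        assert len(result) >= 1
        row = result.iloc[0]
        assert (row.family_a, row.column_a, row.family_b, row.column_b) == \
            ("F01", 10, "F02", 20)
        assert row.fisher_q <= 0.1 and row.pair_q <= 0.1 and row.retained
        # counts sum to the universe used for the test
        assert row.n_both + row.n_a_only + row.n_b_only + row.n_neither > 0

    def test_no_shared_pathway_no_test(self, planted_pair_data):
        cfg, dm, cols, cat, truth, forest = planted_pair_data
        # pathways that separate the two families
        p1 = PathwayNode("X1", "x1", dm.family_genes("F01"))
        p2 = PathwayNode("X2", "x2", dm.family_genes("F02"))
        from famdriver import enrich_positions
        scope = cat.scopes()[0]
        enriched = enrich_positions(cat, dm, cols, scope, ShuffleSpec(seed=cfg.seed))
        result = exclusivity_scan(cat, dm, cols, enriched, [p1, p2], scope,
                                  shuffle_spec=ShuffleSpec(seed=cfg.seed))
        assert len(result) == 0

    def test_min_samples_excludes_sparse_positions(self, planted_pair_data):
        cfg, dm, cols, cat, truth, forest = planted_pair_data
        scope, enriched, _ = _scan(planted_pair_data)
        # force a sparsely mutated column to "significant" and confirm the
        # five-unique-sample rule still keeps it out of the pairing
        sparse = enriched[(enriched.n_samples > 0) & (enriched.n_samples < 5)
                          & (enriched.cclass == "conserved")]
        assert len(sparse) > 0
        forced = enriched.copy()
        forced.loc[sparse.index[:1], "significant"] = True
        from famdriver import select_pathways as sel
        result = exclusivity_scan(cat, dm, cols, forced, sel(forest), scope,
                                  shuffle_spec=ShuffleSpec(seed=cfg.seed))
        fams_cols = set(zip(result.family_a, result.column_a)) | \
            set(zip(result.family_b, result.column_b))
        forced_key = (sparse.iloc[0].family_id, sparse.iloc[0].column)
        assert forced_key not in fams_cols

    def test_result_symmetric_in_pair_order(self, planted_pair_data):
        _, _, result = _scan(planted_pair_data)
        row = result.iloc[0]
        # the table itself is symmetric: swapping roles swaps only labels
        swapped = ContingencyTable(row.n_both, row.n_b_only, row.n_a_only, row.n_neither)
        assert fisher_exclusivity(swapped) == pytest.approx(row.fisher_p)


class TestDriverCooccurrence:
    def _positions(self):
        return {PositionKey("F1", 3, "conserved"): frozenset({"s1", "s2", "s3"})}

    def test_disjoint_alteration_gives_small_p(self):
        driver = pd.DataFrame(
            [(f"s{i}", "TP53", "nonsynonymous", "TSG") for i in range(4, 10)],
            columns=["sample_id", "gene", "alteration_class", "category"])
        universe = {f"s{i}" for i in range(1, 10)}
        out = cooccurrence_with_drivers(self._positions(), driver, universe)
        assert len(out) == 1
        expected = math.comb(3, 3) / math.comb(9, 3)  # P(no overlap at margins)
        assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-12)

    def test_saturated_driver_is_null(self):
        driver = pd.DataFrame(
            [(f"s{i}", "KRAS", "CNV", "oncogene") for i in range(1, 6)],
            columns=["sample_id", "gene", "alteration_class", "category"])
        out = cooccurrence_with_drivers(
            {PositionKey("F1", 3, "conserved"): frozenset({"s1", "s2"})}, driver)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_driver_table(self):
        out = cooccurrence_with_drivers(self._positions(), pd.DataFrame())
        assert len(out) == 0


class TestNetwork:
    def _result_row(self, fam_a="F1", fam_b="F2", retained=True):
        return {
            "scope": "pan-cancer", "family_a": fam_a, "column_a": 1,
            "family_b": fam_b, "column_b": 2, "cclass": "conserved",
            "pathway_id": "P1", "pathway_size": 10, "most_specific": True,
            "n_both": 0, "n_a_only": 5, "n_b_only": 5, "n_neither": 90,
            "n_samples_a": 5, "n_samples_b": 5,
            "fisher_p": 0.001, "fisher_q": 0.01, "pair_observed": 10,
            "pair_n_trials": 100, "pair_p": 0.001, "pair_q": 0.01,
            "retained": retained,
        }

    def _hits(self):
        return pd.DataFrame({
            "family_id": ["F1", "F1", "F2"], "column": [1, 1, 2],
            "cclass": ["conserved"] * 3, "sample_id": ["s1", "s2", "s3"],
            "gene": ["g1", "g1", "g2"], "position": [1, 1, 2],
            "mclass": ["missense"] * 3, "tissue": ["T"] * 3,
            "histology": ["H"] * 3, "cancer_type": ["T/H"] * 3})

    def test_single_edge(self):
        g = build_network(pd.DataFrame([self._result_row()]), self._hits())
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.nodes["F1"]["n_samples"] == 2
        edges = network_to_edges(g)
        assert edges.loc[0, ["family_a", "family_b"]].tolist() == ["F1", "F2"]

    def test_intramolecular_self_loop(self):
        g = build_network(pd.DataFrame([self._result_row(fam_b="F1")]), self._hits())
        assert g.number_of_nodes() == 1
        assert g.has_edge("F1", "F1")

    def test_nothing_retained_empty_graph(self):
        g = build_network(pd.DataFrame([self._result_row(retained=False)]), self._hits())
        assert g.number_of_nodes() == 0
        assert len(network_to_edges(g)) == 0
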