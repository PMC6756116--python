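"""Enrichment statistics: expectations, shuffles, binomial tail, BH-FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from famdriver import (
    DomainInstance,
    DomainMap,
    ShuffleSpec,
    SyntheticConfig,
    bh_fdr,
    binomial_enrichment,
    enrich_positions,
    expected_count,
    generate_mutations,
    generate_proteome,
    log_odds,
    shuffle_background,
)
from famdriver.enrichment import estimate_priors, prior_from_counts

from conftest import make_catalog, make_columns


class TestExpectedCount:
    def test_arithmetic(self):
        assert expected_count(100, 1000, 10) == 1.0

    def test_no_instances(self):
        assert expected_count(100, 1000, 0) == 0.0

    def test_genome_scale_magnitudes(self):
        assert expected_count(4.6e6, 1.1e7, 6) == pytest.approx(2.509, abs=0.001)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            expected_count(100, 0, 1)


class TestLogOdds:
    def test_doubling(self):
        assert log_odds(4, 2) == 1.0

    def test_identity(self):
        assert log_odds(3.5, 3.5) == 0.0

    def test_zero_observed(self):
        assert log_odds(0, 2) == float("-inf")

    def test_bad_expected_warns_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(log_odds(3, 0))


class TestPrior:
    def test_zero_hits(self):
        assert prior_from_counts(0, 100, 1000) == pytest.approx(0.5 / 100001)

    def test_every_shuffle_hits(self):
        assert prior_from_counts(100, 100, 1) == pytest.approx(100.5 / 101)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            prior_from_counts(0, 100, 0)

    @given(hits=st.integers(0, 10_000), n_shuffles=st.integers(1, 1000),
           n_trials=st.integers(1, 10_000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_inside_unit_interval(self, hits, n_shuffles, n_trials):
        prior = prior_from_counts(min(hits, n_shuffles * n_trials), n_shuffles, n_trials)
        assert 0.0 < prior < 1.0


class TestBinomialTail:
    def test_zero_observed_is_one(self):
        assert binomial_enrichment(0, 10, 0.3) == 1.0

    def test_two_of_two_fair(self):
        assert binomial_enrichment(2, 2, 0.5) == pytest.approx(0.25)

    def test_all_successes_closed_form(self):
        assert binomial_enrichment(10, 10, 0.1) == pytest.approx(1e-10, rel=1e-9)

    def test_matches_pmf_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            prior = float(rng.uniform(0.01, 0.99))
            obs = int(rng.integers(0, n + 1))
            direct = sum(math.comb(n, k) * prior ** k * (1 - prior) ** (n - k)
                         for k in range(obs, n + 1))
            assert binomial_enrichment(obs, n, prior) == pytest.approx(direct, abs=1e-12)


def _bh_brute(p):
    """Independent step-up oracle: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    s = p[order]
    crit = m * s / np.arange(1, m + 1)
    q_sorted = np.array([crit[i:].min() for i in range(m)])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhFdr:
    def test_uniform_ladder(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_against_brute_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert np.max(np.abs(bh_fdr(p) - _bh_brute(p))) <= 1e-12

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _toy_shuffle_inputs():
    dm = DomainMap([DomainInstance.from_offset("G1", "F1", 3, 6)],
                   gene_lengths={"G1": 10, "G2": 8})
    cat = make_catalog([
        ("s1", "G1", 1, "A", "V", "missense"),
        ("s1", "G1", 4, "A", "V", "missense"),
        ("s1", "G1", 9, "A", "*", "stop_gain"),
        ("s2", "G2", 2, "A", "V", "missense"),
    ])
    return dm, cat


class TestShuffleBackground:
    def test_per_sample_protein_counts_conserved(self):
        dm, cat = _toy_shuffle_inputs()
        before = cat.nonsynonymous().groupby(["sample_id", "gene"]).size()
        for shuffled in shuffle_background(cat, dm, ShuffleSpec(n_shuffles=25, seed=1)):
            after = shuffled.groupby(["sample_id", "gene"]).size()
            assert before.equals(after)
            assert (shuffled["position"] >= 1).all()

    def test_domain_aware_keeps_instance_membership(self):
        dm, cat = _toy_shuffle_inputs()
        spec = ShuffleSpec(model="domain_aware", n_shuffles=50, seed=2)
        inside = set(range(3, 7))
        for shuffled in shuffle_background(cat, dm, spec):
            g1 = shuffled[shuffled.gene == "G1"].sort_values("position")
            started_inside = {4}
            now_inside = set(g1["position"]) & inside
            # exactly one G1 mutation started inside the instance: one stays in
            assert len(now_inside) == len(started_inside)

    def test_missing_length_rejected(self):
        dm = DomainMap([DomainInstance.from_offset("G1", "F1", 3, 6)],
                       gene_lengths={"G1": 10})
        cat = make_catalog([("s1", "GX", 2, "A", "V", "missense")])
        with pytest.raises(ValueError, match="length missing"):
            list(shuffle_background(cat, dm, ShuffleSpec(n_shuffles=1)))

    def test_single_mutation_uniform_over_protein(self):
        dm = DomainMap([DomainInstance.from_offset("G1", "F1", 1, 10)],
                       gene_lengths={"G1": 10})
        cat = make_catalog([("s1", "G1", 1, "A", "V", "missense")])
        counts = np.zeros(11)
        for shuffled in shuffle_background(cat, dm, ShuffleSpec(n_shuffles=10_000, seed=3)):
            counts[shuffled["position"].iloc[0]] += 1
        # binomial(10000, 0.1): 3 sigma ~ 90
        assert np.all(np.abs(counts[1:] - 1000) < 90)


def test_priors_deterministic_and_positive(planted_pair_data):
    _, dm, cols, cat, _, _ = planted_pair_data
    spec = ShuffleSpec(n_shuffles=20, seed=9)
    priors1, n1 = estimate_priors(cat, dm, cols, spec)
    priors2, n2 = estimate_priors(cat, dm, cols, spec)
    assert n1 == n2 == cat.n_alleles()
    assert priors1.equals(priors2)
    assert ((priors1 > 0) & (priors1 < 1)).all()


class TestEnrichmentCalling:
    """Retention floors and significance rules on engineered catalogs."""

    @staticmethod
    def _single_column_setup(n_hits, scope_label="T/H"):
        dm = DomainMap([DomainInstance.from_offset("G1", "F1", 1, 10)],
                       gene_lengths={"G1": 100})
        cols = make_columns([("F1", c, "A", 0.7) for c in range(1, 11)])
        rows = [(f"s{i}", "G1", 5, "A", "V", "missense") for i in range(n_hits)]
        # keep expected low: a few distant alleles only
        rows += [(f"b{i}", "G1", 50 + i, "A", "V", "missense") for i in range(3)]
        return dm, cols, make_catalog(rows)

    def test_per_cancer_observed_floor(self):
        dm, cols, cat = self._single_column_setup(5)
        res = enrich_positions(cat, dm, cols, "T/H", ShuffleSpec(n_shuffles=10, seed=0))
        row = res[(res.family_id == "F1") & (res.column == 5)].iloc[0]
        assert row.observed == 5 and row.candidate

        dm, cols, cat = self._single_column_setup(4)
        res = enrich_positions(cat, dm, cols, "T/H", ShuffleSpec(n_shuffles=10, seed=0))
        row = res[(res.family_id == "F1") & (res.column == 5)].iloc[0]
        assert row.observed == 4 and not row.candidate

    def test_pan_cancer_floor_is_stricter(self):
        dm, cols, cat = self._single_column_setup(19)
        res = enrich_positions(cat, dm, cols, "pan-cancer", ShuffleSpec(n_shuffles=10, seed=0))
        row = res[(res.family_id == "F1") & (res.column == 5)].iloc[0]
        assert not row.candidate
        dm, cols, cat = self._single_column_setup(20)
        res = enrich_positions(cat, dm, cols, "pan-cancer", ShuffleSpec(n_shuffles=10, seed=0))
        row = res[(res.family_id == "F1") & (res.column == 5)].iloc[0]
        assert row.candidate and row.significant

    def test_negative_log_odds_never_significant(self):
        # many instances inflate the expectation above the observation
        insts = [DomainInstance.from_offset(f"G{i}", "F1", 1, 10) for i in range(40)]
        dm = DomainMap(insts, gene_lengths={f"G{i}": 20 for i in range(40)})
        cols = make_columns([("F1", c, "A", 0.7) for c in range(1, 11)])
        rows = [(f"s{i}", "G0", 5, "A", "V", "missense") for i in range(5)]
        rows += [(f"o{i}", f"G{1 + i % 39}", 15, "A", "V", "missense")
                 for i in range(300)]
        cat = make_catalog(rows)
        res = enrich_positions(cat, dm, cols, "T/H", ShuffleSpec(n_shuffles=10, seed=0))
        row = res[(res.family_id == "F1") & (res.column == 5)].iloc[0]
        assert row.expected > row.observed
        assert row.candidate and row.log_odds < 0 and not row.significant

    def test_unknown_scope_rejected(self):
        dm, cols, cat = self._single_column_setup(5)
        with pytest.raises(ValueError, match="unknown scope"):
            enrich_positions(cat, dm, cols, "nope")


def test_planted_hotspot_recovered_single_seed():
    from famdriver import HotspotSpec
    cfg = SyntheticConfig(seed=21, hotspots=[HotspotSpec("F03", 15, 0.08)])
    dm, cols = generate_proteome(cfg)
    cat, truth = generate_mutations(cfg, dm)
    res = enrich_positions(cat, dm, cols, cat.scopes()[0], ShuffleSpec(seed=21))
    row = res[(res.family_id == "F03") & (res.column == 15)].iloc[0]
    assert row.significant
    assert row.observed >= len(truth.hotspots[0]["samples"])
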