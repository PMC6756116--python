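"""Mutual exclusivity of enriched position pairs within shared pathways.

Two family alignment positions that sit in at least one common pathway are
tested for under-representation of co-mutated samples with a one-tailed
Fisher exact test (hypergeometric lower tail on the co-mutation count), and
for joint enrichment against a pathway-level shuffle background.  Pairs are
retained when both BH q-values are <= 0.1.  Retained pairs assemble into a
family-family network whose edges carry the supporting pathways.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import PositionCounter, ShuffleSpec, _ShufflePrep, bh_fdr
from .mapping import map_catalog, position_sample_sets
from .types import (
    AnalysisThresholds,
    DomainMap,
    FamilyColumnTable,
    MutationCatalog,
    PathwayForest,
    PathwayNode,
    PositionKey,
)

UNIVERSE_RULES = ("same_class", "all_mutated", "family")


@dataclass(frozen=True)
class ContingencyTable:
    """Unique-sample 2x2 table for a position pair."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        if min(self.n_both, self.n_a_only, self.n_b_only, self.n_neither) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must cover a non-empty universe")

    @property
    def total(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither


def select_pathways(forest: PathwayForest, root_limit: int = 200,
                    sub_limit: int = 300) -> List[PathwayNode]:
    """Select intermediate-level pathways by the 200/300 size rule.

    A front-page root smaller than ``root_limit`` is taken directly;
    otherwise its children are considered, taking any smaller than
    ``sub_limit`` and recursing into larger ones.  An oversized leaf is
    taken as-is (there is nothing more specific to descend into).
    """
    selected: List[PathwayNode] = []

    def visit(node: PathwayNode, limit: int) -> None:
        if node.size() < limit:
            selected.append(node)
        elif node.children:
            for child in node.children:
                visit(child, sub_limit)
        else:
            selected.append(node)

    for root in forest.roots:
        visit(root, root_limit)
    # dedupe while keeping order (shared sub-pathways can be reached twice)
    seen: Set[str] = set()
    out = []
    for node in selected:
        if node.pathway_id not in seen:
            seen.add(node.pathway_id)
            out.append(node)
    return out


def build_contingency(hits_a: Iterable[str], hits_b: Iterable[str],
                      universe: Iterable[str],
                      cclass_a: Optional[str] = None,
                      cclass_b: Optional[str] = None) -> ContingencyTable:
    """Unique-sample 2x2 table restricted to the configured universe."""
    if cclass_a is not None and cclass_b is not None and cclass_a != cclass_b:
        raise ValueError(f"conservation class mismatch: {cclass_a} vs {cclass_b}")
    universe = frozenset(universe)
    if not universe:
        raise ValueError("exclusivity universe is empty")
    a = frozenset(hits_a) & universe
    b = frozenset(hits_b) & universe
    return ContingencyTable(
        n_both=len(a & b),
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        n_neither=len(universe - (a | b)),
    )


def fisher_exclusivity(table: ContingencyTable) -> float:
    """One-tailed Fisher p for mutual exclusivity.

    Lower hypergeometric tail: probability of observing the co-mutated
    count or fewer given the table margins.
    """
    mat = [[table.n_both, table.n_a_only], [table.n_b_only, table.n_neither]]
    return float(stats.fisher_exact(mat, alternative="less")[1])


def _pathway_catalog(catalog: MutationCatalog, pathway: PathwayNode) -> MutationCatalog:
    df = catalog.df[catalog.df["gene"].isin(pathway.members)]
    return MutationCatalog(df, cancer_type_rule=catalog.cancer_type_rule)


def pair_background(key_a: PositionKey, key_b: PositionKey, pathway: PathwayNode,
                    catalog: MutationCatalog, domain_map: DomainMap,
                    family_columns: FamilyColumnTable,
                    spec: ShuffleSpec) -> Tuple[float, int, int]:
    """Joint enrichment of a position pair against a pathway-level shuffle.

    Non-synonymous alleles of the pathway's member proteins are shuffled
    within each protein; the pooled shuffle frequency of the two columns'
    union gives a pseudocounted binomial prior, and p = P(X >= combined
    observed alleles) with n = the pathway's allele total.  A pathway with
    no mutations returns p = 1.

    Returns (p, observed combined alleles, n_trials).
    """
    sub = _pathway_catalog(catalog, pathway)
    nonsyn = sub.nonsynonymous()
    n_trials = len(nonsyn)
    if n_trials == 0:
        return 1.0, 0, 0
    counter = PositionCounter(domain_map, family_columns)
    ids = [counter.key_index.get((key_a.family_id, key_a.column)),
           counter.key_index.get((key_b.family_id, key_b.column))]
    ids = [i for i in ids if i is not None]
    observed = int(counter.count(nonsyn["gene"].to_numpy(),
                                 nonsyn["position"].to_numpy())[ids].sum())
    prep = _ShufflePrep(nonsyn, domain_map, "gene_level")
    rng = np.random.default_rng(spec.seed)
    shuffled_hits = 0
    for _ in range(spec.n_shuffles):
        shuffled_hits += int(counter.count(prep.genes, prep.draw(rng))[ids].sum())
    prior = (shuffled_hits + 0.5) / (spec.n_shuffles * n_trials + 1)
    p = float(stats.binom.sf(observed - 1, n_trials, prior)) if observed else 1.0
    return p, observed, n_trials


def _universe(rule: str, cat: MutationCatalog, hits: pd.DataFrame,
              cclass: str, genes: FrozenSet[str]) -> FrozenSet[str]:
    if rule == "all_mutated":
        return cat.samples()
    if rule == "same_class":
        return frozenset(hits.loc[hits["cclass"] == cclass, "sample_id"])
    if rule == "family":
        df = cat.nonsynonymous()
        return frozenset(df.loc[df["gene"].isin(genes), "sample_id"])
    raise ValueError(f"unknown universe rule {rule!r}; choose from {UNIVERSE_RULES}")


def exclusivity_scan(catalog: MutationCatalog, domain_map: DomainMap,
                     family_columns: FamilyColumnTable, enriched: pd.DataFrame,
                     pathways: Sequence[PathwayNode], scope: str,
                     thresholds: Optional[AnalysisThresholds] = None,
                     shuffle_spec: Optional[ShuffleSpec] = None,
                     universe_rule: str = "same_class") -> pd.DataFrame:
    """Test all qualifying position pairs sharing at least one pathway.

    Qualifying positions are significantly enriched in this scope and
    mutated in at least ``min_samples`` unique samples (5 per-cancer, 50
    pan-cancer).  Pairs must share a conservation class; intramolecular
    (same-family) pairs are allowed, same-column pairs are not.  One result
    row is emitted per (pair, pathway); the Fisher q is computed once per
    pair within the scope, the pathway-background q across rows.
    """
    thresholds = thresholds or AnalysisThresholds()
    shuffle_spec = shuffle_spec or ShuffleSpec()
    if universe_rule not in UNIVERSE_RULES:
        raise ValueError(f"unknown universe rule {universe_rule!r}")
    cat = catalog.subset(scope)
    hits, _ = map_catalog(cat, domain_map, family_columns)
    sample_sets = position_sample_sets(hits)

    sig = enriched[(enriched["significant"]) & (enriched["scope"] == scope)]
    keys = []
    for r in sig.itertuples():
        key = PositionKey(r.family_id, int(r.column), r.cclass)
        samples = sample_sets.get(key, frozenset())
        if len(samples) >= thresholds.min_samples(scope):
            keys.append(key)
    keys.sort(key=lambda k: (k.family_id, k.column))

    family_genes = {f: domain_map.family_genes(f) for f in domain_map.families}
    pathway_families: Dict[str, Set[str]] = {}
    for node in pathways:
        pathway_families[node.pathway_id] = {
            f for f, genes in family_genes.items() if genes & node.members}
    by_id = {node.pathway_id: node for node in pathways}

    pair_rows: List[Dict] = []
    fisher_cache: Dict[Tuple[PositionKey, PositionKey], Tuple[float, ContingencyTable]] = {}
    for key_a, key_b in itertools.combinations(keys, 2):
        if key_a.cclass != key_b.cclass:
            continue
        if (key_a.family_id, key_a.column) == (key_b.family_id, key_b.column):
            continue
        shared = [pid for pid, fams in pathway_families.items()
                  if key_a.family_id in fams and key_b.family_id in fams]
        if not shared:
            continue
        shared.sort(key=lambda pid: (by_id[pid].size(), pid))  # most specific first
        genes = family_genes[key_a.family_id] | family_genes[key_b.family_id]
        universe = _universe(universe_rule, cat, hits, key_a.cclass, genes)
        table = build_contingency(sample_sets[key_a], sample_sets[key_b], universe,
                                  key_a.cclass, key_b.cclass)
        fisher_p = fisher_exclusivity(table)
        fisher_cache[(key_a, key_b)] = (fisher_p, table)
        for rank, pid in enumerate(shared):
            pair_rows.append({
                "scope": scope,
                "family_a": key_a.family_id, "column_a": key_a.column,
                "family_b": key_b.family_id, "column_b": key_b.column,
                "cclass": key_a.cclass, "pathway_id": pid,
                "pathway_size": by_id[pid].size(), "most_specific": rank == 0,
                "n_both": table.n_both, "n_a_only": table.n_a_only,
                "n_b_only": table.n_b_only, "n_neither": table.n_neither,
                "n_samples_a": len(sample_sets[key_a]),
                "n_samples_b": len(sample_sets[key_b]),
                "fisher_p": fisher_p,
            })

    columns = ["scope", "family_a", "column_a", "family_b", "column_b", "cclass",
               "pathway_id", "pathway_size", "most_specific",
               "n_both", "n_a_only", "n_b_only", "n_neither",
               "n_samples_a", "n_samples_b", "fisher_p", "fisher_q",
               "pair_observed", "pair_n_trials", "pair_p", "pair_q", "retained"]
    if not pair_rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(pair_rows)

    # Fisher FDR over unique pairs (so duplicated pathways do not inflate m)
    pair_key = out[["family_a", "column_a", "family_b", "column_b"]].apply(tuple, axis=1)
    uniq = out.loc[~pair_key.duplicated()]
    q_by_pair = dict(zip(pair_key[~pair_key.duplicated()],
                         bh_fdr(uniq["fisher_p"].to_numpy())))
    out["fisher_q"] = pair_key.map(q_by_pair)

    pair_stats = []
    for r in out.itertuples():
        key_a = PositionKey(r.family_a, int(r.column_a), r.cclass)
        key_b = PositionKey(r.family_b, int(r.column_b), r.cclass)
        p, obs, n = pair_background(key_a, key_b, by_id[r.pathway_id], cat,
                                    domain_map, family_columns, shuffle_spec)
        pair_stats.append((p, obs, n))
    out["pair_p"] = [s[0] for s in pair_stats]
    out["pair_observed"] = [s[1] for s in pair_stats]
    out["pair_n_trials"] = [s[2] for s in pair_stats]
    out["pair_q"] = bh_fdr(out["pair_p"].to_numpy())
    out["retained"] = (out["fisher_q"] <= thresholds.exclusivity_q_max) & \
                      (out["pair_q"] <= thresholds.pair_q_max)
    out = out.loc[:, columns]
    return out.sort_values(["family_a", "column_a", "family_b", "column_b",
                            "pathway_size", "pathway_id"],
                           kind="mergesort").reset_index(drop=True)


def cooccurrence_with_drivers(position_sets: Mapping[PositionKey, FrozenSet[str]],
                              driver_df: pd.DataFrame,
                              universe: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Exclusivity of position mutations versus known driver alterations.

    ``driver_df`` has one row per (sample_id, gene, alteration_class,
    category) altered-driver event; the universe defaults to all samples
    with driver information.  One Fisher lower-tail test per (position,
    driver category), BH-corrected across all tests.
    """
    columns = ["family_id", "column", "cclass", "category",
               "n_both", "n_pos_only", "n_drv_only", "n_neither", "p", "q"]
    if not len(driver_df) or not position_sets:
        return pd.DataFrame(columns=columns)
    for col in ("sample_id", "gene", "alteration_class", "category"):
        if col not in driver_df.columns:
            raise ValueError(f"driver table missing column {col!r}")
    universe = frozenset(universe) if universe is not None else frozenset(driver_df["sample_id"])
    rows = []
    for key in sorted(position_sets, key=lambda k: (k.family_id, k.column)):
        pos_samples = position_sets[key]
        for category, grp in driver_df.groupby("category"):
            altered = frozenset(grp["sample_id"])
            table = build_contingency(pos_samples, altered, universe)
            rows.append((key.family_id, key.column, key.cclass, category,
                         table.n_both, table.n_a_only, table.n_b_only, table.n_neither,
                         fisher_exclusivity(table)))
    out = pd.DataFrame(rows, columns=columns[:-1])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def build_network(results: pd.DataFrame, hits: pd.DataFrame) -> nx.Graph:
    """Family-level exclusivity network from retained pairs.

    Nodes are families weighted by their total unique mutated samples;
    edges join family pairs with at least one retained position pair and
    carry the best q-values and the supporting pathways.  Intramolecular
    pairs become self-loops.
    """
    graph = nx.Graph()
    retained = results[results["retained"]] if len(results) else results
    if not len(retained):
        return graph
    sample_counts = hits.groupby("family_id")["sample_id"].nunique() if len(hits) else {}
    for _, row in retained.iterrows():
        for fam in (row["family_a"], row["family_b"]):
            if not graph.has_node(fam):
                weight = int(sample_counts.get(fam, 0)) if len(hits) else 0
                graph.add_node(fam, n_samples=weight)
        a, b = sorted((row["family_a"], row["family_b"]))
        if graph.has_edge(a, b):
            edge = graph.edges[a, b]
            edge["best_fisher_q"] = min(edge["best_fisher_q"], row["fisher_q"])
            edge["best_pair_q"] = min(edge["best_pair_q"], row["pair_q"])
            edge["pathways"].add(row["pathway_id"])
            edge["n_pairs"] += 1
        else:
            graph.add_edge(a, b, best_fisher_q=float(row["fisher_q"]),
                           best_pair_q=float(row["pair_q"]),
                           pathways={row["pathway_id"]}, n_pairs=1)
    return graph


def network_to_edges(graph: nx.Graph) -> pd.DataFrame:
    """Edge-list TSV payload importable by standard graph tools."""
    rows = []
    for a, b, attrs in sorted(graph.edges(data=True)):
        rows.append((a, b, ";".join(sorted(attrs["pathways"])),
                     attrs["best_fisher_q"], attrs["best_pair_q"], attrs["n_pairs"],
                     graph.nodes[a].get("n_samples", 0), graph.nodes[b].get("n_samples", 0)))
    return pd.DataFrame(rows, columns=["family_a", "family_b", "pathways",
                                       "best_fisher_q", "best_pair_q", "n_pairs",
                                       "n_samples_a", "n_samples_b"])
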