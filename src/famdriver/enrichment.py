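"""Per-position variant enrichment against shuffle backgrounds.

The observed allele count at a family alignment column is compared with the
count expected if mutations fell uniformly over the proteome: expected =
(total alleles / proteome length) x number of domain instances mapping the
column.  Statistical significance comes from a one-tailed binomial test
whose per-trial prior is estimated by shuffling each sample's mutations
within the same protein (``gene_level``), or within the same domain
instance and the remaining sequence separately (``domain_aware``).
Candidates must clear an observed-OR-expected floor per scope; significant
positions additionally need log-odds >= 0 and BH q <= 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import map_catalog
from .types import (
    AnalysisThresholds,
    DomainMap,
    FamilyColumnTable,
    MutationCatalog,
)

LOG_ODDS_ZERO = float("-inf")


@dataclass
class ShuffleSpec:
    """Background shuffle configuration."""

    model: str = "gene_level"
    n_shuffles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gene_level", "domain_aware"):
            raise ValueError("shuffle model must be gene_level or domain_aware")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


def expected_count(total_alleles: float, proteome_length: int, n_instances: int) -> float:
    """Uniform-background expectation at one column.

    expected = (total alleles / proteome length) x instances mapping the
    column; zero instances give zero expectation.
    """
    if proteome_length <= 0:
        raise ValueError("proteome length must be positive")
    return (total_alleles / proteome_length) * n_instances


def log_odds(observed: float, expected: float) -> float:
    """log2(observed / expected); 0 observed gives -inf, bad expected NaN."""
    if expected <= 0:
        warnings.warn("log_odds undefined for non-positive expected count")
        return float("nan")
    if observed == 0:
        return LOG_ODDS_ZERO
    return math.log2(observed / expected)


class _ShufflePrep:
    """Precomputed arrays for vectorized within-protein shuffles.

    Rows follow the non-synonymous allele table of the catalog subset.  The
    shuffle relocates positions only, so per-(sample, protein) counts — and
    for the domain-aware model per-(sample, instance, inside/outside)
    assignments — are conserved by construction on every draw.
    """

    def __init__(self, df: pd.DataFrame, domain_map: DomainMap, model: str) -> None:
        self.df = df.reset_index(drop=True)
        self.model = model
        self.genes = self.df["gene"].to_numpy()
        self.positions = self.df["position"].to_numpy(dtype=np.int64)
        missing = [g for g in dict.fromkeys(self.genes) if g not in domain_map.gene_lengths]
        if missing:
            raise ValueError(f"protein length missing for genes: {missing[:5]}")
        self.lengths = np.array([domain_map.gene_lengths[g] for g in self.genes], dtype=np.int64)

        if model == "domain_aware":
            # per gene: ordered instances, residue -> instance id, outside residues
            self.inst_positions: List[np.ndarray] = []
            self.row_inst = np.full(len(self.df), -1, dtype=np.int64)
            self.outside: Dict[str, np.ndarray] = {}
            inst_of: Dict[str, Dict[int, int]] = {}
            for gene in dict.fromkeys(self.genes):
                insts = sorted(domain_map.by_gene.get(gene, []),
                               key=lambda i: (i.start, i.family_id))
                lookup: Dict[int, int] = {}
                mapped_union: Set[int] = set()
                for inst in insts:
                    idx = len(self.inst_positions)
                    self.inst_positions.append(np.array(inst.mapped_positions, dtype=np.int64))
                    for pos in inst.colmap:
                        lookup.setdefault(pos, idx)
                        mapped_union.add(pos)
                inst_of[gene] = lookup
                length = domain_map.gene_lengths[gene]
                self.outside[gene] = np.array(
                    sorted(set(range(1, length + 1)) - mapped_union), dtype=np.int64)
            for i, (gene, pos) in enumerate(zip(self.genes, self.positions)):
                self.row_inst[i] = inst_of.get(gene, {}).get(int(pos), -1)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One shuffled position vector aligned with the allele rows."""
        if not len(self.df):
            return np.empty(0, dtype=np.int64)
        if self.model == "gene_level":
            return rng.integers(1, self.lengths + 1)
        new_pos = self.positions.copy()
        for i in range(len(new_pos)):
            inst = self.row_inst[i]
            if inst >= 0:
                pool = self.inst_positions[inst]
            else:
                pool = self.outside[self.genes[i]]
                if not len(pool):  # fully mapped protein: nowhere else to go
                    continue
            new_pos[i] = pool[int(rng.integers(len(pool)))]
        return new_pos


def shuffle_background(catalog: MutationCatalog, domain_map: DomainMap,
                       spec: ShuffleSpec) -> Iterator[pd.DataFrame]:
    """Yield shuffled copies of the non-synonymous allele table.

    Every draw preserves per-(sample, protein) mutation counts exactly; the
    domain-aware model additionally keeps each in-domain mutation inside its
    own instance and out-of-domain mutations outside all instances.
    """
    prep = _ShufflePrep(catalog.nonsynonymous(), domain_map, spec.model)
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_shuffles):
        shuffled = prep.df.copy()
        shuffled["position"] = prep.draw(rng)
        yield shuffled


class PositionCounter:
    """Fast allele counting per (family, column) key from position vectors."""

    def __init__(self, domain_map: DomainMap, family_columns: FamilyColumnTable) -> None:
        keys = sorted({(r.family_id, int(r.column)) for r in family_columns.df.itertuples()})
        self.key_index = {k: i for i, k in enumerate(keys)}
        self.keys = keys
        index = domain_map.position_index()
        # residue -> key id maps; two layers cover overlapping families
        self.maps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for gene, gene_idx in index.items():
            length = domain_map.gene_lengths.get(gene, max(gene_idx, default=1))
            a = np.full(length + 1, -1, dtype=np.int64)
            b = np.full(length + 1, -1, dtype=np.int64)
            for pos, entries in gene_idx.items():
                ids = [self.key_index[e] for e in entries if e in self.key_index]
                if ids:
                    a[pos] = ids[0]
                if len(ids) > 1:
                    b[pos] = ids[1]
            self.maps[gene] = (a, b)

    def count(self, genes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Allele count per key id for one (gene, position) vector."""
        counts = np.zeros(len(self.keys), dtype=np.int64)
        df = pd.DataFrame({"gene": genes, "pos": positions})
        for gene, grp in df.groupby("gene", sort=False):
            layers = self.maps.get(gene)
            if layers is None:
                continue
            pos = grp["pos"].to_numpy(dtype=np.int64)
            pos = pos[pos < len(layers[0])]
            for layer in layers:
                ids = layer[pos]
                ids = ids[ids >= 0]
                if len(ids):
                    counts += np.bincount(ids, minlength=len(self.keys))
        return counts


def prior_from_counts(shuffled_hits: float, n_shuffles: int, n_trials: int) -> float:
    """Pseudocounted per-trial prior from pooled shuffle hits.

    prior = (total shuffled hits + 0.5) / (n_shuffles * n_trials + 1),
    strictly inside (0, 1) for any input.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return (shuffled_hits + 0.5) / (n_shuffles * n_trials + 1)


def estimate_priors(catalog: MutationCatalog, domain_map: DomainMap,
                    family_columns: FamilyColumnTable,
                    spec: ShuffleSpec) -> Tuple[pd.Series, int]:
    """Per-position binomial priors from within-protein shuffles.

    Returns (prior per (family_id, column) key, n_trials) where n_trials is
    the total non-synonymous allele count in the catalog.
    """
    nonsyn = catalog.nonsynonymous()
    n_trials = len(nonsyn)
    if n_trials == 0:
        raise ValueError("cannot estimate priors on an empty catalog")
    prep = _ShufflePrep(nonsyn, domain_map, spec.model)
    counter = PositionCounter(domain_map, family_columns)
    rng = np.random.default_rng(spec.seed)
    totals = np.zeros(len(counter.keys), dtype=np.int64)
    for _ in range(spec.n_shuffles):
        totals += counter.count(prep.genes, prep.draw(rng))
    priors = (totals + 0.5) / (spec.n_shuffles * n_trials + 1)
    index = pd.MultiIndex.from_tuples(counter.keys, names=["family_id", "column"])
    return pd.Series(priors, index=index, name="prior"), n_trials


def binomial_enrichment(observed: int, n_trials: int, prior: float) -> float:
    """Upper-tail binomial p-value: P(X >= observed), X ~ Bin(n, prior)."""
    if not 0 <= observed <= n_trials:
        raise ValueError("observed must lie in [0, n_trials]")
    if not 0 < prior < 1:
        raise ValueError("prior must lie strictly inside (0, 1)")
    return float(stats.binom.sf(observed - 1, n_trials, prior))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def candidate_mask(observed, expected, scope: str,
                   thresholds: Optional[AnalysisThresholds] = None):
    """Observed-OR-expected retention floor for one scope.

    Per-cancer scopes keep positions with >= 5 observed or >= 2.5 expected
    alleles; pan-cancer uses 20 / 5.
    """
    thresholds = thresholds or AnalysisThresholds()
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    return (observed >= thresholds.obs_floor(scope)) | \
           (expected >= thresholds.exp_floor(scope))


def significance_mask(candidate, log_odds_values, q_values,
                      thresholds: Optional[AnalysisThresholds] = None):
    """Significance rule: candidate with log-odds >= 0 and q <= 0.01."""
    thresholds = thresholds or AnalysisThresholds()
    candidate = np.asarray(candidate, dtype=bool)
    lo = np.asarray(log_odds_values, dtype=float)
    q = np.asarray(q_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return candidate & (lo >= thresholds.min_log_odds) & (q <= thresholds.enrichment_q_max)


def enrich_positions(catalog: MutationCatalog, domain_map: DomainMap,
                     family_columns: FamilyColumnTable, scope: str,
                     shuffle_spec: Optional[ShuffleSpec] = None,
                     thresholds: Optional[AnalysisThresholds] = None,
                     dubious_genes: Optional[Set[str]] = None) -> pd.DataFrame:
    """Score every proteome column for variant enrichment in one scope.

    Returns one row per (family, column) with observed/expected allele
    counts, log-odds, shuffle prior, binomial p, BH q (within scope, over
    candidates), unique-sample count, dubious-gene allele share, and the
    candidate/significant flags.
    """
    thresholds = thresholds or AnalysisThresholds()
    shuffle_spec = shuffle_spec or ShuffleSpec()
    if scope != "pan-cancer" and scope not in catalog.scopes():
        raise ValueError(f"unknown scope {scope!r}; catalog has {catalog.scopes()}")
    cat = catalog.subset(scope)
    hits, _ = map_catalog(cat, domain_map, family_columns)

    total_alleles = cat.n_alleles()
    proteome_length = domain_map.proteome_length()

    rows = []
    grouped = hits.groupby(["family_id", "column"]) if len(hits) else {}
    obs_map: Dict[Tuple[str, int], pd.DataFrame] = (
        {k: g for k, g in grouped} if len(hits) else {})
    for r in family_columns.df.itertuples():
        key = (r.family_id, int(r.column))
        k_inst = domain_map.n_instances_with_column(*key)
        if k_inst == 0:
            continue
        grp = obs_map.get(key)
        observed = len(grp) if grp is not None else 0
        n_samples = grp["sample_id"].nunique() if grp is not None else 0
        expected = expected_count(total_alleles, proteome_length, k_inst)
        if dubious_genes and grp is not None and observed:
            dub_share = float(grp["gene"].isin(dubious_genes).mean())
        else:
            dub_share = 0.0
        rows.append((scope, r.family_id, int(r.column),
                     "conserved" if r.is_conserved else "nonconserved",
                     f"{r.consensus_aa.upper() if r.is_conserved else r.consensus_aa.lower()}"
                     f"{int(r.column)}",
                     observed, expected, log_odds(observed, expected) if expected > 0 else
                     float("nan"), n_samples, dub_share))
    out = pd.DataFrame(rows, columns=[
        "scope", "family_id", "column", "cclass", "label",
        "observed", "expected", "log_odds", "n_samples", "dubious_gene_share"])
    if not len(out):
        for col in ("prior", "p", "q"):
            out[col] = pd.Series(dtype=float)
        out["candidate"] = pd.Series(dtype=bool)
        out["significant"] = pd.Series(dtype=bool)
        return out

    out["candidate"] = candidate_mask(out["observed"], out["expected"], scope, thresholds)

    out["prior"] = np.nan
    out["p"] = np.nan
    out["q"] = np.nan
    cand = out.index[out["candidate"]]
    if len(cand) and total_alleles > 0:
        priors, n_trials = estimate_priors(cat, domain_map, family_columns, shuffle_spec)
        key_index = list(zip(out.loc[cand, "family_id"], out.loc[cand, "column"]))
        prior_vals = np.array([priors.get(k, 0.5 / (shuffle_spec.n_shuffles * n_trials + 1))
                               for k in key_index])
        out.loc[cand, "prior"] = prior_vals
        out.loc[cand, "p"] = stats.binom.sf(
            out.loc[cand, "observed"].to_numpy() - 1, n_trials, prior_vals)
        out.loc[cand, "q"] = bh_fdr(out.loc[cand, "p"].to_numpy())

    out["significant"] = significance_mask(out["candidate"], out["log_odds"], out["q"],
                                           thresholds)
    return out.sort_values(["family_id", "column"], kind="mergesort").reset_index(drop=True)
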