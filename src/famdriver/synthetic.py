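"""Synthetic data generator with planted ground truth.

Emulates the six input kinds the pipeline consumes — a somatic mutation
catalog, domain assignments with residue->column maps, per-family alignment
column summaries, pathway gene sets with a hierarchy, differential
expression summaries, and receptor->G-protein couplings — so every stage is
testable end to end without external downloads.

The background model is deliberately the model the downstream statistics
assume: per-sample mutation counts are Poisson, placed uniformly over the
proteome (no trinucleotide context).  Hotspot columns add Bernoulli hits at
a uniformly chosen family member; exclusive pairs assign disjoint sample
subsets hit at A only, B only, or both.  Planted columns are generated as
conserved so a planted pair always shares a conservation class.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as fio
from .types import (
    DEFAULT_GPROTEIN_FAMILIES,
    CouplingTable,
    DomainInstance,
    DomainMap,
    FamilyColumnTable,
    MutationCatalog,
    PathwayForest,
    PathwayNode,
    PositionKey,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

# stage indices salt the master seed so each generator has its own stream
_STAGE_PROTEOME, _STAGE_MUTATIONS, _STAGE_EXPRESSION, _STAGE_COUPLINGS = 1, 2, 3, 4


@dataclass(frozen=True)
class HotspotSpec:
    """Planted hotspot: extra per-sample hit probability at one column."""

    family_id: str
    column: int
    extra_prob: float


@dataclass(frozen=True)
class PairSpec:
    """Planted mutually exclusive pair with fixed sample-set sizes."""

    family_a: str
    column_a: int
    family_b: str
    column_b: int
    n_a: int
    n_b: int
    n_both: int


@dataclass(frozen=True)
class ExpressionPlant:
    """Planted differential-expression shift for one gene in one cancer type."""

    cancer_type: str
    gene: str
    lfc: float
    padj: float
    base_mean: Optional[float] = None


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults model a single-cancer-type cohort of 500 samples over a
    proteome of 10 families with 4 members each (400-residue proteins, one
    contiguous 100-column domain per protein) and a Poisson background of 2
    non-synonymous mutations per sample.
    """

    n_samples: int = 500
    n_families: int = 10
    members_per_family: int = 4
    protein_length: int = 400
    domain_length: int = 100
    conserved_share: float = 0.5
    background_rate: float = 2.0
    class_probs: Tuple[float, float, float] = (0.90, 0.06, 0.04)  # missense, stop, fs
    hotspots: List[HotspotSpec] = field(default_factory=list)
    exclusive_pairs: List[PairSpec] = field(default_factory=list)
    families_per_pathway: int = 2
    tissue: str = "synthetic"
    histology: str = "NS"
    expression_cancer_types: Optional[List[str]] = None
    expression_log_mean: float = 4.0
    expression_log_sd: float = 1.0
    expression_plants: List[ExpressionPlant] = field(default_factory=list)
    extra_expression_genes: List[str] = field(default_factory=list)
    coupling_spec: Optional[Dict[str, int]] = None
    receptor_genes: Optional[List[str]] = None
    secondary_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_length > self.protein_length:
            raise ValueError("domain_length must not exceed protein_length")
        if not 0.0 <= self.conserved_share <= 1.0:
            raise ValueError("conserved_share must lie in [0,1]")
        for pair in self.exclusive_pairs:
            if pair.n_a + pair.n_b + pair.n_both > self.n_samples:
                raise ValueError(
                    f"planted pair needs {pair.n_a + pair.n_b + pair.n_both} samples, "
                    f"only {self.n_samples} available")
        if self.coupling_spec:
            bad = set(self.coupling_spec) - set(DEFAULT_GPROTEIN_FAMILIES)
            if bad:
                raise ValueError(f"unknown G-protein families in coupling spec: {sorted(bad)}")

    @property
    def cancer_type(self) -> str:
        return f"{self.tissue}/{self.histology}"

    def family_name(self, i: int) -> str:
        return f"F{i:02d}"

    def gene_name(self, family_i: int, member_j: int) -> str:
        return f"F{family_i:02d}m{member_j}"

    def genes(self) -> List[str]:
        return [self.gene_name(i, j)
                for i in range(1, self.n_families + 1)
                for j in range(1, self.members_per_family + 1)]


@dataclass
class GroundTruth:
    """Exactly what was planted, for recovery checks."""

    hotspots: List[Dict] = field(default_factory=list)
    pairs: List[Dict] = field(default_factory=list)
    expression: List[Dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(hotspots=d["hotspots"], pairs=d["pairs"], expression=d["expression"])


def _rng(config: SyntheticConfig, stage: int, seed: Optional[int]) -> np.random.Generator:
    master = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(master), stage]))


def _ref_aa(gene: str, position: int) -> str:
    """Deterministic reference residue so a site has one ref across samples."""
    # crc32, not hash(): stable across processes regardless of hash seeding
    return _AA[zlib.crc32(f"{gene}:{position}".encode()) % len(_AA)]


def generate_proteome(config: SyntheticConfig,
                      seed: Optional[int] = None) -> Tuple[DomainMap, FamilyColumnTable]:
    """Build the synthetic proteome: one contiguous domain instance per gene.

    Each family gets ``members_per_family`` genes with an offset
    residue->column map; a ``conserved_share`` of columns draw conservation
    fractions >= 0.5, the rest < 0.5.  Columns named by planted hotspots or
    pairs are forced conserved so pair tests share a conservation class.
    """
    rng = _rng(config, _STAGE_PROTEOME, seed)
    planted_cols: Dict[str, set] = {}
    for h in config.hotspots:
        planted_cols.setdefault(h.family_id, set()).add(h.column)
    for p in config.exclusive_pairs:
        planted_cols.setdefault(p.family_a, set()).add(p.column_a)
        planted_cols.setdefault(p.family_b, set()).add(p.column_b)

    instances: List[DomainInstance] = []
    gene_lengths: Dict[str, int] = {}
    col_rows = []
    max_start = config.protein_length - config.domain_length + 1
    for i in range(1, config.n_families + 1):
        family = config.family_name(i)
        for j in range(1, config.members_per_family + 1):
            gene = config.gene_name(i, j)
            start = int(rng.integers(1, max_start + 1))
            end = start + config.domain_length - 1
            instances.append(DomainInstance.from_offset(gene, family, start, end))
            gene_lengths[gene] = config.protein_length
        n_conserved = int(round(config.conserved_share * config.domain_length))
        conserved = set(rng.choice(config.domain_length, size=n_conserved, replace=False) + 1) \
            if n_conserved else set()
        for column in range(1, config.domain_length + 1):
            if column in planted_cols.get(family, ()):  # planted columns are conserved
                frac = 0.9
            elif column in conserved:
                frac = float(rng.uniform(0.5, 0.95))
            else:
                frac = float(rng.uniform(0.05, 0.45))
            consensus = _AA[int(rng.integers(len(_AA)))]
            col_rows.append((family, column, consensus, frac, ""))
    columns = FamilyColumnTable(pd.DataFrame(
        col_rows, columns=["family_id", "column", "consensus_aa",
                           "conservation_fraction", "aux_label"]))
    return DomainMap(instances, gene_lengths=gene_lengths), columns


def _residue_of_column(domain_map: DomainMap, gene: str, column: int) -> int:
    for inst in domain_map.by_gene[gene]:
        for pos, col in inst.colmap.items():
            if col == column:
                return pos
    raise ValueError(f"column {column} not mapped on {gene}")


def _planted_members(config: SyntheticConfig, domain_map: DomainMap,
                     family_id: str, column: int) -> List[Tuple[str, int]]:
    genes = sorted(domain_map.family_genes(family_id))
    if not genes:
        raise ValueError(f"planted family {family_id} absent from proteome")
    out = []
    for gene in genes:
        out.append((gene, _residue_of_column(domain_map, gene, column)))
    return out


def _random_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [a for a in _AA if a != ref]
    return choices[int(rng.integers(len(choices)))]


def generate_mutations(config: SyntheticConfig, domain_map: DomainMap,
                       seed: Optional[int] = None) -> Tuple[MutationCatalog, GroundTruth]:
    """Draw the somatic catalog: Poisson background plus planted hits.

    Background mutations are uniform over all residues of the proteome;
    every planted hit is missense at the planted column of a uniformly
    chosen family member.
    """
    rng = _rng(config, _STAGE_MUTATIONS, seed)
    samples = [f"S{k:04d}" for k in range(1, config.n_samples + 1)]
    genes = config.genes()
    rows: List[Tuple] = []
    truth = GroundTruth()

    def add(sample: str, gene: str, pos: int, mclass: str) -> None:
        ref = _ref_aa(gene, pos)
        if mclass == "missense":
            alt = _random_alt(rng, ref)
        elif mclass == "stop_gain":
            alt = "*"
        else:
            alt = "fs"
        rows.append((sample, gene, pos, ref, alt, mclass, config.tissue, config.histology))

    # background: per-sample Poisson, uniform residue placement
    counts = rng.poisson(config.background_rate, size=config.n_samples)
    pm, ps, pf = config.class_probs
    for sample, k in zip(samples, counts):
        for _ in range(int(k)):
            gene = genes[int(rng.integers(len(genes)))]
            pos = int(rng.integers(1, domain_map.gene_lengths[gene] + 1))
            mclass = ["missense", "stop_gain", "frameshift"][
                int(rng.choice(3, p=[pm, ps, pf]))]
            add(sample, gene, pos, mclass)

    for spec in config.hotspots:
        members = _planted_members(config, domain_map, spec.family_id, spec.column)
        hit_samples = []
        draws = rng.random(config.n_samples) < spec.extra_prob
        for sample, hit in zip(samples, draws):
            if hit:
                gene, pos = members[int(rng.integers(len(members)))]
                add(sample, gene, pos, "missense")
                hit_samples.append(sample)
        truth.hotspots.append({
            "family_id": spec.family_id, "column": spec.column,
            "extra_prob": spec.extra_prob, "samples": hit_samples,
        })

    for spec in config.exclusive_pairs:
        members_a = _planted_members(config, domain_map, spec.family_a, spec.column_a)
        members_b = _planted_members(config, domain_map, spec.family_b, spec.column_b)
        perm = rng.permutation(config.n_samples)
        sel_a = [samples[i] for i in perm[:spec.n_a]]
        sel_b = [samples[i] for i in perm[spec.n_a:spec.n_a + spec.n_b]]
        sel_both = [samples[i] for i in perm[spec.n_a + spec.n_b:
                                             spec.n_a + spec.n_b + spec.n_both]]
        for sample in sel_a + sel_both:
            gene, pos = members_a[int(rng.integers(len(members_a)))]
            add(sample, gene, pos, "missense")
        for sample in sel_b + sel_both:
            gene, pos = members_b[int(rng.integers(len(members_b)))]
            add(sample, gene, pos, "missense")
        truth.pairs.append({
            "family_a": spec.family_a, "column_a": spec.column_a,
            "family_b": spec.family_b, "column_b": spec.column_b,
            "samples_a": sorted(sel_a), "samples_b": sorted(sel_b),
            "samples_both": sorted(sel_both),
        })

    df = pd.DataFrame(rows, columns=MutationCatalog.COLUMNS)
    return MutationCatalog(df, cancer_type_rule="tissue+histology"), truth


def generate_pathways(config: SyntheticConfig, domain_map: DomainMap) -> PathwayForest:
    """Group families into pathways under a single front-page root.

    Consecutive families form one pathway each of ``families_per_pathway``
    families; the root pathway holds the whole proteome.
    """
    nodes: Dict[str, PathwayNode] = {}
    children: List[PathwayNode] = []
    fams = [config.family_name(i) for i in range(1, config.n_families + 1)]
    for chunk_i, start in enumerate(range(0, len(fams), config.families_per_pathway), start=1):
        chunk = fams[start:start + config.families_per_pathway]
        members = frozenset().union(*(domain_map.family_genes(f) for f in chunk))
        node = PathwayNode(f"P{chunk_i:02d}", "+".join(chunk), members)
        nodes[node.pathway_id] = node
        children.append(node)
    root = PathwayNode("ROOT", "front page", frozenset(domain_map.genes),
                       children=children, is_root=True)
    nodes[root.pathway_id] = root
    return PathwayForest(nodes, [root])


def generate_expression(config: SyntheticConfig, domain_map: DomainMap,
                        seed: Optional[int] = None) -> Tuple[pd.DataFrame, List[Dict]]:
    """Differential-expression summaries: log-normal base means, planted shifts.

    Unplanted genes get lfc ~ N(0, 0.1) with padj = 1; planted genes carry
    their stated lfc and padj verbatim.
    """
    rng = _rng(config, _STAGE_EXPRESSION, seed)
    gprot = sorted({g for members in DEFAULT_GPROTEIN_FAMILIES.values() for g in members})
    universe = sorted(set(domain_map.genes) | set(gprot) | set(config.extra_expression_genes)
                      | {p.gene for p in config.expression_plants})
    cancer_types = config.expression_cancer_types or [config.cancer_type]
    plants = {(p.cancer_type, p.gene): p for p in config.expression_plants}
    rows = []
    for ct in cancer_types:
        for gene in universe:
            base_mean = float(rng.lognormal(config.expression_log_mean, config.expression_log_sd))
            lfc = float(rng.normal(0.0, 0.1))
            padj = 1.0
            plant = plants.get((ct, gene))
            if plant is not None:
                lfc, padj = plant.lfc, plant.padj
                if plant.base_mean is not None:
                    base_mean = plant.base_mean
            rows.append((ct, gene, base_mean, lfc, padj))
    df = pd.DataFrame(rows, columns=["cancer_type", "gene", "base_mean", "lfc", "padj"])
    truth = [dataclasses.asdict(p) for p in config.expression_plants]
    return df, truth


def generate_couplings(config: SyntheticConfig, domain_map: DomainMap,
                       seed: Optional[int] = None) -> CouplingTable:
    """Assign each receptor a primary G family, optionally a secondary one."""
    rng = _rng(config, _STAGE_COUPLINGS, seed)
    receptors = config.receptor_genes if config.receptor_genes is not None else domain_map.genes
    families = list(DEFAULT_GPROTEIN_FAMILIES)
    rows = []
    if config.coupling_spec is not None:
        queue = list(receptors)
        for family in sorted(config.coupling_spec):
            n = config.coupling_spec[family]
            if n > len(queue):
                raise ValueError(f"coupling spec asks for {n} receptors, {len(queue)} left")
            for r in queue[:n]:
                rows.append((r, family, "primary"))
            queue = queue[n:]
    else:
        for r in receptors:
            primary = families[int(rng.integers(len(families)))]
            rows.append((r, primary, "primary"))
            if config.secondary_prob > 0 and rng.random() < config.secondary_prob:
                others = [f for f in families if f != primary]
                rows.append((r, others[int(rng.integers(len(others)))], "secondary"))
    df = pd.DataFrame(rows, columns=["receptor", "gfamily", "provenance"])
    return CouplingTable(df)


def write_fixtures(config: SyntheticConfig, outdir,
                   seed: Optional[int] = None) -> Dict[str, Path]:
    """Write the complete six-input toy dataset plus the ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    domain_map, columns = generate_proteome(config, seed)
    catalog, truth = generate_mutations(config, domain_map, seed)
    forest = generate_pathways(config, domain_map)
    expression, expr_truth = generate_expression(config, domain_map, seed)
    truth.expression = expr_truth
    couplings = generate_couplings(config, domain_map, seed)

    paths = {
        "mutations": outdir / "mutations.tsv",
        "domains": outdir / "domains.tsv",
        "family_columns": outdir / "family_columns.tsv",
        "gmt": outdir / "pathways.gmt",
        "hierarchy": outdir / "hierarchy.tsv",
        "expression": outdir / "expression.tsv",
        "couplings": outdir / "couplings.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    fio.write_mutation_table(catalog, paths["mutations"])
    fio.write_domain_assignments(domain_map, paths["domains"])
    fio.write_family_columns(columns, paths["family_columns"])
    fio.write_pathway_hierarchy(forest, paths["gmt"], paths["hierarchy"])
    fio.write_expression(expression, paths["expression"])
    fio.write_couplings(couplings, paths["couplings"])
    truth.to_json(paths["ground_truth"])
    return paths
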