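"""Core domain types shared by every analysis stage.

The analysis pools somatic protein-level mutations across members of a
protein family by projecting each mutated residue onto a column of the
family's multiple alignment.  These types carry the bookkeeping that makes
that pooling well defined: 1-based protein coordinates, inclusive domain
ranges, partial residue->column maps (match states only; insertion states
are unmapped), and a conservation class per column (a column is conserved
when one amino acid recurs in at least half of the family sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MUTATION_CLASSES = frozenset({"missense", "stop_gain", "frameshift", "synonymous", "other"})
#: classes that count as non-synonymous in every statistic
NONSYNONYMOUS_CLASSES = frozenset({"missense", "stop_gain", "frameshift", "other"})

#: a column is conserved when one residue recurs in >= this share of sequences
CONSERVATION_THRESHOLD = 0.5

CANCER_TYPE_RULES = ("tissue", "histology", "tissue+histology")

#: default heterotrimeric G-protein family membership
DEFAULT_GPROTEIN_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "Gs": ("GNAS", "GNAL"),
    "Gi/o": ("GNAI1", "GNAI2", "GNAI3", "GNAO1"),
    "Gq/11": ("GNAQ", "GNA14", "GNA15"),
    "G12/13": ("GNA12", "GNA13"),
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic protein-level mutation allele in one sample."""

    sample_id: str
    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    mclass: str
    tissue: str = "NS"
    histology: str = "NS"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"protein position must be >= 1, got {self.position}")
        if self.mclass not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")


class MutationCatalog:
    """Somatic mutation catalog with allele- and sample-level accessors.

    Rows are alleles: identical (sample, gene, position, alt) rows collapse
    to a single allele, while distinct alternate residues at the same site in
    the same sample stay separate alleles.  Unique-sample counting and allele
    counting are deliberately distinct accessors.
    """

    COLUMNS = ["sample_id", "gene", "position", "ref_aa", "alt_aa", "mclass", "tissue", "histology"]

    def __init__(self, df: pd.DataFrame, n_skipped: int = 0,
                 cancer_type_rule: str = "tissue+histology") -> None:
        if cancer_type_rule not in CANCER_TYPE_RULES:
            raise ValueError(f"cancer_type_rule must be one of {CANCER_TYPE_RULES}")
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        df = df.loc[:, self.COLUMNS].copy()
        if len(df):
            if (df["position"] < 1).any():
                raise ValueError("protein positions must be >= 1")
            bad = set(df["mclass"]) - MUTATION_CLASSES
            if bad:
                raise ValueError(f"unknown mutation classes: {sorted(bad)}")
        # collapse duplicate alleles; stable sort keeps output deterministic
        df = df.drop_duplicates(subset=["sample_id", "gene", "position", "alt_aa"])
        df = df.sort_values(self.COLUMNS, kind="mergesort").reset_index(drop=True)
        self.df = df
        self.n_skipped = int(n_skipped)
        self.cancer_type_rule = cancer_type_rule

    @classmethod
    def from_records(cls, records: Iterable[MutationRecord], n_skipped: int = 0,
                     cancer_type_rule: str = "tissue+histology") -> "MutationCatalog":
        rows = [(r.sample_id, r.gene, r.position, r.ref_aa, r.alt_aa, r.mclass, r.tissue, r.histology)
                for r in records]
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        return cls(df, n_skipped=n_skipped, cancer_type_rule=cancer_type_rule)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> List[MutationRecord]:
        return [MutationRecord(*row) for row in self.df.itertuples(index=False, name=None)]

    def cancer_types(self) -> pd.Series:
        """Per-row cancer-type label derived from the configured rule."""
        if self.cancer_type_rule == "tissue":
            return self.df["tissue"].copy()
        if self.cancer_type_rule == "histology":
            return self.df["histology"].copy()
        return self.df["tissue"].str.cat(self.df["histology"], sep="/")

    def scopes(self) -> List[str]:
        """All cancer-type labels present in the catalog, sorted."""
        return sorted(self.cancer_types().unique())

    def subset(self, scope: str) -> "MutationCatalog":
        """Restrict to one cancer type; ``"pan-cancer"`` returns self."""
        if scope == "pan-cancer":
            return self
        mask = self.cancer_types() == scope
        return MutationCatalog(self.df[mask], n_skipped=0, cancer_type_rule=self.cancer_type_rule)

    def nonsynonymous(self) -> pd.DataFrame:
        """Allele rows excluding synonymous changes (the statistical universe)."""
        return self.df[self.df["mclass"] != "synonymous"]

    def n_alleles(self) -> int:
        return len(self.nonsynonymous())

    def samples(self) -> FrozenSet[str]:
        """Samples carrying at least one non-synonymous allele."""
        return frozenset(self.nonsynonymous()["sample_id"])

    def n_samples(self) -> int:
        return len(self.samples())


@dataclass
class DomainInstance:
    """One family domain hit on one protein, with its residue->column map.

    ``colmap`` is partial: only alignment match states appear; residues
    emitted by insertion states have no column and are unmapped.
    """

    gene: str
    family_id: str
    start: int
    end: int
    colmap: Dict[int, int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain start {self.start} > end {self.end} on {self.gene}")
        if self.start < 1:
            raise ValueError("domain coordinates are 1-based")
        for pos in self.colmap:
            if not (self.start <= pos <= self.end):
                raise ValueError(
                    f"colmap position {pos} outside [{self.start},{self.end}] on {self.gene}")
        cols = list(self.colmap.values())
        if len(set(cols)) != len(cols):
            raise ValueError(f"colmap not injective on {self.gene}/{self.family_id}")

    @classmethod
    def from_offset(cls, gene: str, family_id: str, start: int, end: int) -> "DomainInstance":
        """Contiguous match-state map: position start+k-1 -> column k."""
        colmap = {pos: pos - start + 1 for pos in range(start, end + 1)}
        return cls(gene, family_id, start, end, colmap)

    def column_of(self, position: int) -> Optional[int]:
        return self.colmap.get(position)

    @property
    def mapped_positions(self) -> List[int]:
        return sorted(self.colmap)


class DomainMap:
    """All domain instances of the proteome plus protein lengths."""

    def __init__(self, instances: Sequence[DomainInstance],
                 gene_lengths: Optional[Mapping[str, int]] = None) -> None:
        self.instances = sorted(instances, key=lambda i: (i.gene, i.family_id, i.start, i.end))
        self.gene_lengths: Dict[str, int] = dict(gene_lengths or {})
        for inst in self.instances:
            length = self.gene_lengths.get(inst.gene)
            if length is not None and inst.end > length:
                raise ValueError(f"instance on {inst.gene} ends past protein length {length}")
        self.by_gene: Dict[str, List[DomainInstance]] = {}
        for inst in self.instances:
            self.by_gene.setdefault(inst.gene, []).append(inst)
        self._position_index: Optional[Dict[str, Dict[int, List[Tuple[str, int]]]]] = None

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def families(self) -> List[str]:
        return sorted({i.family_id for i in self.instances})

    @property
    def genes(self) -> List[str]:
        return sorted(self.by_gene)

    def family_genes(self, family_id: str) -> FrozenSet[str]:
        return frozenset(i.gene for i in self.instances if i.family_id == family_id)

    def proteome_length(self) -> int:
        """Total residues across all proteins with a known length."""
        return int(sum(self.gene_lengths.values()))

    def n_instances_with_column(self, family_id: str, column: int) -> int:
        """Instances in the proteome whose match-state map includes the column."""
        return sum(1 for i in self.instances
                   if i.family_id == family_id and column in i.colmap.values())

    def position_index(self) -> Dict[str, Dict[int, List[Tuple[str, int]]]]:
        """gene -> residue -> [(family, column)] with overlap resolution.

        Overlapping instances of *different* families each contribute one
        entry.  Overlapping instances of the *same* family resolve to the
        lowest-start instance covering the residue.
        """
        if self._position_index is not None:
            return self._position_index
        index: Dict[str, Dict[int, List[Tuple[str, int]]]] = {}
        for gene, insts in self.by_gene.items():
            per_family: Dict[str, Dict[int, int]] = {}
            for inst in insts:  # already sorted by (family, start): first mapping wins
                fam = per_family.setdefault(inst.family_id, {})
                for pos, col in inst.colmap.items():
                    fam.setdefault(pos, col)
            gene_idx: Dict[int, List[Tuple[str, int]]] = {}
            for family_id in sorted(per_family):
                for pos, col in per_family[family_id].items():
                    gene_idx.setdefault(pos, []).append((family_id, col))
            index[gene] = gene_idx
        self._position_index = index
        return index


@dataclass(frozen=True)
class PositionKey:
    """A family alignment column together with its conservation class."""

    family_id: str
    column: int
    cclass: str

    def __post_init__(self) -> None:
        if self.cclass not in ("conserved", "nonconserved"):
            raise ValueError(f"cclass must be conserved|nonconserved, got {self.cclass!r}")

    def __str__(self) -> str:
        return f"{self.family_id}:{self.column}:{self.cclass}"


class FamilyColumnTable:
    """Per-family alignment column summaries (consensus, conservation)."""

    COLUMNS = ["family_id", "column", "consensus_aa", "conservation_fraction", "aux_label"]

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.copy()
        if "aux_label" not in df.columns:
            df["aux_label"] = ""
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"family column table missing columns: {missing}")
        df = df.loc[:, self.COLUMNS]
        if len(df):
            cf = df["conservation_fraction"]
            if ((cf < 0) | (cf > 1)).any():
                raise ValueError("conservation_fraction must lie in [0,1]")
        df["is_conserved"] = df["conservation_fraction"] >= CONSERVATION_THRESHOLD
        df = df.sort_values(["family_id", "column"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self._lookup = {(r.family_id, r.column): r
                        for r in df.itertuples(index=False)}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, key: Tuple[str, int]) -> bool:
        return key in self._lookup

    def is_conserved(self, family_id: str, column: int) -> bool:
        return bool(self._lookup[(family_id, column)].is_conserved)

    def consensus(self, family_id: str, column: int) -> str:
        return self._lookup[(family_id, column)].consensus_aa

    def cclass(self, family_id: str, column: int) -> str:
        return "conserved" if self.is_conserved(family_id, column) else "nonconserved"

    def key(self, family_id: str, column: int) -> PositionKey:
        return PositionKey(family_id, column, self.cclass(family_id, column))


@dataclass
class PathwayNode:
    """A pathway gene set inside a parent-child hierarchy."""

    pathway_id: str
    name: str
    members: FrozenSet[str]
    children: List["PathwayNode"] = field(default_factory=list)
    is_root: bool = False

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def size(self) -> int:
        return len(self.members)


class PathwayForest:
    """Forest of pathway nodes; roots are front-page (parentless) pathways."""

    def __init__(self, nodes: Mapping[str, PathwayNode], roots: Sequence[PathwayNode]) -> None:
        self.nodes = dict(nodes)
        self.roots = sorted(roots, key=lambda n: n.pathway_id)

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, pathway_id: str) -> PathwayNode:
        return self.nodes[pathway_id]

    def all_nodes(self) -> List[PathwayNode]:
        return [self.nodes[k] for k in sorted(self.nodes)]


class CouplingTable:
    """Receptor -> G-protein-family couplings with provenance.

    The coupling constant c(receptor, family) is 1 iff a primary *or*
    secondary coupling entry exists for the pair.
    """

    COLUMNS = ["receptor", "gfamily", "provenance"]

    def __init__(self, df: pd.DataFrame,
                 families: Iterable[str] = tuple(DEFAULT_GPROTEIN_FAMILIES)) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"coupling table missing columns: {missing}")
        families = tuple(families)
        bad = set(df["gfamily"]) - set(families)
        if bad:
            raise ValueError(f"unknown G-protein families in coupling table: {sorted(bad)}")
        bad_prov = set(df["provenance"]) - {"primary", "secondary"}
        if bad_prov:
            raise ValueError(f"coupling provenance must be primary|secondary: {sorted(bad_prov)}")
        df = df.loc[:, self.COLUMNS].drop_duplicates(subset=["receptor", "gfamily"])
        self.df = df.sort_values(self.COLUMNS, kind="mergesort").reset_index(drop=True)
        self.families = families
        self._pairs = set(zip(self.df["receptor"], self.df["gfamily"]))

    def __len__(self) -> int:
        return len(self.df)

    def c(self, receptor: str, family: str) -> int:
        return 1 if (receptor, family) in self._pairs else 0

    def receptors(self, family: str) -> FrozenSet[str]:
        return frozenset(r for r, f in self._pairs if f == family)

    def groups_of(self, receptor: str) -> FrozenSet[str]:
        return frozenset(f for r, f in self._pairs if r == receptor)


@dataclass
class AnalysisThresholds:
    """Retention thresholds for enrichment and exclusivity calling.

    Defaults are the published heuristics: per-cancer positions pass with 5
    observed or 2.5 expected alleles (pan-cancer 20 / 5), significance needs
    log-odds >= 0 and q <= 0.01, exclusivity needs q <= 0.1 on both the
    Fisher and the pathway-background test, and pairs qualify with at least
    5 (per-cancer) / 50 (pan-cancer) unique mutated samples.
    """

    obs_floor_cancer: float = 5.0
    exp_floor_cancer: float = 2.5
    obs_floor_pan: float = 20.0
    exp_floor_pan: float = 5.0
    enrichment_q_max: float = 0.01
    min_log_odds: float = 0.0
    min_samples_cancer: int = 5
    min_samples_pan: int = 50
    exclusivity_q_max: float = 0.1
    pair_q_max: float = 0.1

    def obs_floor(self, scope: str) -> float:
        return self.obs_floor_pan if scope == "pan-cancer" else self.obs_floor_cancer

    def exp_floor(self, scope: str) -> float:
        return self.exp_floor_pan if scope == "pan-cancer" else self.exp_floor_cancer

    def min_samples(self, scope: str) -> int:
        return self.min_samples_pan if scope == "pan-cancer" else self.min_samples_cancer
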