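"""Readers and writers for the tabular input/output formats.

Mutation catalogs arrive as COSMIC-style or minimal-MAF TSVs with an HGVS-p
protein-change string per row; domain assignments as an hmmscan-style table
with either contiguous ("offset") or explicit residue->column maps; pathways
as GMT plus a parent-child edge TSV.  All writers emit plain TSV so that a
read -> write -> read round trip is lossless.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import pandas as pd
import yaml

from .types import (
    CouplingTable,
    DomainInstance,
    DomainMap,
    FamilyColumnTable,
    MutationCatalog,
    PathwayForest,
    PathwayNode,
)

PathLike = Union[str, Path]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CHANGE_RE = re.compile(r"^p\.\(?([A-Z])(\d+)([A-Za-z*=][A-Za-z0-9*]*)?\)?$")

#: required columns per mutation-table dialect, mapped to canonical names
DIALECTS = {
    "cosmic_tsv": {
        "sample_id": "sample_id",
        "gene": "gene",
        "protein_change": "protein_change",
        "tissue": "tissue",
        "histology": "histology",
    },
    "maf_min": {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene",
        "HGVSp_Short": "protein_change",
    },
}


def parse_protein_change(change: str) -> Optional[Tuple[str, int, str, str]]:
    """Parse an HGVS-p style string into (ref, position, alt, class).

    Accepted forms: ``p.R273H`` (missense; synonymous when ref == alt or
    alt is ``=``), ``p.R201*`` (stop gain), and a ``fs`` suffix anywhere
    after the position (frameshift, e.g. ``p.G12fs`` or ``p.V600Efs*3``).
    Anything else (``p.?``, in-frame indels, extensions) returns None and
    is counted by the caller, not raised.
    """
    m = _CHANGE_RE.match(change.strip())
    if not m:
        return None
    ref, pos_s, suffix = m.group(1), m.group(2), m.group(3) or ""
    pos = int(pos_s)
    if pos < 1 or ref not in _AA:
        return None
    if suffix == "*":
        return ref, pos, "*", "stop_gain"
    if "fs" in suffix:
        return ref, pos, "fs", "frameshift"
    if suffix == "=":
        return ref, pos, ref, "synonymous"
    if len(suffix) == 1 and suffix in _AA:
        mclass = "synonymous" if suffix == ref else "missense"
        return ref, pos, suffix, mclass
    return None


def read_mutation_table(path: PathLike, dialect: str = "cosmic_tsv",
                        cancer_type_rule: str = "tissue+histology") -> MutationCatalog:
    """Read a somatic mutation TSV into a MutationCatalog.

    Rows whose protein-change string cannot be parsed are skipped and
    counted on the returned catalog (``n_skipped``), never fatal.  A missing
    required column is a hard error naming the column.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in colmap:
        if col not in df.columns:
            raise ValueError(f"mutation table {path} missing required column {col!r}")
    df = df.rename(columns=colmap)
    for optional in ("tissue", "histology"):
        if optional not in df.columns:
            df[optional] = "NS"
    rows = []
    n_skipped = 0
    for r in df.itertuples(index=False):
        parsed = parse_protein_change(str(r.protein_change))
        if parsed is None:
            n_skipped += 1
            continue
        ref, pos, alt, mclass = parsed
        rows.append((r.sample_id, r.gene, pos, ref, alt, mclass, r.tissue, r.histology))
    if not rows:
        warnings.warn(f"mutation table {path}: no parseable rows ({n_skipped} skipped)")
    out = pd.DataFrame(rows, columns=MutationCatalog.COLUMNS)
    return MutationCatalog(out, n_skipped=n_skipped, cancer_type_rule=cancer_type_rule)


def write_mutation_table(catalog: MutationCatalog, path: PathLike) -> None:
    """Write a catalog back to the cosmic_tsv dialect (one row per allele)."""
    df = catalog.df.copy()
    alt = df["alt_aa"].where(df["alt_aa"].isin(list(_AA)), other=df["alt_aa"])
    change = "p." + df["ref_aa"] + df["position"].astype(str) + alt
    change = change.where(df["alt_aa"] != "fs", "p." + df["ref_aa"] + df["position"].astype(str) + "fs")
    out = pd.DataFrame({
        "sample_id": df["sample_id"],
        "gene": df["gene"],
        "protein_change": change,
        "tissue": df["tissue"],
        "histology": df["histology"],
    })
    out.to_csv(path, sep="\t", index=False)


def _parse_colmap(spec: str, start: int, end: int) -> Dict[int, int]:
    if spec == "offset":
        return {pos: pos - start + 1 for pos in range(start, end + 1)}
    colmap: Dict[int, int] = {}
    for pair in spec.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        pos_s, col_s = pair.split(":")
        colmap[int(pos_s)] = int(col_s)
    return colmap


def read_domain_assignments(path: PathLike) -> DomainMap:
    """Read an hmmscan-style domain table into a DomainMap.

    Columns: gene, family_id, start, end, protein_length, colmap where
    colmap is either ``offset`` (contiguous match) or explicit
    ``pos:col;pos:col`` pairs.  start > end or out-of-range map entries are
    hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "family_id": str})
    required = ["gene", "family_id", "start", "end", "protein_length", "colmap"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"domain table {path} missing required column {col!r}")
    instances = []
    gene_lengths: Dict[str, int] = {}
    for r in df.itertuples(index=False):
        start, end = int(r.start), int(r.end)
        colmap = _parse_colmap(str(r.colmap), start, end)
        instances.append(DomainInstance(r.gene, r.family_id, start, end, colmap))
        gene_lengths[r.gene] = int(r.protein_length)
    return DomainMap(instances, gene_lengths=gene_lengths)


def write_domain_assignments(domain_map: DomainMap, path: PathLike) -> None:
    rows = []
    for inst in domain_map.instances:
        offset = {pos: pos - inst.start + 1 for pos in range(inst.start, inst.end + 1)}
        if inst.colmap == offset:
            spec = "offset"
        else:
            spec = ";".join(f"{p}:{c}" for p, c in sorted(inst.colmap.items()))
        rows.append((inst.gene, inst.family_id, inst.start, inst.end,
                     domain_map.gene_lengths.get(inst.gene, inst.end), spec))
    pd.DataFrame(rows, columns=["gene", "family_id", "start", "end", "protein_length", "colmap"]) \
        .to_csv(path, sep="\t", index=False)


def read_family_columns(path: PathLike) -> FamilyColumnTable:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "consensus_aa": str})
    if "aux_label" in df.columns:
        df["aux_label"] = df["aux_label"].fillna("").astype(str)
    return FamilyColumnTable(df)


def write_family_columns(table: FamilyColumnTable, path: PathLike) -> None:
    table.df.drop(columns=["is_conserved"]).to_csv(path, sep="\t", index=False)


def read_pathway_hierarchy(gmt_path: PathLike, hierarchy_path: PathLike) -> PathwayForest:
    """Read GMT gene sets plus a parent-child TSV into a pathway forest.

    Every hierarchy edge must reference pathway ids present in the GMT; a
    cycle is a hard error listing one offending cycle.  Roots are the
    parentless pathways (the front-page list).
    """
    sets: Dict[str, Tuple[str, frozenset]] = {}
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {gmt_path}: {line[:80]!r}")
            pid, name, genes = parts[0], parts[1], parts[2:]
            sets[pid] = (name, frozenset(g for g in genes if g))
    edges = pd.read_csv(hierarchy_path, sep="\t", dtype=str)
    for col in ("parent", "child"):
        if col not in edges.columns:
            raise ValueError(f"hierarchy table {hierarchy_path} missing column {col!r}")
    graph = nx.DiGraph()
    graph.add_nodes_from(sets)
    for r in edges.itertuples(index=False):
        for pid in (r.parent, r.child):
            if pid not in sets:
                raise ValueError(f"hierarchy references unknown pathway id {pid!r}")
        graph.add_edge(r.parent, r.child)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path_s = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise ValueError(f"pathway hierarchy contains a cycle: {path_s}")
    nodes = {pid: PathwayNode(pid, name, members) for pid, (name, members) in sets.items()}
    for parent, child in graph.edges:
        nodes[parent].children.append(nodes[child])
    for node in nodes.values():
        node.children.sort(key=lambda n: n.pathway_id)
    roots = [nodes[pid] for pid in sets if graph.in_degree(pid) == 0]
    for root in roots:
        root.is_root = True
    return PathwayForest(nodes, roots)


def write_pathway_hierarchy(forest: PathwayForest, gmt_path: PathLike,
                            hierarchy_path: PathLike) -> None:
    with open(gmt_path, "w") as fh:
        for node in forest.all_nodes():
            fh.write("\t".join([node.pathway_id, node.name, *sorted(node.members)]) + "\n")
    rows = [(n.pathway_id, c.pathway_id) for n in forest.all_nodes() for c in n.children]
    pd.DataFrame(rows, columns=["parent", "child"]).to_csv(hierarchy_path, sep="\t", index=False)


def read_expression(path: PathLike) -> pd.DataFrame:
    """Differential-expression summary: cancer_type, gene, base_mean, lfc, padj."""
    df = pd.read_csv(path, sep="\t", dtype={"cancer_type": str, "gene": str})
    required = ["cancer_type", "gene", "base_mean", "lfc", "padj"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"expression table {path} missing column {col!r}")
    if len(df) and (df["base_mean"] < 0).any():
        raise ValueError("base_mean must be >= 0")
    return df.loc[:, required]


def write_expression(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_couplings(path: PathLike) -> CouplingTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CouplingTable(df)


def write_couplings(table: CouplingTable, path: PathLike) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_gene_scores(path: PathLike) -> pd.Series:
    """Gene -> mutation-tolerance score table (larger = more tolerant)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "score"):
        if col not in df.columns:
            raise ValueError(f"gene score table {path} missing column {col!r}")
    return pd.Series(df["score"].to_numpy(float), index=df["gene"])


def annotate_dubious_genes(gene_scores: Union[Mapping[str, float], pd.Series],
                           top_fraction: float = 0.02) -> Set[str]:
    """Flag the most mutation-tolerant genes as dubious drivers.

    Returns the ceil(top_fraction * N) highest-scoring genes; ties at the
    cutoff score are all included.  Empty input yields an empty set.
    """
    scores = pd.Series(dict(gene_scores)) if not isinstance(gene_scores, pd.Series) else gene_scores
    if len(scores) == 0:
        return set()
    k = math.ceil(top_fraction * len(scores))
    cutoff = scores.sort_values(ascending=False).iloc[k - 1]
    return set(scores.index[scores >= cutoff])


def sha256_of(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(outdir: PathLike,
                  enrichment: Optional[pd.DataFrame] = None,
                  exclusivity: Optional[pd.DataFrame] = None,
                  network_edges: Optional[pd.DataFrame] = None,
                  extra_tables: Optional[Mapping[str, pd.DataFrame]] = None,
                  config: Optional[Mapping] = None,
                  seed: Optional[int] = None,
                  input_paths: Optional[Mapping[str, PathLike]] = None,
                  counters: Optional[Mapping[str, int]] = None) -> Dict[str, Path]:
    """Write result TSVs plus a reproducibility manifest.

    Empty result tables still produce header-only TSVs; the manifest records
    the run configuration, master seed, per-stage counters, and a sha256
    checksum per input file so a rerun can be verified byte for byte.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    written: Dict[str, Path] = {}

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[name] = path

    if enrichment is not None:
        _emit("enrichment", enrichment)
    if exclusivity is not None:
        _emit("exclusivity", exclusivity)
    if network_edges is not None:
        _emit("network_edges", network_edges)
    for name, df in (extra_tables or {}).items():
        _emit(name, df)
    manifest = {
        "seed": seed,
        "config": json.loads(json.dumps(config, default=str)) if config is not None else None,
        "counters": dict(counters or {}),
        "inputs": {name: {"path": str(p), "sha256": sha256_of(p)}
                   for name, p in sorted((input_paths or {}).items())},
        "outputs": sorted(str(p.name) for p in written.values()),
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written["manifest"] = manifest_path
    return written
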