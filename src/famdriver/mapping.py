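"""Project mutations onto family alignment columns.

A non-synonymous mutation landing on a match-state residue of a domain
instance yields one position hit per family covering it (overlapping
instances of different families each count once; overlapping instances of
the same family resolve to the lowest-start instance).  Mutations outside
domains, or on insertion-state residues, are tallied but produce no hit.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .types import DomainMap, FamilyColumnTable, MutationCatalog, PositionKey

HIT_COLUMNS = ["family_id", "column", "cclass", "sample_id", "gene", "position",
               "mclass", "tissue", "histology", "cancer_type"]


def map_catalog(catalog: MutationCatalog, domain_map: DomainMap,
                family_columns: FamilyColumnTable) -> Tuple[pd.DataFrame, int]:
    """Map every non-synonymous allele to family alignment columns.

    Returns the position-hit table (one row per allele per covering family)
    and the count of alleles that mapped to no column.  Conservation of
    mutations holds: hits from distinct alleles + unmapped = total alleles,
    counting each allele once even when two families cover it.
    """
    index = domain_map.position_index()
    nonsyn = catalog.nonsynonymous()
    cancer_types = catalog.cancer_types().loc[nonsyn.index]
    rows: List[Tuple] = []
    unmapped = 0
    for (row, ct) in zip(nonsyn.itertuples(index=False), cancer_types):
        gene_idx = index.get(row.gene)
        entries = gene_idx.get(row.position) if gene_idx else None
        if not entries:
            unmapped += 1
            continue
        for family_id, column in entries:
            if (family_id, column) not in family_columns:
                raise KeyError(f"no column summary for {family_id} column {column}")
            cclass = family_columns.cclass(family_id, column)
            rows.append((family_id, column, cclass, row.sample_id, row.gene,
                         row.position, row.mclass, row.tissue, row.histology, ct))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    hits = hits.sort_values(HIT_COLUMNS, kind="mergesort").reset_index(drop=True)
    return hits, unmapped


def call_conservation(residue_counts: Mapping[str, int]) -> Tuple[bool, str]:
    """Call a column's conservation flag and consensus residue.

    Conserved iff the most frequent residue covers >= 50% of sequences;
    consensus is the most frequent residue, ties broken alphabetically.
    """
    total = sum(residue_counts.values())
    if total == 0:
        raise ValueError("cannot call conservation with zero sequences")
    # sort by (-count, residue): top row is the alphabetical argmax
    consensus, count = sorted(residue_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return count / total >= 0.5, consensus


class AnchorTable:
    """Per-family anchor lists for structural numbering schemes.

    An anchor pins a dotted structural label (e.g. ``3.50`` in the
    Ballesteros-Weinstein scheme, ``G.hfs2.2`` in the common G-alpha
    numbering) to an alignment column; other columns in the same segment are
    labelled by adding the signed column offset to the anchor's last dotted
    component.
    """

    SCHEMES = ("pfam", "ballesteros_weinstein", "cgn")
    COLUMNS = ["family_id", "scheme", "column", "label"]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"anchor table missing columns: {missing}")
        bad = set(df["scheme"]) - set(self.SCHEMES)
        if bad:
            raise ValueError(f"unknown numbering schemes: {sorted(bad)}")
        df = df.loc[:, self.COLUMNS].sort_values(
            ["family_id", "scheme", "column"], kind="mergesort").reset_index(drop=True)
        for (fam, scheme), grp in df.groupby(["family_id", "scheme"]):
            if not grp["column"].is_monotonic_increasing or grp["column"].duplicated().any():
                raise ValueError(f"anchors for {fam}/{scheme} must strictly increase in column")
        self.df = df

    @classmethod
    def from_tsv(cls, path) -> "AnchorTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"family_id": str, "scheme": str,
                                                      "label": str}))

    def anchors(self, family_id: str, scheme: str) -> List[Tuple[int, str]]:
        grp = self.df[(self.df["family_id"] == family_id) & (self.df["scheme"] == scheme)]
        return list(zip(grp["column"].astype(int), grp["label"]))


def _apply_offset(label: str, offset: int) -> Optional[str]:
    head, _, tail = label.rpartition(".")
    if not head or not tail.isdigit():
        return None
    value = int(tail) + offset
    if value <= 0:
        return None
    return f"{head}.{value}"


def label_position(family_id: str, column: int, family_columns: FamilyColumnTable,
                   anchor_table: Optional[AnchorTable] = None,
                   scheme: str = "pfam") -> str:
    """Label an alignment column under a numbering scheme.

    The consecutive-numbering label is the consensus residue (uppercase when
    conserved, lowercase otherwise) followed by the column index, e.g.
    ``R12``.  Anchored schemes take the nearest anchor and add the signed
    column offset to the last dotted component of its label; a query that
    falls before its segment start falls back to the consecutive label with
    a warning.
    """
    consensus = family_columns.consensus(family_id, column)
    conserved = family_columns.is_conserved(family_id, column)
    pfam_label = f"{consensus.upper() if conserved else consensus.lower()}{column}"
    if scheme == "pfam":
        return pfam_label
    anchors = anchor_table.anchors(family_id, scheme) if anchor_table is not None else []
    if not anchors:
        return pfam_label
    nearest_col, nearest_label = min(anchors, key=lambda a: (abs(a[0] - column), a[0]))
    labelled = _apply_offset(nearest_label, column - nearest_col)
    if labelled is None:
        warnings.warn(f"column {column} precedes segment of anchor {nearest_label}; "
                      f"falling back to consecutive label {pfam_label}")
        return pfam_label
    return labelled


def classify_deleterious(mclass: str, is_conserved_column: Optional[bool]) -> bool:
    """Deleterious = stop gain, frameshift, or missense at a conserved column."""
    if mclass in ("stop_gain", "frameshift"):
        return True
    if mclass == "missense":
        return bool(is_conserved_column)
    return False


def position_sample_sets(hits: pd.DataFrame) -> Dict[PositionKey, frozenset]:
    """Unique-sample sets per position key, aggregated over family members."""
    out: Dict[PositionKey, frozenset] = {}
    if not len(hits):
        return out
    for (fam, col, cclass), grp in hits.groupby(["family_id", "column", "cclass"]):
        out[PositionKey(fam, int(col), cclass)] = frozenset(grp["sample_id"])
    return out
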