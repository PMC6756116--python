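"""Integrative G-protein pathway activity and mutation-burden summaries.

The activity of a heterotrimeric G-protein family in a cancer type is a
coupling-gated sum over (G-protein, receptor) pairs of scaled expression
products:

    A_G = sum_g sum_r  m_g s_g  x  m_r s_r  x  c(r, G)

where m is the base mean of normalized counts, s is the log fold change
when significant (padj < 0.01) and 1 otherwise, and c is 1 iff the
receptor's coupling to the family is reported (primary or secondary).  The
default reads the scaling multiplicatively (m x s); an exponent reading
(m ** s) is available behind ``mode="exponent"`` for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mapping import classify_deleterious
from .types import (
    DEFAULT_GPROTEIN_FAMILIES,
    CouplingTable,
    DomainMap,
    FamilyColumnTable,
    MutationCatalog,
)

#: default known activating G-alpha hotspots: switch-I / switch-II arginine
#: and glutamine recurrently mutated in cancer
DEFAULT_GALPHA_HOTSPOTS: Tuple[Tuple[str, int], ...] = (
    ("GNAS", 201), ("GNAQ", 209), ("GNA11", 209),
)


@dataclass
class GActivityResult:
    cancer_type: str
    gfamily: str
    activity: float
    n_pairs: int


def scaled_expression(base_mean: float, lfc: float, padj: Optional[float],
                      alpha: float = 0.01, mode: str = "multiplicative") -> float:
    """m x s with s = lfc when padj < alpha, else 1; missing padj means 1."""
    if base_mean < 0:
        raise ValueError("base_mean must be >= 0")
    significant = padj is not None and not (isinstance(padj, float) and math.isnan(padj)) \
        and padj < alpha
    scale = lfc if significant else 1.0
    if mode == "exponent":
        return float(base_mean ** scale)
    if mode != "multiplicative":
        raise ValueError("mode must be multiplicative or exponent")
    return float(base_mean * scale)


def gprotein_activity(expression: pd.DataFrame, coupling: CouplingTable,
                      cancer_type: str, gfamily: str,
                      family_def: Mapping[str, Sequence[str]] = DEFAULT_GPROTEIN_FAMILIES,
                      alpha: float = 0.01, mode: str = "multiplicative") -> GActivityResult:
    """Activity A_G of one G-protein family in one cancer type.

    Receptors or G-proteins without an expression row contribute nothing;
    A_G is exactly additive over the coupled (G-protein, receptor) pairs.
    """
    if gfamily not in family_def:
        raise ValueError(f"unknown G-protein family {gfamily!r}")
    expr = expression[expression["cancer_type"] == cancer_type]
    values = {r.gene: scaled_expression(r.base_mean, r.lfc, r.padj, alpha, mode)
              for r in expr.itertuples()}
    receptors = sorted(coupling.receptors(gfamily))
    activity = 0.0
    n_pairs = 0
    for gprot in family_def[gfamily]:
        if gprot not in values:
            continue
        for receptor in receptors:
            if receptor not in values:
                continue
            activity += values[gprot] * values[receptor]
            n_pairs += 1
    return GActivityResult(cancer_type, gfamily, activity, n_pairs)


def activity_matrix(expression: pd.DataFrame, coupling: CouplingTable,
                    family_def: Mapping[str, Sequence[str]] = DEFAULT_GPROTEIN_FAMILIES,
                    alpha: float = 0.01, mode: str = "multiplicative") -> pd.DataFrame:
    """Cancer type x G-family activity table."""
    rows = []
    for ct in sorted(expression["cancer_type"].unique()):
        for gfamily in family_def:
            res = gprotein_activity(expression, coupling, ct, gfamily, family_def, alpha, mode)
            rows.append((ct, gfamily, res.activity, res.n_pairs))
    return pd.DataFrame(rows, columns=["cancer_type", "gfamily", "activity", "n_pairs"])


def group_mutation_summary(catalog: MutationCatalog, coupling: CouplingTable,
                           hits: pd.DataFrame,
                           hotspot_list: Sequence[Tuple[str, int]] = DEFAULT_GALPHA_HOTSPOTS,
                           family_def: Mapping[str, Sequence[str]] = DEFAULT_GPROTEIN_FAMILIES,
                           ) -> pd.DataFrame:
    """Per cancer type and coupling group: deleterious and hotspot fractions.

    The deleterious fraction is the share of the cancer type's unique
    samples carrying at least one stop gain, frameshift, or
    conserved-column missense in any receptor of the group.  The hotspot
    fraction is the share carrying an allele at a listed activating G-alpha
    residue of the family's member genes.  A receptor with both a primary
    and a secondary coupling counts in both groups.
    """
    df = catalog.nonsynonymous().copy()
    df["cancer_type"] = catalog.cancer_types().loc[df.index]
    # deleterious flag per allele: truncating anywhere, missense at conserved column
    conserved_sites = set()
    if len(hits):
        mask = (hits["mclass"] == "missense") & (hits["cclass"] == "conserved")
        conserved_sites = set(zip(hits.loc[mask, "sample_id"], hits.loc[mask, "gene"],
                                  hits.loc[mask, "position"]))
    truncating = df["mclass"].isin(["stop_gain", "frameshift"])
    cons_missense = [
        (s, g, p) in conserved_sites
        for s, g, p in zip(df["sample_id"], df["gene"], df["position"])]
    df["deleterious"] = truncating.to_numpy() | np.asarray(cons_missense, dtype=bool)

    hotspot_set = set(hotspot_list)
    df["is_hotspot"] = [(g, p) in hotspot_set for g, p in zip(df["gene"], df["position"])]

    rows = []
    for ct, grp in df.groupby("cancer_type"):
        n_samples = grp["sample_id"].nunique()
        for gfamily in family_def:
            receptors = coupling.receptors(gfamily)
            if not receptors:
                warnings.warn(f"coupling group {gfamily} has no receptors")
            del_samples = set(grp.loc[grp["deleterious"] & grp["gene"].isin(receptors),
                                      "sample_id"]) if receptors else set()
            members = set(family_def[gfamily])
            hot_samples = set(grp.loc[grp["is_hotspot"] & grp["gene"].isin(members),
                                      "sample_id"])
            rows.append((ct, gfamily, len(del_samples),
                         len(del_samples) / n_samples if n_samples else 0.0,
                         len(hot_samples),
                         len(hot_samples) / n_samples if n_samples else 0.0,
                         n_samples))
    return pd.DataFrame(rows, columns=[
        "cancer_type", "gfamily", "n_deleterious_samples", "deleterious_fraction",
        "n_hotspot_samples", "hotspot_fraction", "n_samples"])


def tf_target_jaccard(targets_by_tf: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of transcription-factor target sets.

    J(A, B) = |A n B| / |A u B|; two empty sets score 0 by convention, a
    set against itself scores 1.
    """
    names = sorted(targets_by_tf)
    sets = {name: frozenset(targets_by_tf[name]) for name in names}
    matrix = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b:
                score = 1.0  # unit diagonal by definition
            else:
                union = sets[a] | sets[b]
                score = len(sets[a] & sets[b]) / len(union) if union else 0.0
            matrix.loc[a, b] = matrix.loc[b, a] = score
    return matrix
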