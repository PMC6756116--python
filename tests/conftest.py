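"""Shared fixtures: tiny hand-built inputs and planted synthetic cohorts."""

import pandas as pd
import pytest

from famdriver import (
    DomainInstance,
    DomainMap,
    FamilyColumnTable,
    MutationCatalog,
    PairSpec,
    SyntheticConfig,
    generate_mutations,
    generate_pathways,
    generate_proteome,
)


def make_catalog(rows, rule="tissue+histology"):
    """rows: (sample, gene, pos, ref, alt, mclass[, tissue, histology])."""
    full = []
    for r in rows:
        r = tuple(r)
        if len(r) == 6:
            r = r + ("T", "H")
        full.append(r)
    df = pd.DataFrame(full, columns=MutationCatalog.COLUMNS)
    return MutationCatalog(df, cancer_type_rule=rule)


def make_columns(entries):
    """entries: (family, column, consensus, conservation_fraction)."""
    df = pd.DataFrame(entries, columns=["family_id", "column", "consensus_aa",
                                        "conservation_fraction"])
    return FamilyColumnTable(df)


@pytest.fixture
def toy_domain_map():
    """One gene, one family instance 40-120 with a contiguous offset map."""
    inst = DomainInstance.from_offset("G1", "F1", 40, 120)
    return DomainMap([inst], gene_lengths={"G1": 200})


@pytest.fixture
def planted_pair_config():
    """The planted-exclusivity study conditions: 30/30/0 over 500 samples."""
    return SyntheticConfig(
        seed=11,
        exclusive_pairs=[PairSpec("F01", 10, "F02", 20, 30, 30, 0)],
    )


@pytest.fixture
def planted_pair_data(planted_pair_config):
    cfg = planted_pair_config
    domain_map, columns = generate_proteome(cfg)
    catalog, truth = generate_mutations(cfg, domain_map)
    forest = generate_pathways(cfg, domain_map)
    return cfg, domain_map, columns, catalog, truth, forest
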