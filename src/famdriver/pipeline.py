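"""End-to-end orchestration: inputs -> mapping -> enrichment -> exclusivity
-> network -> signaling, with a reproducibility manifest.

All randomness flows from one master seed; a rerun with the same seed and
configuration produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd
import yaml

from . import io as fio
from .enrichment import ShuffleSpec, enrich_positions
from .exclusivity import build_network, exclusivity_scan, network_to_edges, select_pathways
from .mapping import map_catalog
from .signaling import activity_matrix, group_mutation_summary
from .types import AnalysisThresholds, MutationCatalog


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One reproducible run: input paths, scopes, thresholds, seed.

    ``scopes`` may list ``"pan-cancer"``, explicit cancer-type labels, or
    ``"per-cancer"`` which expands to every cancer type in the catalog.
    """

    mutations: str
    domains: str
    family_columns: str
    gmt: str
    hierarchy: str
    outdir: str
    seed: int
    expression: Optional[str] = None
    couplings: Optional[str] = None
    gene_scores: Optional[str] = None
    scopes: List[str] = field(default_factory=lambda: ["per-cancer", "pan-cancer"])
    dialect: str = "cosmic_tsv"
    cancer_type_rule: str = "tissue+histology"
    universe_rule: str = "same_class"
    shuffle_model: str = "gene_level"
    n_shuffles: int = 100
    eq1_mode: str = "multiplicative"
    root_limit: int = 200
    sub_limit: int = 300
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = AnalysisThresholds(**thr)
        return cfg

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d

    def input_paths(self) -> Dict[str, str]:
        paths = {"mutations": self.mutations, "domains": self.domains,
                 "family_columns": self.family_columns, "gmt": self.gmt,
                 "hierarchy": self.hierarchy}
        for name in ("expression", "couplings", "gene_scores"):
            value = getattr(self, name)
            if value:
                paths[name] = value
        return paths


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute every stage and write all artifacts to ``config.outdir``.

    Any stage failure aborts with the stage name after removing partial
    outputs, so an output directory is either complete or absent.
    """
    outdir = Path(config.outdir)
    created = not outdir.exists()
    stage = "read_inputs"
    try:
        catalog = fio.read_mutation_table(config.mutations, config.dialect,
                                          config.cancer_type_rule)
        domain_map = fio.read_domain_assignments(config.domains)
        family_columns = fio.read_family_columns(config.family_columns)
        forest = fio.read_pathway_hierarchy(config.gmt, config.hierarchy)
        dubious = None
        if config.gene_scores:
            dubious = fio.annotate_dubious_genes(fio.read_gene_scores(config.gene_scores))

        scopes: List[str] = []
        for scope in config.scopes:
            if scope == "per-cancer":
                scopes.extend(catalog.scopes())
            else:
                scopes.append(scope)
        scopes = list(dict.fromkeys(scopes))

        stage = "map"
        hits, unmapped = map_catalog(catalog, domain_map, family_columns)

        stage = "enrich"
        spec = ShuffleSpec(model=config.shuffle_model, n_shuffles=config.n_shuffles,
                           seed=config.seed)
        enriched_frames = []
        for scope in scopes:
            enriched_frames.append(enrich_positions(
                catalog, domain_map, family_columns, scope,
                shuffle_spec=spec, thresholds=config.thresholds, dubious_genes=dubious))
        enriched = pd.concat(enriched_frames, ignore_index=True) if enriched_frames \
            else pd.DataFrame()

        stage = "exclusivity"
        pathways = select_pathways(forest, config.root_limit, config.sub_limit)
        excl_frames = []
        for scope in scopes:
            excl_frames.append(exclusivity_scan(
                catalog, domain_map, family_columns, enriched, pathways, scope,
                thresholds=config.thresholds, shuffle_spec=spec,
                universe_rule=config.universe_rule))
        exclusivity = pd.concat(excl_frames, ignore_index=True) if excl_frames \
            else pd.DataFrame()

        stage = "network"
        graph = build_network(exclusivity, hits)
        edges = network_to_edges(graph)

        stage = "signaling"
        extra_tables: Dict[str, pd.DataFrame] = {}
        if config.expression and config.couplings:
            expression = fio.read_expression(config.expression)
            coupling = fio.read_couplings(config.couplings)
            extra_tables["gprotein_activity"] = activity_matrix(
                expression, coupling, mode=config.eq1_mode)
            extra_tables["group_mutation_summary"] = group_mutation_summary(
                catalog, coupling, hits)

        stage = "write_outputs"
        counters = {
            "records_read": len(catalog),
            "records_skipped": catalog.n_skipped,
            "alleles_nonsynonymous": catalog.n_alleles(),
            "alleles_unmapped": unmapped,
            "positions_candidate": int(enriched["candidate"].sum()) if len(enriched) else 0,
            "positions_significant": int(enriched["significant"].sum()) if len(enriched) else 0,
            "pairs_tested": len(exclusivity),
            "pairs_retained": int(exclusivity["retained"].sum()) if len(exclusivity) else 0,
        }
        return fio.write_outputs(
            outdir, enrichment=enriched, exclusivity=exclusivity, network_edges=edges,
            extra_tables=extra_tables, config=config.to_dict(), seed=config.seed,
            input_paths=config.input_paths(), counters=counters)
    except Exception as exc:
        if created and outdir.exists():
            shutil.rmtree(outdir, ignore_errors=True)
        raise StageError(stage, exc) from exc
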