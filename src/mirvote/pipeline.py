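"""End-to-end analysis: convert -> filter -> call targets -> enrich.

The pipeline stages mirror how the method is used in practice: queried
miRNA IDs are first converted to the current annotation (retired and
unknown entries excluded with a logged report), consensus target genes are
called through the voting filter and O/E ratio, and pathways are scored by
the cumulative hypergeometric test — optionally with empirical P-values
against a prebuilt null baseline and the expression-weighted ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import enrichment as enr
from .enrichment import NullBaseline, PathwayRecord
from .io import RunConfig, read_gmt, read_query, read_synonym_map, write_results
from .predictions import Store, load_predictions
from .registry import Registry, convert_batch, load_registry
from .targets import GeneTargetCall, QuerySet, select_targets

logger = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    conversion: pd.DataFrame
    targets: list[GeneTargetCall]
    enrichment: list[enr.EnrichmentRow]
    weighted: dict[str, float] | None
    paths: dict[str, Path]


TARGET_COLUMNS = [
    "gene_symbol",
    "observed",
    "expected",
    "oe_ratio",
    "supporting_mirnas",
    "hit_counts",
]
ENRICHMENT_COLUMNS = [
    "pathway_id",
    "name",
    "source_db",
    "overlap",
    "pathway_size",
    "n_targets",
    "universe_size",
    "raw_p",
    "neg_log_p",
    "empirical_p",
    "weighted_score",
]


def targets_to_frame(calls: Sequence[GeneTargetCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_symbol": c.gene_symbol,
            "observed": c.observed_prop,
            "expected": c.expected_prop,
            "oe_ratio": c.oe_ratio,
            "supporting_mirnas": ";".join(sorted(c.supporting_mirnas)),
            "hit_counts": ";".join(
                f"{m}:{h}" for m, h in sorted(c.hit_counts.items())
            ),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def enrichment_to_frame(rows: Sequence[enr.EnrichmentRow]) -> pd.DataFrame:
    recs = [
        {
            "pathway_id": r.pathway_id,
            "name": r.name,
            "source_db": r.source_db,
            "overlap": r.overlap,
            "pathway_size": r.pathway_size,
            "n_targets": r.n_targets,
            "universe_size": r.universe_size,
            "raw_p": r.raw_p,
            "neg_log_p": r.neg_log_p,
            "empirical_p": r.empirical_p,
            "weighted_score": r.weighted_score,
        }
        for r in rows
    ]
    return pd.DataFrame(recs, columns=ENRICHMENT_COLUMNS)


def conversion_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": r.query,
                "accession": r.accession or "",
                "latest_name": r.latest_name or "",
                "status": r.status,
                "candidates": ";".join(r.candidates),
            }
            for r in results
        ],
        columns=["query", "accession", "latest_name", "status", "candidates"],
    )


def load_inputs(
    config: RunConfig,
) -> tuple[Registry, Store, list[PathwayRecord]]:
    if config.alias_table is None:
        raise ValueError("config.alias_table is required")
    registry = load_registry(config.alias_table, config.sequences)
    synonyms = None
    syn_path = getattr(config, "synonyms", None)
    if syn_path:
        synonyms = read_synonym_map(syn_path)
    store = load_predictions(
        config.predictions,
        synonym_map=synonyms,
        validated_files=config.validated or None,
        algorithms=config.algorithms or None,
        species=config.species,
    )
    pathways: list[PathwayRecord] = []
    for g in config.gmt:
        pathways.extend(read_gmt(g))
    return registry, store, pathways


def run_pipeline(
    config: RunConfig, query_file: str | Path, out_dir: str | Path
) -> ResultBundle:
    """Run the full analysis and write targets.csv / enrichment.csv / conversion.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry, store, pathways = load_inputs(config)

    ids, expression = read_query(query_file)
    logger.info("stage convert: %d queried IDs", len(ids))
    conv = convert_batch(ids, registry)
    usable = [r for r in conv if r.usable]
    logger.info(
        "stage convert: %d usable, %d excluded",
        len(usable),
        len(conv) - len(usable),
    )
    accessions: list[str] = []
    expr_by_acc: dict[str, float] = {}
    for r in usable:
        if r.accession not in accessions:
            accessions.append(r.accession)
            if expression is not None:
                expr_by_acc[r.accession] = expression[r.query]
    query = QuerySet.from_list(accessions, expr_by_acc if expression else None)

    calls = select_targets(
        query,
        store,
        min_oe=config.min_oe,
        min_hits=config.min_hits,
        include_validated=config.include_validated,
    )
    logger.info("stage targets: %d consensus target genes", len(calls))

    rows: list[enr.EnrichmentRow] = []
    weighted: dict[str, float] | None = None
    if pathways:
        universe = enr.default_universe(store, pathways, config.universe_mode)
        rows = enr.enrich(
            [c.gene_symbol for c in calls], pathways, universe, config.epsilon
        )
        if config.baseline:
            baseline = NullBaseline.load(
                config.baseline, expected_fingerprint=store.fingerprint()
            )
            eff = [m for m in query.mirnas if m in
                   enr.ConsensusIndex.build(store, config.min_hits, config.include_validated).mirna_genes]
            enr.attach_empirical(rows, baseline, len(eff))
        if query.expression:
            weighted = dict(
                enr.weighted_pathway_ranking(
                    query,
                    store,
                    pathways,
                    min_oe=config.min_oe,
                    min_hits=config.min_hits,
                    include_validated=config.include_validated,
                    universe_mode=config.universe_mode,
                )
            )
            for r in rows:
                r.weighted_score = weighted.get(r.pathway_id)
        logger.info("stage enrich: %d pathways scored", len(rows))

    paths = {
        "conversion": write_results(
            conversion_to_frame(conv), out_dir / "conversion.csv", config
        ),
        "targets": write_results(
            targets_to_frame(calls), out_dir / "targets.csv", config
        ),
        "enrichment": write_results(
            enrichment_to_frame(rows), out_dir / "enrichment.csv", config
        ),
    }
    return ResultBundle(
        conversion=conversion_to_frame(conv),
        targets=calls,
        enrichment=rows,
        weighted=weighted,
        paths=paths,
    )
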