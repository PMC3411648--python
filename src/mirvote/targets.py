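"""Consensus target-gene calling via observed/expected targeting ratios.

For a query set of miRNAs, a gene is called a consensus target when the
proportion of queried miRNAs predicted to target it (observed) exceeds the
proportion of *all* database miRNAs predicted to target it (expected) by a
configurable factor — the O/E ratio, default 2.  Both proportions are
computed on pairs that already passed the voting/validated filter, with the
same filter parameters on both sides, so the ratio compares like with like.

Queried miRNAs with no retained prediction at all are dropped from the
denominator (and reported): a miRNA the database knows nothing about
carries no evidence for or against any gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .predictions import PairSummary, Store, filter_pairs, pair_table, summarize_pairs

logger = logging.getLogger(__name__)

DEFAULT_MIN_OE = 2.0


class EmptyEffectiveQueryError(ValueError):
    """No queried miRNA has any retained prediction."""


@dataclass(frozen=True)
class QuerySet:
    """A converted, deduplicated miRNA query with optional expression ratios."""

    mirnas: tuple[str, ...]
    expression: Mapping[str, float] | None = None

    @staticmethod
    def from_list(
        mirnas: Sequence[str], expression: Mapping[str, float] | None = None
    ) -> "QuerySet":
        seen: list[str] = []
        for m in mirnas:
            if m not in seen:
                seen.append(m)
        if expression is not None:
            missing = [m for m in seen if m not in expression]
            if missing:
                raise ValueError(f"expression ratios missing for: {missing}")
        return QuerySet(tuple(seen), expression)


@dataclass(frozen=True)
class GeneTargetCall:
    gene_symbol: str
    observed_prop: float
    expected_prop: float
    oe_ratio: float
    supporting_mirnas: frozenset[str]
    hit_counts: Mapping[str, int] = field(default_factory=dict)


class ConsensusIndex:
    """Retained-pair index for one (store, filter-parameter) combination.

    Precomputes, once, everything the O/E calculation and the enrichment
    resampling loop need: per-miRNA retained gene arrays, per-gene database
    targeting counts, and the effective database miRNA denominator.  This is
    what makes building 1000-replicate null baselines cheap.
    """

    def __init__(self, mirnas: Sequence[str], genes_col: Sequence[str], hits: Sequence[int]):
        genes = sorted(set(genes_col))
        self.genes = genes
        self.gene_index = {g: i for i, g in enumerate(genes)}
        per_mirna: dict[str, list[int]] = {}
        per_mirna_hits: dict[str, dict[int, int]] = {}
        for m, g, h in zip(mirnas, genes_col, hits):
            gi = self.gene_index[g]
            per_mirna.setdefault(m, []).append(gi)
            per_mirna_hits.setdefault(m, {})[gi] = int(h)
        self.mirna_genes = {
            m: np.array(sorted(set(v)), dtype=np.intp) for m, v in per_mirna.items()
        }
        self.mirna_hits = per_mirna_hits
        self.n_db_mirnas = len(self.mirna_genes)
        counts = np.zeros(len(genes), dtype=np.int64)
        for arr in self.mirna_genes.values():
            counts[arr] += 1
        self.db_gene_counts = counts

    @classmethod
    def from_summaries(cls, retained: Sequence[PairSummary]) -> "ConsensusIndex":
        return cls(
            [s.mirna_accession for s in retained],
            [s.gene_symbol for s in retained],
            [s.hit_count for s in retained],
        )

    @classmethod
    def build(
        cls, store: Store, min_hits: int, include_validated: bool
    ) -> "ConsensusIndex":
        key = (min_hits, include_validated)
        cache = getattr(store, "_index_cache", None)
        if cache is None:
            cache = {}
            store._index_cache = cache
        if key not in cache:
            tbl = pair_table(store)
            keep = tbl["hit_count"] >= min_hits
            if include_validated:
                keep |= tbl["validated"]
            kept = tbl[keep]
            cache[key] = cls(
                kept["mirna_accession"].to_numpy(),
                kept["gene_symbol"].to_numpy(),
                kept["hit_count"].to_numpy(),
            )
        return cache[key]

    # -- core counting -----------------------------------------------------

    def effective_query(self, mirnas: Iterable[str]) -> list[str]:
        """Queried miRNAs that have at least one retained pair."""
        kept, dropped = [], []
        for m in mirnas:
            (kept if m in self.mirna_genes else dropped).append(m)
        if dropped:
            logger.warning(
                "queried miRNAs with no retained predictions dropped from the "
                "denominator: %s",
                ", ".join(dropped),
            )
        return kept

    def observed_counts(self, effective: Sequence[str]) -> np.ndarray:
        counts = np.zeros(len(self.genes), dtype=np.int64)
        for m in effective:
            counts[self.mirna_genes[m]] += 1
        return counts

    def expected_prop(self) -> np.ndarray:
        return self.db_gene_counts / self.n_db_mirnas


def observed_proportion(
    gene: str, query: QuerySet, index: ConsensusIndex
) -> float:
    """Fraction of effective queried miRNAs with a retained pair to *gene*."""
    effective = index.effective_query(query.mirnas)
    if not effective:
        raise EmptyEffectiveQueryError(
            "none of the queried miRNAs has retained predictions"
        )
    gi = index.gene_index.get(gene)
    if gi is None:
        return 0.0
    return sum(gi in set(index.mirna_genes[m]) for m in effective) / len(effective)


def expected_proportion(
    gene: str,
    store: Store,
    min_hits: int = 3,
    include_validated: bool = True,
) -> float | None:
    """Fraction of database miRNAs (with >=1 retained pair) targeting *gene*.

    Returns None for a gene absent from every retained pair (the 0/0 case);
    such genes are excluded from calling rather than given an infinite O/E.
    """
    index = ConsensusIndex.build(store, min_hits, include_validated)
    gi = index.gene_index.get(gene)
    if gi is None:
        logger.info("gene %s absent from retained pairs: expected undefined", gene)
        return None
    return index.db_gene_counts[gi] / index.n_db_mirnas


def select_targets(
    query: QuerySet,
    store: Store,
    min_oe: float = DEFAULT_MIN_OE,
    min_hits: int = 3,
    include_validated: bool = True,
    expected_prefilter: bool = False,
) -> list[GeneTargetCall]:
    """Call consensus target genes for a query set.

    Returns genes with oe_ratio >= min_oe and at least one supporting query
    miRNA, sorted by descending oe_ratio then gene symbol.  By default the
    expected proportion uses the same post-filter pairs as the observed
    side; ``expected_prefilter=True`` computes it on all predicted pairs
    instead (threshold 1, validated included).
    """
    index = ConsensusIndex.build(store, min_hits, include_validated)
    exp_index = (
        ConsensusIndex.build(store, 1, True) if expected_prefilter else index
    )
    effective = index.effective_query(query.mirnas)
    if not effective:
        raise EmptyEffectiveQueryError(
            "none of the queried miRNAs has retained predictions"
        )
    obs_counts = index.observed_counts(effective)
    observed = obs_counts / len(effective)
    calls: list[GeneTargetCall] = []
    exp_all = exp_index.expected_prop()
    for gi in np.nonzero(obs_counts)[0]:
        gene = index.genes[gi]
        egi = exp_index.gene_index.get(gene)
        if egi is None or exp_index.db_gene_counts[egi] == 0:
            continue  # 0/0 convention: no expected evidence, gene excluded
        expected = exp_all[egi]
        oe = observed[gi] / expected
        if oe >= min_oe:
            supporting = frozenset(
                m for m in effective if gi in index.mirna_hits.get(m, {})
            )
            calls.append(
                GeneTargetCall(
                    gene_symbol=gene,
                    observed_prop=float(observed[gi]),
                    expected_prop=float(expected),
                    oe_ratio=float(oe),
                    supporting_mirnas=supporting,
                    hit_counts={
                        m: index.mirna_hits[m][gi] for m in sorted(supporting)
                    },
                )
            )
    calls.sort(key=lambda c: (-c.oe_ratio, c.gene_symbol))
    return calls


def regulatory_mirnas(
    genes: Sequence[str],
    store: Store,
    min_hits: int = 3,
    include_validated: bool = True,
) -> dict[str, list[tuple[str, frozenset[str], bool]]]:
    """Inverse query: which retained miRNAs target each given gene.

    Returns gene -> list of (miRNA, supporting algorithm set, validated);
    unknown genes get an empty list with a warning.
    """
    retained = filter_pairs(
        summarize_pairs(store), min_hits=min_hits, include_validated=include_validated
    )
    by_gene: dict[str, list[tuple[str, frozenset[str], bool]]] = {}
    for s in retained:
        by_gene.setdefault(s.gene_symbol, []).append(
            (s.mirna_accession, s.algorithms, s.validated)
        )
    out: dict[str, list[tuple[str, frozenset[str], bool]]] = {}
    for g in genes:
        if g not in by_gene:
            logger.warning("gene %s has no retained regulatory miRNAs", g)
            out[g] = []
        else:
            out[g] = sorted(by_gene[g], key=lambda t: t[0])
    return out
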