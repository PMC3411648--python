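"""Pathway over-representation of consensus target genes.

Three complementary statistics are computed per pathway:

* the raw upper-tail (cumulative) hypergeometric P-value for observing at
  least k pathway genes among the n called targets drawn from a universe of
  N genes containing K pathway members;
* an empirical P-value ranking that raw P against a null baseline built by
  repeatedly re-running the whole pipeline on randomly drawn miRNA sets of
  matching size — this corrects for the strong dependence of raw P-values
  on pathway size;
* an optional expression-weighted ranking score, the sum over queried
  miRNAs of (normalised |expression| weight) x (-log10 P of that miRNA's
  own enrichment), for when expression ratios are available.

Raw P-values come from scipy's hypergeometric survival function, which is
numerically stable for large universes.  -log P uses base 10, the axis
convention of enrichment tools, with raw P floored at a small epsilon
before logging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .predictions import Store
from .targets import ConsensusIndex, QuerySet

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
DEFAULT_REPS = 1000
DEFAULT_NULL_SIZES = range(1, 101)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    name: str
    source_db: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise EnrichmentError(f"pathway {self.pathway_id} has an empty gene set")


@dataclass
class EnrichmentRow:
    pathway_id: str
    name: str
    source_db: str
    overlap: int
    pathway_size: int
    n_targets: int
    universe_size: int
    raw_p: float
    neg_log_p: float
    empirical_p: float | None = None
    weighted_score: float | None = None
    bh_q: float | None = None  # Benjamini-Hochberg extra, not part of the core procedure


def hyper_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def neg_log10(p: float, floor: float = P_FLOOR) -> float:
    return float(-np.log10(max(p, floor)))


def default_universe(
    store: Store, pathways: Sequence[PathwayRecord], mode: str = "pathways_and_store"
) -> frozenset[str]:
    """The gene universe N for the hypergeometric test.

    ``pathways_and_store`` (default): genes annotated in any loaded pathway
    that are also present in the prediction store — genes that could in
    principle have been both called and annotated.  Alternatives:
    ``pathways`` (all annotated genes) and ``store`` (all predicted genes).
    """
    pathway_genes: set[str] = set()
    for p in pathways:
        pathway_genes |= p.genes
    if mode == "pathways":
        return frozenset(pathway_genes)
    store_genes = set(store.gene_universe())
    if mode == "store":
        return frozenset(store_genes)
    if mode == "pathways_and_store":
        return frozenset(pathway_genes & store_genes)
    raise ValueError(f"unknown universe mode {mode!r}")


def enrich(
    targets: Iterable[str],
    pathways: Sequence[PathwayRecord],
    universe: Iterable[str],
    epsilon: float = P_FLOOR,
) -> list[EnrichmentRow]:
    """Score every pathway for over-representation of the target genes.

    Pathway gene sets are intersected with the universe first; target genes
    outside the universe are dropped with a warning.  Rows are sorted by
    descending -log10 P, ties broken by pathway_id; pathways from different
    source databases stay as separate rows even when their gene sets agree.
    """
    universe = frozenset(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    targets = set(targets)
    if not targets:
        raise EnrichmentError("no targets to enrich")
    outside = targets - universe
    if outside:
        logger.warning(
            "%d target genes outside the universe dropped from enrichment",
            len(outside),
        )
    targets &= universe
    if not targets:
        raise EnrichmentError("no targets to enrich (none inside the universe)")
    N = len(universe)
    n = len(targets)
    rows: list[EnrichmentRow] = []
    for p in pathways:
        members = p.genes & universe
        K = len(members)
        k = len(members & targets)
        raw = hyper_pvalue(k, K, n, N) if K else 1.0
        rows.append(
            EnrichmentRow(
                pathway_id=p.pathway_id,
                name=p.name,
                source_db=p.source_db,
                overlap=k,
                pathway_size=K,
                n_targets=n,
                universe_size=N,
                raw_p=raw,
                neg_log_p=neg_log10(raw, epsilon),
            )
        )
    rows.sort(key=lambda r: (-r.neg_log_p, r.pathway_id))
    return rows


def add_bh_column(rows: Sequence[EnrichmentRow]) -> None:
    """Attach Benjamini-Hochberg q-values in place (optional extra)."""
    if not rows:
        return
    q = multipletests([r.raw_p for r in rows], method="fdr_bh")[1]
    for r, qv in zip(rows, q):
        r.bh_q = float(qv)


# -- fast resampling context -------------------------------------------------


class _EnrichmentContext:
    """Precomputed machinery to score one random miRNA draw in microseconds.

    Shares exactly the pipeline semantics of select_targets + enrich (same
    filter, same O/E rule, same universe) but works on integer gene indices
    and a dense pathway-membership matrix.
    """

    def __init__(
        self,
        store: Store,
        pathways: Sequence[PathwayRecord],
        min_oe: float,
        min_hits: int,
        include_validated: bool,
        universe_mode: str = "pathways_and_store",
    ):
        self.pathways = list(pathways)
        self.min_oe = min_oe
        self.index = ConsensusIndex.build(store, min_hits, include_validated)
        self.universe = default_universe(store, pathways, universe_mode)
        self.N = len(self.universe)
        genes = self.index.genes
        self.in_universe = np.array([g in self.universe for g in genes], dtype=bool)
        # int matrix: boolean matmul would OR-reduce instead of counting
        self.membership = np.zeros((len(pathways), len(genes)), dtype=np.int64)
        gidx = self.index.gene_index
        self.K = np.zeros(len(pathways), dtype=np.int64)
        for pi, p in enumerate(pathways):
            members = p.genes & self.universe
            self.K[pi] = len(members)
            for g in members:
                gi = gidx.get(g)
                if gi is not None:
                    self.membership[pi, gi] = 1
        self.db_counts = self.index.db_gene_counts
        self.n_db = self.index.n_db_mirnas

    def raw_pvalues(self, mirnas: Sequence[str]) -> np.ndarray:
        """Per-pathway raw P for one query; all-ones when nothing is called."""
        effective = [m for m in mirnas if m in self.index.mirna_genes]
        if not effective:
            return np.ones(len(self.pathways))
        counts = self.index.observed_counts(effective)
        observed = counts / len(effective)
        expected = self.db_counts / self.n_db  # same expression as the public path
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(self.db_counts > 0, observed / np.where(expected > 0, expected, 1.0), 0.0)
        mask = (counts > 0) & (self.db_counts > 0) & (oe >= self.min_oe) & self.in_universe
        n = int(mask.sum())
        if n == 0:
            return np.ones(len(self.pathways))
        k = self.membership @ mask
        return hypergeom.sf(k - 1, self.N, self.K, n)


# -- null baseline -----------------------------------------------------------


@dataclass
class NullBaseline:
    """Per-(query size, pathway) resampled raw P-value distributions.

    ``values[s]`` is a (n_pathways, B) array, sorted ascending along the
    replicate axis.  Metadata pins the seed, replicate count, filter
    parameters and a store fingerprint so a baseline cannot silently be
    reused against different data.
    """

    sizes: list[int]
    reps: int
    pathway_ids: list[str]
    values: dict[int, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "sizes": self.sizes,
            "reps": self.reps,
            "pathway_ids": self.pathway_ids,
            "metadata": self.metadata,
            "values": {str(s): v.tolist() for s, v in self.values.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path, expected_fingerprint: str | None = None) -> "NullBaseline":
        payload = json.loads(Path(path).read_text())
        bl = NullBaseline(
            sizes=list(payload["sizes"]),
            reps=int(payload["reps"]),
            pathway_ids=list(payload["pathway_ids"]),
            values={int(s): np.asarray(v, dtype=float) for s, v in payload["values"].items()},
            metadata=payload.get("metadata", {}),
        )
        if (
            expected_fingerprint is not None
            and bl.metadata.get("store_fingerprint") != expected_fingerprint
        ):
            raise EnrichmentError(
                "null baseline was built against a different prediction store "
                f"(fingerprint {bl.metadata.get('store_fingerprint')!r} != "
                f"{expected_fingerprint!r})"
            )
        return bl

    def nearest_size(self, s: int) -> int:
        if s in self.values:
            return s
        avail = sorted(self.values)
        nearest = min(avail, key=lambda a: (abs(a - s), a))
        logger.warning(
            "query size %d not in baseline; using nearest available size %d",
            s,
            nearest,
        )
        return nearest


def build_null_baseline(
    store: Store,
    pathways: Sequence[PathwayRecord],
    sizes: Iterable[int] = DEFAULT_NULL_SIZES,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    min_oe: float = 2.0,
    min_hits: int = 3,
    include_validated: bool = True,
    universe_mode: str = "pathways_and_store",
) -> NullBaseline:
    """Resample the whole pipeline on random miRNA draws of each size.

    For each size s, ``reps`` times: draw s miRNAs uniformly without
    replacement from the store's miRNA universe, call consensus targets and
    score every pathway, recording the raw P-values.  Draws are reproducible
    from the seed.  A draw that calls no target gene contributes raw P = 1
    for every pathway (no enrichment evidence).
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    mirnas = np.array(store.mirna_universe())
    too_big = [s for s in sizes if s > len(mirnas)]
    if too_big:
        raise ValueError(
            f"sizes {too_big} exceed the {len(mirnas)} miRNAs in the store"
        )
    ctx = _EnrichmentContext(
        store, pathways, min_oe, min_hits, include_validated, universe_mode
    )
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    for s in sizes:
        mat = np.empty((len(pathways), reps))
        for b in range(reps):
            draw = rng.choice(mirnas, size=s, replace=False)
            mat[:, b] = ctx.raw_pvalues(list(draw))
        mat.sort(axis=1)
        values[s] = mat
    return NullBaseline(
        sizes=sizes,
        reps=reps,
        pathway_ids=[p.pathway_id for p in pathways],
        values=values,
        metadata={
            "seed": int(seed),
            "reps": int(reps),
            "min_oe": min_oe,
            "min_hits": min_hits,
            "include_validated": include_validated,
            "universe_mode": universe_mode,
            "store_fingerprint": store.fingerprint(),
        },
    )


def empirical_pvalue(
    observed_raw_p: float, baseline: NullBaseline, size: int, pathway_id: str
) -> float:
    """Rank the observed raw P within the matching null distribution.

    Returns (r + 1) / (B + 1) where r counts null raw P-values <= observed —
    the add-one convention that keeps empirical P strictly positive.  A query
    size missing from the baseline falls back to the nearest available size
    with a logged flag.
    """
    try:
        pi = baseline.pathway_ids.index(pathway_id)
    except ValueError:
        raise EnrichmentError(f"pathway {pathway_id!r} absent from baseline") from None
    s = baseline.nearest_size(size)
    nulls = baseline.values[s][pi]
    r = int(np.searchsorted(nulls, observed_raw_p, side="right"))
    return (r + 1) / (baseline.reps + 1)


def attach_empirical(
    rows: Sequence[EnrichmentRow], baseline: NullBaseline, query_size: int
) -> None:
    """Fill the empirical_p field of each row in place."""
    for r in rows:
        r.empirical_p = empirical_pvalue(r.raw_p, baseline, query_size, r.pathway_id)


# -- expression-weighted ranking ---------------------------------------------


def expression_weights(expression: Mapping[str, float]) -> dict[str, float]:
    """w_i = |e_i| / sum_j |e_j| over the input miRNAs."""
    total = sum(abs(v) for v in expression.values())
    if total == 0:
        raise EnrichmentError("degenerate weights: all expression values are zero")
    return {m: abs(v) / total for m, v in expression.items()}


def weighted_scores(
    per_mirna_enrichment: Mapping[str, Mapping[str, float]],
    expression: Mapping[str, float],
    epsilon: float = P_FLOOR,
) -> dict[str, float]:
    """Score each pathway as sum_i w_i * (-log10 P_{i, pathway}).

    ``per_mirna_enrichment`` maps miRNA -> pathway -> raw P from that
    miRNA's own target-set enrichment.  Every miRNA present must carry an
    expression value.  With a single miRNA the weight is 1 and the ranking
    reduces exactly to that miRNA's -log P ranking.
    """
    missing = [m for m in per_mirna_enrichment if m not in expression]
    if missing:
        raise EnrichmentError(f"expression values missing for: {missing}")
    weights = expression_weights({m: expression[m] for m in per_mirna_enrichment})
    scores: dict[str, float] = {}
    for m, pmap in per_mirna_enrichment.items():
        w = weights[m]
        for pathway, raw in pmap.items():
            scores[pathway] = scores.get(pathway, 0.0) + w * neg_log10(raw, epsilon)
    return scores


def per_mirna_raw_pvalues(
    query: QuerySet,
    store: Store,
    pathways: Sequence[PathwayRecord],
    min_oe: float = 2.0,
    min_hits: int = 3,
    include_validated: bool = True,
    universe_mode: str = "pathways_and_store",
) -> dict[str, dict[str, float]]:
    """Per-miRNA pathway enrichment through the same consensus-calling path.

    Each miRNA's own filtered target set is selected and enriched exactly as
    a pooled query would be, so the weighted ranking shares provenance with
    the pooled analysis.  A miRNA with no retained predictions is dropped
    with a warning; one whose targets miss every pathway scores raw P = 1
    everywhere.
    """
    ctx = _EnrichmentContext(
        store, pathways, min_oe, min_hits, include_validated, universe_mode
    )
    out: dict[str, dict[str, float]] = {}
    for m in query.mirnas:
        if m not in ctx.index.mirna_genes:
            logger.warning("miRNA %s has no retained predictions; excluded from weighting", m)
            continue
        praw = ctx.raw_pvalues([m])
        out[m] = {p.pathway_id: float(v) for p, v in zip(pathways, praw)}
    return out


def weighted_pathway_ranking(
    query: QuerySet,
    store: Store,
    pathways: Sequence[PathwayRecord],
    min_oe: float = 2.0,
    min_hits: int = 3,
    include_validated: bool = True,
    universe_mode: str = "pathways_and_store",
) -> list[tuple[str, float]]:
    """Convenience: per-miRNA enrichment + weighting, ranked descending."""
    if query.expression is None:
        raise EnrichmentError("weighted ranking requires expression ratios")
    per = per_mirna_raw_pvalues(
        query, store, pathways, min_oe, min_hits, include_validated, universe_mode
    )
    if not per:
        raise EnrichmentError("no queried miRNA has retained predictions")
    scores = weighted_scores(per, dict(query.expression))
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
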