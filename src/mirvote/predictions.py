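"""Per-algorithm miRNA-gene predictions and the voting-threshold filter.

Target-prediction algorithms disagree widely: in large compendia roughly
three quarters of all miRNA-gene pairs are predicted by a single algorithm
only.  The consensus strategy implemented here counts, for every distinct
(miRNA, gene) pair, the number of distinct algorithms predicting it (the
"hit" count) and retains pairs reaching a configurable threshold (default
3), plus experimentally validated pairs regardless of hit count when
``include_validated`` is on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_HITS = 3


class StoreError(ValueError):
    pass


@dataclass(frozen=True)
class PairSummary:
    """One distinct (miRNA, gene) pair with its supporting evidence."""

    mirna_accession: str
    gene_symbol: str
    hit_count: int
    algorithms: frozenset[str]
    validated: bool

    def __post_init__(self):
        if self.hit_count != len(self.algorithms):
            raise StoreError("hit_count must equal the number of supporting algorithms")


class Store:
    """Predicted and validated miRNA-gene pairs for one species."""

    def __init__(
        self,
        predictions: pd.DataFrame,
        validated: pd.DataFrame | None = None,
        algorithms: Iterable[str] = (),
        species: str = "hsa",
    ):
        self.species = species
        self.algorithms = list(algorithms)
        cols = ["mirna_accession", "gene_symbol", "algorithm_id", "score"]
        self.predictions = predictions.reindex(columns=cols)
        if validated is None:
            validated = pd.DataFrame(columns=["mirna_accession", "gene_symbol", "source"])
        self.validated = validated
        self._summaries: list[PairSummary] | None = None

    @property
    def n_prediction_rows(self) -> int:
        return len(self.predictions)

    def mirna_universe(self) -> list[str]:
        """All miRNAs present in the store (predicted or validated)."""
        mirnas = set(self.predictions["mirna_accession"])
        mirnas.update(self.validated["mirna_accession"])
        return sorted(mirnas)

    def gene_universe(self) -> list[str]:
        genes = set(self.predictions["gene_symbol"])
        genes.update(self.validated["gene_symbol"])
        return sorted(genes)

    def fingerprint(self) -> str:
        """Order-independent content hash, used to pin null baselines."""
        import hashlib

        h = hashlib.sha256()
        pred = self.predictions[["mirna_accession", "gene_symbol", "algorithm_id"]]
        for row in sorted(map(tuple, pred.itertuples(index=False))):
            h.update("\t".join(row).encode())
            h.update(b"\n")
        val = self.validated[["mirna_accession", "gene_symbol"]]
        for row in sorted(map(tuple, val.itertuples(index=False))):
            h.update(("V\t" + "\t".join(row)).encode())
            h.update(b"\n")
        return h.hexdigest()[:16]


def _read_pair_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StoreError(f"{path}: missing columns {missing}")
    return df


def _apply_synonyms(genes: pd.Series, synonym_map: Mapping[str, str] | None) -> pd.Series:
    if not synonym_map:
        return genes
    return genes.map(lambda g: synonym_map.get(g, g))


def load_predictions(
    files: Mapping[str, str | Path],
    synonym_map: Mapping[str, str] | None = None,
    validated_files: Mapping[str, str | Path] | None = None,
    algorithms: Iterable[str] | None = None,
    species: str = "hsa",
) -> Store:
    """Load one TSV per algorithm (and optional validated tables) into a Store.

    Gene symbols are rewritten through ``synonym_map`` (old -> unified symbol)
    before storage so that every downstream computation operates in one
    namespace.  Exact duplicate rows are collapsed with a logged count; rows
    with an empty gene symbol are skipped with a warning.
    """
    declared = list(algorithms) if algorithms is not None else sorted(files)
    unknown = sorted(set(files) - set(declared))
    if unknown:
        raise StoreError(f"algorithm tags not declared in config: {unknown}")
    frames = []
    for tag in sorted(files):
        df = _read_pair_table(files[tag], ["mirna_accession", "gene_symbol"])
        if "score" not in df.columns:
            df["score"] = pd.NA
        empty = df["gene_symbol"].isna() | (df["gene_symbol"].str.strip() == "")
        if empty.any():
            logger.warning("%s: skipped %d rows with empty gene symbol", tag, int(empty.sum()))
            df = df[~empty]
        df = df.assign(
            algorithm_id=tag,
            gene_symbol=_apply_synonyms(df["gene_symbol"].str.strip(), synonym_map),
            mirna_accession=df["mirna_accession"].str.strip(),
        )
        frames.append(df[["mirna_accession", "gene_symbol", "algorithm_id", "score"]])
    pred = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["mirna_accession", "gene_symbol", "algorithm_id", "score"])
    )
    before = len(pred)
    pred = pred.drop_duplicates(subset=["mirna_accession", "gene_symbol", "algorithm_id"])
    dropped = before - len(pred)
    if dropped:
        logger.info("collapsed %d duplicate prediction rows", dropped)

    val_frames = []
    for source, path in sorted((validated_files or {}).items()):
        df = _read_pair_table(path, ["mirna_accession", "gene_symbol"])
        df = df.assign(
            source=source,
            gene_symbol=_apply_synonyms(df["gene_symbol"].str.strip(), synonym_map),
            mirna_accession=df["mirna_accession"].str.strip(),
        )
        val_frames.append(df[["mirna_accession", "gene_symbol", "source"]])
    val = (
        pd.concat(val_frames, ignore_index=True).drop_duplicates()
        if val_frames
        else None
    )
    return Store(pred.reset_index(drop=True), val, algorithms=declared, species=species)


def pair_table(store: Store) -> pd.DataFrame:
    """Vectorised per-pair hit counts: columns mirna_accession, gene_symbol,
    hit_count, validated — one row per distinct pair, sorted by (miRNA, gene).

    Same content as summarize_pairs minus the per-pair algorithm sets; used
    by the index/resampling machinery where building 10^5 dataclass
    instances per replicate would dominate the runtime.
    """
    cached = getattr(store, "_pair_table", None)
    if cached is not None:
        return cached
    tbl = (
        store.predictions.groupby(["mirna_accession", "gene_symbol"], sort=True)
        .size()
        .rename("hit_count")
        .reset_index()
    )
    vkeys = store.validated[["mirna_accession", "gene_symbol"]].drop_duplicates()
    vkeys = vkeys.assign(validated=True)
    tbl = tbl.merge(vkeys, on=["mirna_accession", "gene_symbol"], how="outer")
    tbl["hit_count"] = tbl["hit_count"].fillna(0).astype(int)
    tbl["validated"] = tbl["validated"].notna()  # merge marker column holds only True
    tbl = tbl.sort_values(["mirna_accession", "gene_symbol"], ignore_index=True)
    store._pair_table = tbl
    return tbl


def summarize_pairs(store: Store) -> list[PairSummary]:
    """One PairSummary per distinct (miRNA, gene) pair.

    Pairs appearing only in a validated table get hit_count 0 and
    validated=True.  Results are cached on the store.
    """
    if store._summaries is not None:
        return store._summaries
    validated_keys = set(
        map(tuple, store.validated[["mirna_accession", "gene_symbol"]].itertuples(index=False))
    )
    grouped: dict[tuple[str, str], set[str]] = {}
    for m, g, a in store.predictions[
        ["mirna_accession", "gene_symbol", "algorithm_id"]
    ].itertuples(index=False):
        grouped.setdefault((m, g), set()).add(a)
    for key in validated_keys:
        grouped.setdefault(key, set())
    summaries = [
        PairSummary(
            mirna_accession=m,
            gene_symbol=g,
            hit_count=len(algs),
            algorithms=frozenset(algs),
            validated=(m, g) in validated_keys,
        )
        for (m, g), algs in sorted(grouped.items())
    ]
    store._summaries = summaries
    return summaries


def filter_pairs(
    summaries: Iterable[PairSummary],
    min_hits: int = DEFAULT_MIN_HITS,
    include_validated: bool = True,
) -> list[PairSummary]:
    """Apply the voting threshold: keep pairs with hit_count >= min_hits.

    Validated pairs bypass the threshold when include_validated is on —
    experimental support substitutes for algorithmic consensus.  Output is
    in stable (miRNA, gene) order.
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    kept = [
        s
        for s in summaries
        if s.hit_count >= min_hits or (include_validated and s.validated)
    ]
    kept.sort(key=lambda s: (s.mirna_accession, s.gene_symbol))
    if not kept:
        logger.warning("voting filter retained no pairs (min_hits=%d)", min_hits)
    return kept


def hit_distribution(
    summaries: Iterable[PairSummary], include_validated_only: bool = True
) -> dict[int, tuple[int, float]]:
    """Map hit_count -> (number of pairs, fraction of pairs).

    ``include_validated_only=False`` drops pairs present only in the
    validated tables (hit 0) from the denominator; both conventions are
    defensible, so the choice is explicit.
    """
    counts: dict[int, int] = {}
    for s in summaries:
        if s.hit_count == 0 and not include_validated_only:
            continue
        counts[s.hit_count] = counts.get(s.hit_count, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {h: (c, c / total) for h, c in sorted(counts.items())}
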