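"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes — a versioned alias registry with mature
sequences, per-algorithm prediction tables, validated-pair tables and GMT
pathway files — can be generated here, self-contained and seeded, so that
every analysis module is testable without any external database download.

The generator emulates the statistical *shape* of real prediction
compendia, not their biophysics: the hit-count distribution is heavily
skewed toward single-algorithm pairs (three quarters of pairs by default,
with under a tenth reaching three or more algorithms), pathway gene sets
are random draws of realistic size, and an optional planted signal makes
one pathway genuinely enriched for the consensus targets of a designated
query miRNA set.  Hit counts are assigned per pair and algorithms then
sampled uniformly — correlations between specific predictors are not
simulated because only the hit distribution matters to the voting filter.

Ground truth (exact per-pair hit counts, the planted pathway and gene pool)
is written to ``*.truth.json`` sidecars read only by tests, never by the
analysis path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import PathwayRecord
from .predictions import Store
from .registry import Registry, load_registry

RNA = np.array(list("ACGU"))

#: hard-coded regression alias: hsa-miR-189 was renamed hsa-miR-24-1*
REGRESSION_OLD_NAME = "hsa-miR-189"
REGRESSION_NEW_NAME = "hsa-miR-24-1*"
REGRESSION_ACCESSION = "MIMATSYN00189"  # synthetic accession for the regression pair


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSignal:
    """One pathway made genuinely enriched for a designated query's targets."""

    n_query_mirnas: int = 5
    strength: float = 0.8  # fraction of the pathway drawn from planted target genes
    pathway_size: int = 30
    min_planted_hits: int = 4  # planted pairs always clear the default voting filter


@dataclass(frozen=True)
class FixtureSpec:
    n_mirnas: int = 200
    n_genes: int = 2000
    n_algorithms: int = 7
    # ~525 predicted genes per miRNA (about a quarter of the gene universe),
    # the per-miRNA density real multi-algorithm unions exhibit
    n_pairs: int = 100_000
    # ~75% of pairs predicted by one algorithm only; <10% reach 3+ hits,
    # mirroring the skew of real multi-algorithm compendia
    hit_profile: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.75, 2: 0.16, 3: 0.05, 4: 0.03, 5: 0.01}
    )
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (10, 60)
    historical_fraction: float = 0.3
    retired_fraction: float = 0.05
    n_validated: int = 60
    planted: PlantedSignal | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.hit_profile.values()) - 1.0) > 1e-9:
            raise FixtureSpecError("hit_profile fractions must sum to 1")
        if max(self.hit_profile) > self.n_algorithms:
            raise FixtureSpecError("hit counts exceed the number of algorithms")
        if min(self.hit_profile) < 1:
            raise FixtureSpecError("hit_profile keys must be >= 1")
        if self.planted is not None:
            lo, hi = self.pathway_size_range
            if not lo <= self.planted.pathway_size <= hi:
                raise FixtureSpecError("planted pathway size outside pathway_size_range")
            if self.planted.n_query_mirnas > self.n_mirnas:
                raise FixtureSpecError("planted query larger than the miRNA universe")
            if not 0 < self.planted.strength <= 1:
                raise FixtureSpecError("planted strength must be in (0, 1]")
            if self.planted.min_planted_hits > self.n_algorithms:
                raise FixtureSpecError("min_planted_hits exceeds the number of algorithms")


def planted_spec(seed: int = 0, strength: float = 0.8, **kwargs) -> FixtureSpec:
    """Default fixture with a planted enriched pathway."""
    return FixtureSpec(planted=PlantedSignal(strength=strength), seed=seed, **kwargs)


def _largest_remainder_counts(fractions: Mapping[int, float], total: int) -> dict[int, int]:
    """Allocate `total` items to levels matching the fractions exactly.

    Deterministic: floors plus largest fractional remainders (ties broken by
    level).  Guarantees the realised distribution is within one item of the
    target at every level.
    """
    levels = sorted(fractions)
    raw = {h: fractions[h] * total for h in levels}
    counts = {h: int(np.floor(raw[h])) for h in levels}
    short = total - sum(counts.values())
    by_remainder = sorted(levels, key=lambda h: (-(raw[h] - counts[h]), h))
    for h in by_remainder[:short]:
        counts[h] += 1
    return counts


# -- naming -------------------------------------------------------------------


def _mirna_accession(i: int) -> str:
    return f"MIMATSYN{i:07d}"


def _mirna_name(i: int) -> str:
    return f"hsa-miR-syn{i + 1}"


def _gene_symbol(i: int) -> str:
    return f"GENE{i + 1:05d}"


def _pathway_id(i: int) -> str:
    return f"PW{i + 1:04d}"


# -- fixture container --------------------------------------------------------


@dataclass
class Fixture:
    """In-memory synthetic fixture plus its ground-truth sidecar data."""

    spec: FixtureSpec
    alias_table_text: str
    sequences_fasta_text: str
    prediction_tables: dict[str, pd.DataFrame]
    validated_table: pd.DataFrame
    pathways: list[PathwayRecord]
    truth: dict

    @property
    def algorithms(self) -> list[str]:
        return sorted(self.prediction_tables)

    def registry(self) -> Registry:
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            alias = Path(d) / "alias.tsv"
            seqs = Path(d) / "mature.fa"
            alias.write_text(self.alias_table_text)
            seqs.write_text(self.sequences_fasta_text)
            return load_registry(alias, seqs)

    def store(self) -> Store:
        pred = pd.concat(
            [
                df.assign(algorithm_id=tag)
                for tag, df in sorted(self.prediction_tables.items())
            ],
            ignore_index=True,
        )
        pred["score"] = pd.NA
        return Store(
            pred[["mirna_accession", "gene_symbol", "algorithm_id", "score"]],
            self.validated_table,
            algorithms=self.algorithms,
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all fixture files (plus truth sidecars) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["alias"] = outdir / "alias.tsv"
        paths["alias"].write_text(self.alias_table_text)
        paths["sequences"] = outdir / "mature.fa"
        paths["sequences"].write_text(self.sequences_fasta_text)
        for tag, df in sorted(self.prediction_tables.items()):
            p = outdir / f"predictions_{tag}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[f"predictions:{tag}"] = p
        paths["validated"] = outdir / "validated.tsv"
        self.validated_table.to_csv(paths["validated"], sep="\t", index=False)
        paths["gmt"] = outdir / "pathways.gmt"
        with paths["gmt"].open("w") as fh:
            for p in self.pathways:
                fh.write(
                    "\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n"
                )
        paths["truth"] = outdir / "fixture.truth.json"
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


# -- generators ---------------------------------------------------------------


def gen_registry(spec: FixtureSpec) -> tuple[str, str, dict]:
    """Alias table text, mature-sequence FASTA text, and registry truth.

    Every miRNA gets a current name; ``historical_fraction`` also get one
    earlier alias, and ``retired_fraction`` (rounded) are retired.  The
    hsa-miR-189 -> hsa-miR-24-1* renaming is always included for regression
    coverage.
    """
    rng = np.random.default_rng([spec.seed, 1])
    versions = [f"v{i}" for i in range(6, 18)]  # v6 .. v17
    n = spec.n_mirnas
    n_retired = int(round(spec.retired_fraction * n))
    n_historical = int(round(spec.historical_fraction * n))
    retired = set(range(n - n_retired, n))  # last block retired, deterministic
    historical = set(range(n_historical))  # first block carries an old alias
    lines = [f"#versions: {' '.join(versions)}"]
    lines.append("accession\tname\tversion_from\tversion_to\tstatus")
    fasta: list[str] = []
    active_accessions: list[str] = []
    for i in range(n):
        acc, name = _mirna_accession(i), _mirna_name(i)
        if i in retired:
            lines.append(f"{acc}\t{name}\tv6\tv16\tretired")
        else:
            active_accessions.append(acc)
            if i in historical:
                lines.append(f"{acc}\t{name}-old\tv6\tv16\tactive")
                lines.append(f"{acc}\t{name}\tv17\t-\tactive")
            else:
                lines.append(f"{acc}\t{name}\tv6\t-\tactive")
        seq = "".join(rng.choice(RNA, size=22))
        fasta.append(f">{acc}\n{seq}")
    # regression alias pair (not part of the prediction universe)
    lines.append(f"{REGRESSION_ACCESSION}\t{REGRESSION_OLD_NAME}\tv6\tv9\tactive")
    lines.append(f"{REGRESSION_ACCESSION}\t{REGRESSION_NEW_NAME}\tv10\t-\tactive")
    fasta.append(f">{REGRESSION_ACCESSION}\n" + "".join(rng.choice(RNA, size=22)))
    truth = {
        "n_retired": n_retired,
        "n_historical": n_historical,
        "retired_accessions": sorted(_mirna_accession(i) for i in retired),
        "active_accessions": active_accessions + [REGRESSION_ACCESSION],
    }
    return "\n".join(lines) + "\n", "\n".join(fasta) + "\n", truth


def gen_prediction_db(
    spec: FixtureSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Per-algorithm prediction tables, validated table, and pair truth.

    Distinct (miRNA, gene) pairs are sampled uniformly; each is assigned a
    hit count by exact largest-remainder allocation against the hit profile
    and that many distinct algorithms chosen uniformly.  If a signal is
    planted, the designated query miRNAs additionally target a reserved gene
    pool at hit counts clearing the default voting threshold.
    """
    rng = np.random.default_rng([spec.seed, 2])
    n_active = spec.n_mirnas - int(round(spec.retired_fraction * spec.n_mirnas))
    mirnas = [_mirna_accession(i) for i in range(n_active)]
    genes = [_gene_symbol(i) for i in range(spec.n_genes)]
    algorithms = [f"alg{i + 1}" for i in range(spec.n_algorithms)]

    planted_rows: list[tuple[str, str, int]] = []
    planted_genes: list[str] = []
    planted_query: list[str] = []
    reserved_gene_idx: set[int] = set()
    if spec.planted is not None:
        pl = spec.planted
        planted_query = mirnas[: pl.n_query_mirnas]
        n_planted_genes = int(round(pl.strength * pl.pathway_size))
        # reserve the last genes for the plant so background stays uniform
        gidx = list(range(spec.n_genes - n_planted_genes, spec.n_genes))
        reserved_gene_idx = set(gidx)
        planted_genes = [genes[i] for i in gidx]
        for g in planted_genes:
            for m in planted_query:
                hits = int(rng.integers(pl.min_planted_hits, spec.n_algorithms + 1))
                planted_rows.append((m, g, hits))

    n_bg_genes = spec.n_genes - len(reserved_gene_idx)
    n_cells = n_active * n_bg_genes
    if spec.n_pairs > n_cells:
        raise FixtureSpecError("n_pairs exceeds the number of available (miRNA, gene) cells")
    flat = rng.choice(n_cells, size=spec.n_pairs, replace=False)
    hit_alloc = _largest_remainder_counts(spec.hit_profile, spec.n_pairs)
    hits_arr = np.concatenate(
        [np.full(c, h, dtype=int) for h, c in sorted(hit_alloc.items())]
    )
    hits_arr = rng.permutation(hits_arr)

    mirna_arr = np.array(mirnas)
    gene_arr = np.array(genes)
    mi_all, gi_all = np.divmod(flat.astype(np.int64), n_bg_genes)
    h_all = hits_arr.astype(np.int64)
    if planted_rows:
        p_mi = np.array([mirnas.index(m) for m, _, _ in planted_rows], dtype=np.int64)
        p_gi = np.array([genes.index(g) for _, g, _ in planted_rows], dtype=np.int64)
        p_h = np.array([h for _, _, h in planted_rows], dtype=np.int64)
        mi_all = np.concatenate([mi_all, p_mi])
        gi_all = np.concatenate([gi_all, p_gi])
        h_all = np.concatenate([h_all, p_h])

    # vectorised per-pair algorithm assignment: a random permutation of the
    # algorithm indices per pair, of which the first h are used
    order = np.argsort(rng.random((len(h_all), spec.n_algorithms)), axis=1)
    used = np.arange(spec.n_algorithms)[None, :] < h_all[:, None]
    pair_idx_flat = np.nonzero(used)[0]
    alg_flat = order[used]

    truth_hits: dict[str, int] = {
        f"{mirna_arr[mi]}\t{gene_arr[gi]}": int(h)
        for mi, gi, h in zip(mi_all, gi_all, h_all)
    }
    tables: dict[str, pd.DataFrame] = {}
    for ai, tag in enumerate(algorithms):
        sel = pair_idx_flat[alg_flat == ai]
        tables[tag] = pd.DataFrame(
            {
                "mirna_accession": mirna_arr[mi_all[sel]],
                "gene_symbol": gene_arr[gi_all[sel]],
            }
        ).sort_values(["mirna_accession", "gene_symbol"], ignore_index=True)
    pair_rows = list(zip(mirna_arr[mi_all], gene_arr[gi_all], h_all))

    # validated set straddling high- and zero-hit pairs
    n_val = min(spec.n_validated, len(pair_rows))
    half = n_val // 2
    existing_idx = rng.choice(len(pair_rows), size=half, replace=False)
    val_rows = [(pair_rows[i][0], pair_rows[i][1], "VDB1") for i in existing_idx]
    fresh = 0
    while fresh < n_val - half:
        mi = int(rng.integers(n_active))
        gi = int(rng.integers(spec.n_genes))
        key = f"{mirnas[mi]}\t{genes[gi]}"
        if key not in truth_hits:
            val_rows.append((mirnas[mi], genes[gi], "VDB2"))
            truth_hits.setdefault(key, 0)
            fresh += 1
    validated = pd.DataFrame(
        val_rows, columns=["mirna_accession", "gene_symbol", "source"]
    ).drop_duplicates(ignore_index=True)

    truth = {
        "hit_counts": truth_hits,
        "hit_allocation": {str(h): c for h, c in sorted(hit_alloc.items())},
        "planted_query": planted_query,
        "planted_genes": planted_genes,
    }
    return tables, validated, truth


def gen_pathways(
    spec: FixtureSpec, planted_genes: Sequence[str] = ()
) -> tuple[list[PathwayRecord], dict]:
    """Random pathway gene sets, with the planted pathway (if any) first.

    The planted pathway draws ``strength`` of its genes from the planted
    target pool and the remainder at random, so at strength 1.0 it is a
    subset of the planted query's consensus targets.
    """
    rng = np.random.default_rng([spec.seed, 3])
    genes = [_gene_symbol(i) for i in range(spec.n_genes)]
    lo, hi = spec.pathway_size_range
    records: list[PathwayRecord] = []
    truth: dict = {"planted_pathway_id": None, "expected_overlap": 0}
    start = 0
    if spec.planted is not None:
        if not planted_genes:
            raise FixtureSpecError("planted spec requires the planted gene pool")
        pl = spec.planted
        n_plant = int(round(pl.strength * pl.pathway_size))
        pool = list(planted_genes)[:n_plant]
        others = [g for g in genes if g not in set(pool)]
        filler_idx = rng.choice(len(others), size=pl.pathway_size - len(pool), replace=False)
        members = frozenset(pool) | frozenset(others[i] for i in filler_idx)
        pid = _pathway_id(0)
        records.append(
            PathwayRecord(pid, "planted pathway", "SIMDB", frozenset(members))
        )
        truth["planted_pathway_id"] = pid
        truth["expected_overlap"] = len(pool)
        start = 1
    for i in range(start, spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(spec.n_genes, size=size, replace=False)
        records.append(
            PathwayRecord(
                _pathway_id(i),
                f"simulated pathway {i + 1}",
                "SIMDB",
                frozenset(genes[j] for j in idx),
            )
        )
    return records, truth


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete, internally consistent fixture from one seed."""
    alias_text, fasta_text, reg_truth = gen_registry(spec)
    tables, validated, pair_truth = gen_prediction_db(spec)
    pathways, pw_truth = gen_pathways(spec, pair_truth["planted_genes"])
    truth = {
        "spec": {
            **{
                k: v
                for k, v in asdict(spec).items()
                if k not in ("hit_profile", "planted")
            },
            "hit_profile": {str(k): v for k, v in spec.hit_profile.items()},
            "planted": asdict(spec.planted) if spec.planted else None,
        },
        "registry": reg_truth,
        "pairs": pair_truth,
        "pathways": pw_truth,
    }
    return Fixture(
        spec=spec,
        alias_table_text=alias_text,
        sequences_fasta_text=fasta_text,
        prediction_tables=tables,
        validated_table=validated,
        pathways=pathways,
        truth=truth,
    )
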