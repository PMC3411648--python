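"""Versioned miRNA annotation registry.

Mature-miRNA names change between annotation releases while the underlying
accession (MIMAT-style) is stable, and entries whose original report could
not be reproduced are retired outright.  Analysing a query list written
against an old release therefore requires (a) resolving any historical name
or accession to the current name, (b) flagging retired entries so they can
be excluded downstream, and (c) optionally recovering an identity from the
mature sequence itself.

The registry is loaded from a plain TSV alias table whose header declares
the total order of version labels, plus a FASTA or TSV file of mature
sequences keyed by accession.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

OPEN_VERSION_TOKENS = {"", "-", "open", "current", "na"}
RNA_ALPHABET = frozenset("ACGU")

#: statuses a conversion can end in
CONVERTED = "converted"
ALREADY_CURRENT = "already_current"
RETIRED = "retired"
UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"


class RegistryError(ValueError):
    """Malformed alias table or invariant violation at load time."""


@dataclass(frozen=True)
class AliasRecord:
    """One (accession, name) binding valid over a half-open version range."""

    accession: str
    name: str
    version_from: str
    version_to: str | None  # None = still current
    status: str  # "active" | "retired"


@dataclass(frozen=True)
class MatureEntry:
    """A mature miRNA sequence bound to its accession and current name."""

    accession: str
    latest_name: str
    sequence: str
    species: str = ""


@dataclass
class ConversionResult:
    query: str
    accession: str | None
    latest_name: str | None
    status: str
    history: list[tuple[str, str, str | None]] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        """Whether the entry may enter downstream target analysis."""
        return self.status in (CONVERTED, ALREADY_CURRENT)


def _normalize_query(q: str) -> str:
    """Case-fold the species prefix ('HSA-MIR-189' -> 'hsa-miR-189' style).

    Matching is done fully case-insensitively; this helper just produces the
    canonical lookup key (lowercase) used by the indexes.
    """
    return q.strip().lower()


class Registry:
    """Indexes alias records by name, accession and mature sequence."""

    def __init__(
        self,
        records: Iterable[AliasRecord],
        version_order: list[str],
        entries: Iterable[MatureEntry] = (),
    ):
        self.version_order = list(version_order)
        self._vrank = {v: i for i, v in enumerate(self.version_order)}
        self.records: list[AliasRecord] = list(records)
        self._by_accession: dict[str, list[AliasRecord]] = {}
        self._by_name: dict[str, set[str]] = {}
        for rec in self.records:
            self._by_accession.setdefault(rec.accession, []).append(rec)
            self._by_name.setdefault(_normalize_query(rec.name), set()).add(rec.accession)
        self._validate()
        self.entries: dict[str, MatureEntry] = {}
        for e in entries:
            self.entries[e.accession] = e

    # -- validation ------------------------------------------------------

    def _rank(self, label: str | None) -> float:
        if label is None:
            return math.inf
        try:
            return self._vrank[label]
        except KeyError:
            raise RegistryError(f"version label {label!r} not declared in header") from None

    def _validate(self) -> None:
        for acc, recs in self._by_accession.items():
            spans = sorted(
                ((self._rank(r.version_from), self._rank(r.version_to)) for r in recs)
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 <= a1:  # ranges inclusive on both ends
                    raise RegistryError(
                        f"overlapping version ranges for accession {acc}"
                    )
            open_recs = [r for r in recs if r.version_to is None]
            if len(open_recs) > 1:
                raise RegistryError(
                    f"accession {acc} has {len(open_recs)} open-ended records"
                )

    # -- accessors -------------------------------------------------------

    def accessions(self) -> list[str]:
        return sorted(self._by_accession)

    def _latest_record(self, acc: str) -> AliasRecord:
        return max(self._by_accession[acc], key=lambda r: self._rank(r.version_from))

    def is_retired(self, acc: str) -> bool:
        last = self._latest_record(acc)
        return last.status == "retired" or last.version_to is not None

    def latest_name(self, acc: str) -> str:
        return self._latest_record(acc).name

    def history(self, acc: str) -> list[tuple[str, str, str | None]]:
        recs = sorted(self._by_accession[acc], key=lambda r: self._rank(r.version_from))
        return [(r.name, r.version_from, r.version_to) for r in recs]


# -- loading ---------------------------------------------------------------


def _parse_alias_table(path: str | Path) -> tuple[list[AliasRecord], list[str]]:
    path = Path(path)
    version_order: list[str] | None = None
    records: list[AliasRecord] = []
    header: list[str] | None = None
    seen: set[tuple[str, str, str]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#versions:"):
                version_order = line.split(":", 1)[1].split()
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                expected = {"accession", "name", "version_from", "version_to", "status"}
                if not expected <= set(header):
                    raise RegistryError(
                        f"{path}:{lineno}: alias table header must contain {sorted(expected)}"
                    )
                continue
            if len(fields) < len(header):
                raise RegistryError(f"{path}:{lineno}: expected {len(header)} columns")
            row = dict(zip(header, (f.strip() for f in fields)))
            vto = row["version_to"]
            vto_norm = None if vto.lower() in OPEN_VERSION_TOKENS else vto
            key = (row["accession"], row["name"], row["version_from"])
            if key in seen:
                raise RegistryError(
                    f"{path}:{lineno}: duplicate (accession, name, version) row {key}"
                )
            seen.add(key)
            status = row["status"].lower()
            if status not in ("active", "retired"):
                raise RegistryError(f"{path}:{lineno}: unknown status {row['status']!r}")
            records.append(
                AliasRecord(
                    accession=row["accession"],
                    name=row["name"],
                    version_from=row["version_from"],
                    version_to=vto_norm,
                    status=status,
                )
            )
    if version_order is None:
        raise RegistryError(f"{path}: missing '#versions:' header line")
    return records, version_order


def _load_sequences(path: str | Path) -> list[tuple[str, str, str]]:
    """Yield (accession, sequence, species) from FASTA or 2/3-column TSV."""
    path = Path(path)
    out: list[tuple[str, str, str]] = []
    with path.open() as fh:
        first = fh.read(1)
    if first == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append((rec.id, str(rec.seq).upper(), ""))
        return out
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "accession":
                continue
            if len(parts) < 2:
                raise RegistryError(f"{path}:{lineno}: need accession<TAB>sequence")
            species = parts[2] if len(parts) > 2 else ""
            out.append((parts[0], parts[1].upper(), species))
    return out


def _check_sequence(seq: str, where: str = "sequence") -> str:
    """Validate/normalise a mature sequence: DNA T transliterated to U."""
    s = seq.strip().upper()
    if not s:
        raise ValueError(f"{where}: empty sequence")
    if "T" in s:
        logger.info("%s: DNA alphabet detected, transliterating T->U", where)
        s = s.replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{where}: non-nucleotide characters {sorted(bad)}")
    return s


def load_registry(alias_table: str | Path, sequences: str | Path | None = None) -> Registry:
    """Load the alias table and (optionally) mature sequences into a Registry.

    The alias table is a TSV with columns accession, name, version_from,
    version_to, status and a ``#versions:`` header line declaring the total
    order of version labels.  Sequences come from FASTA (record id =
    accession) or a TSV with columns accession, sequence[, species].
    """
    records, version_order = _parse_alias_table(alias_table)
    reg = Registry(records, version_order)
    if sequences is not None:
        entries = []
        for acc, seq, species in _load_sequences(sequences):
            if acc not in reg._by_accession:
                logger.warning("sequence for unknown accession %s skipped", acc)
                continue
            s = _check_sequence(seq, where=acc)
            if not 15 <= len(s) <= 30:
                raise RegistryError(
                    f"{acc}: mature sequence length {len(s)} outside [15, 30]"
                )
            entries.append(
                MatureEntry(
                    accession=acc,
                    latest_name=reg.latest_name(acc),
                    sequence=s,
                    species=species,
                )
            )
        reg.entries = {e.accession: e for e in entries}
    return reg


# -- conversion ------------------------------------------------------------


def convert_id(query: str, registry: Registry) -> ConversionResult:
    """Resolve a name (any version) or accession to the current annotation.

    Unknown queries yield status ``unknown`` rather than raising; retired
    accessions are reported with status ``retired`` and must be excluded
    from downstream target analysis by the caller.  A historical name that
    maps to more than one accession and is not the current name of exactly
    one of them comes back ``ambiguous`` with every candidate listed.
    """
    q = query.strip()
    key = _normalize_query(q)
    # accession lookup first (accessions are unique by construction)
    acc_match = [a for a in registry._by_accession if a.lower() == key]
    if acc_match:
        acc = acc_match[0]
        return _result_for_accession(q, acc, registry)
    candidates = sorted(registry._by_name.get(key, ()))
    if not candidates:
        return ConversionResult(q, None, None, UNKNOWN)
    if len(candidates) == 1:
        return _result_for_accession(q, candidates[0], registry)
    # several accessions carried this name over history; the one whose
    # *current* name it is wins, if unique
    current = [
        a
        for a in candidates
        if not registry.is_retired(a) and _normalize_query(registry.latest_name(a)) == key
    ]
    if len(current) == 1:
        return _result_for_accession(q, current[0], registry)
    return ConversionResult(q, None, None, AMBIGUOUS, candidates=candidates)


def _result_for_accession(query: str, acc: str, registry: Registry) -> ConversionResult:
    history = registry.history(acc)
    latest = registry.latest_name(acc)
    if registry.is_retired(acc):
        return ConversionResult(query, acc, latest, RETIRED, history=history)
    status = (
        ALREADY_CURRENT if _normalize_query(query) == _normalize_query(latest) else CONVERTED
    )
    return ConversionResult(query, acc, latest, status, history=history)


def convert_batch(queries: Iterable[str], registry: Registry) -> list[ConversionResult]:
    """Convert a batch, logging one summary warning listing retired/unknown IDs."""
    results = [convert_id(q, registry) for q in queries]
    retired = [r.query for r in results if r.status == RETIRED]
    unknown = [r.query for r in results if r.status == UNKNOWN]
    ambiguous = [r.query for r in results if r.status == AMBIGUOUS]
    if retired:
        logger.warning("retired miRNAs excluded from analysis: %s", ", ".join(retired))
    if unknown:
        logger.warning("unknown miRNA IDs: %s", ", ".join(unknown))
    if ambiguous:
        logger.warning(
            "ambiguous names (supply the accession to disambiguate): %s",
            ", ".join(ambiguous),
        )
    return results


# -- sequence matching -----------------------------------------------------


def _ungapped_mismatches(query: str, subject: str) -> int:
    """Minimum mismatch count over ungapped alignments.

    Equal lengths: plain Hamming distance.  Unequal lengths: the shorter
    sequence slides along the longer one and the best (fewest-mismatch)
    full-containment window wins; the length difference itself is not
    charged.
    """
    if len(query) == len(subject):
        return sum(a != b for a, b in zip(query, subject))
    short, long_ = (query, subject) if len(query) < len(subject) else (subject, query)
    best = len(short)
    for off in range(len(long_) - len(short) + 1):
        mm = sum(a != b for a, b in zip(short, long_[off : off + len(short)]))
        if mm < best:
            best = mm
    return best


def match_sequence(
    seq: str, registry: Registry, max_mismatches: int = 2
) -> list[tuple[MatureEntry, int]]:
    """Rank registry mature entries by ungapped mismatch count against seq.

    Returns (entry, mismatches) pairs with mismatches <= max_mismatches,
    sorted by ascending mismatch count then accession.  Mature miRNAs are
    short (<=30 nt), so a full scan over the registry is exact and cheap —
    no heuristic seeding is needed.
    """
    s = _check_sequence(seq, where="query")
    hits: list[tuple[MatureEntry, int]] = []
    for entry in registry.entries.values():
        mm = _ungapped_mismatches(s, entry.sequence)
        if mm <= max_mismatches:
            hits.append((entry, mm))
    hits.sort(key=lambda t: (t[1], t[0].accession))
    return hits
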