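"""Readers, writers and run configuration.

All tabular interchange is plain text: TSV for pair tables and queries, GMT
for pathway gene sets, CSV (RFC 4180, UTF-8, '.' decimal separator) for
results.  Every result file opens with '#'-prefixed comment lines echoing
the exact effective configuration, so two outputs with identical embedded
configs and inputs are identical byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .enrichment import PathwayRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective analysis parameters; defaults are the standard operating point.

    min_hits=3 (voting threshold), min_oe=2.0 (O/E ratio cut-off) and
    include_validated=True are the canonical defaults of the consensus
    procedure; -log P is always base 10.
    """

    species: str = "hsa"
    algorithms: list[str] = field(default_factory=list)
    min_hits: int = 3
    min_oe: float = 2.0
    include_validated: bool = True
    universe_mode: str = "pathways_and_store"
    epsilon: float = 1e-300
    baseline: str | None = None
    seed: int = 0
    # data locations (optional: the library API can be fed objects directly)
    alias_table: str | None = None
    sequences: str | None = None
    predictions: dict[str, str] = field(default_factory=dict)
    validated: dict[str, str] = field(default_factory=dict)
    gmt: list[str] = field(default_factory=list)

    log_base: int = 10  # fixed; recorded for the config echo

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return RunConfig(**data)

    def comment_lines(self) -> list[str]:
        d = dataclasses.asdict(self)
        lines = []
        for k in sorted(d):
            v = d[k]
            if isinstance(v, dict):
                v = ",".join(f"{a}={b}" for a, b in sorted(v.items()))
            elif isinstance(v, list):
                v = ",".join(map(str, v))
            lines.append(f"# {k}: {v}")
        return lines


def read_gmt(path: str | Path, source_db: str | None = None) -> list[PathwayRecord]:
    """Read one GMT file: pathway_id TAB name TAB gene [TAB gene ...].

    ``source_db`` defaults to the file stem; multiple GMT files loaded with
    distinct tags stay distinguishable downstream.
    """
    path = Path(path)
    tag = source_db if source_db is not None else path.stem
    records: list[PathwayRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, name and >=1 gene")
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            records.append(PathwayRecord(parts[0], parts[1], tag, genes))
    return records


def read_query(path: str | Path) -> tuple[list[str], dict[str, float] | None]:
    """Read a query TSV: miRNA id, optionally TAB expression ratio.

    A header row (first field 'mirna_id' or similar non-numeric second
    column on line 1 starting with 'mirna') is skipped.  Returns the ordered
    id list and an expression map, or None when no ratios are present.
    """
    ids: list[str] = []
    expr: dict[str, float] = {}
    has_expr = False
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            if lineno == 1 and name.lower() in ("mirna_id", "mirna", "id", "name"):
                continue
            ids.append(name)
            if len(parts) > 1 and parts[1].strip():
                expr[name] = float(parts[1])
                has_expr = True
    if has_expr:
        missing = [m for m in ids if m not in expr]
        if missing:
            raise ValueError(f"expression ratios missing for: {missing}")
        return ids, expr
    return ids, None


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV old_symbol TAB unified_symbol."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            old, new = line.split("\t")[:2]
            out[old.strip()] = new.strip()
    return out


def write_results(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write a result CSV with header and '#' config-echo comment lines.

    Empty inputs still produce the comments plus a header row (when columns
    are known), so downstream tooling always sees a parsable file.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=list(columns) if columns else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        if config is not None:
            for line in config.comment_lines():
                fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result CSV, skipping the config-echo comments."""
    return pd.read_csv(path, comment="#")
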