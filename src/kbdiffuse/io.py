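"""Readers and writers for collection files.

Supported formats: GMT (tab-separated gene sets: name, description,
members...), YAML/JSON item files with {id, title, data, metadata} records,
and GFF3/GTF gene coordinates reduced to (gene, chrom, start, end) tuples.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable

import yaml

from .store import DataItem

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_items",
    "read_gene_coords",
    "items_from_gene_sets",
]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member genes}; the description column
    is ignored."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def items_from_gene_sets(sets: dict[str, set[str]], collection: str = "") -> list[DataItem]:
    """Represent each gene set as a text item whose body lists the member
    symbols."""
    return [
        DataItem(id=name, title=name, body=" ".join(sorted(genes)), collection=collection)
        for name, genes in sorted(sets.items())
    ]


def read_items(path: str | Path) -> list[DataItem]:
    """Read DataItems from a YAML or JSON file of {id, title, data, metadata}
    records (a list, or a mapping id -> record)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if isinstance(raw, dict):
        records = [{"id": k, **v} for k, v in raw.items()]
    else:
        records = raw
    items = []
    for rec in records:
        items.append(
            DataItem(
                id=str(rec["id"]),
                title=str(rec.get("title", "")),
                body=str(rec.get("data", rec.get("body", ""))),
                metadata={str(k): str(v) for k, v in (rec.get("metadata") or {}).items()},
            )
        )
    return items


_GFF_ATTR_PATTERNS = [
    re.compile(r'gene_name[ =]+"?([\w.\-]+)"?'),
    re.compile(r'Name=([\w.\-]+)'),
    re.compile(r'gene_id[ =]+"?([\w.\-]+)"?'),
    re.compile(r'ID=(?:gene:)?([\w.\-]+)'),
]


def read_gene_coords(path: str | Path, feature_type: str = "gene") -> list[tuple[str, str, int, int]]:
    """Extract (gene, chrom, start, end) from a GFF3/GTF file.

    Rows whose feature type differs from ``feature_type`` are ignored;
    malformed rows are skipped and counted in a log message.  Coordinates
    are 1-based inclusive as in the source format.
    """
    out: list[tuple[str, str, int, int]] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or parts[2] != feature_type:
            continue
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError:
            skipped += 1
            continue
        name = None
        for pat in _GFF_ATTR_PATTERNS:
            m = pat.search(parts[8])
            if m:
                name = m.group(1)
                break
        if name is None:
            skipped += 1
            continue
        out.append((name, parts[0], start, end))
    if skipped:
        logger.warning("skipped %d malformed annotation rows", skipped)
    return out
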