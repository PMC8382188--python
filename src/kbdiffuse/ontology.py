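"""Ontology terms as text items, and cross-ontology translation scoring.

OBO ontologies are flattened into one text item per non-obsolete term,
concatenating the term name, definition, comment, synonyms, parent-term
names, and the name of the top ancestor.  The name fields tie a term both to
its meaning and to its position in the hierarchy, so nearest-neighbor search
over these items can translate terms between ontologies (e.g. human to
mammalian phenotypes).

Translation quality is measured two ways: *precision* (exact identifier
match between the predicted and expected term) and *path length* (shortest
path between them in the target ontology's undirected is_a graph: 0 for an
exact match, 1 for parent/child, 2 for sibling or grandparent).
"""

from __future__ import annotations

import io as _io
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .diffusion import DiffusionSettings
from .query import search
from .store import DataItem, KnowledgeBase

logger = logging.getLogger(__name__)

__all__ = [
    "obo_to_items",
    "ontology_graph",
    "path_length",
    "top_ancestor",
    "evaluate_translation",
    "UNREACHABLE",
]

#: Sentinel for pairs with no connecting path; compares greater than any int.
UNREACHABLE = math.inf


def _read_obo(source) -> nx.MultiDiGraph:
    if isinstance(source, (str, Path)) and "\n" in str(source):
        return obonet.read_obo(_io.StringIO(str(source)))
    if isinstance(source, (str, Path)):
        return obonet.read_obo(str(source))
    return obonet.read_obo(source)


def _clean_def(text: str) -> str:
    # OBO defs look like: "definition text" [source refs]
    text = text.strip()
    if text.startswith('"'):
        end = text.rfind('"')
        if end > 0:
            return text[1:end]
    return text


def ontology_graph(source) -> nx.Graph:
    """Undirected graph over term ids with edges from is_a relations."""
    multi = source if isinstance(source, nx.MultiDiGraph) else _read_obo(source)
    graph = nx.Graph()
    graph.add_nodes_from(multi.nodes(data=True))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    return graph


def top_ancestor(multi: nx.MultiDiGraph, term_id: str) -> str:
    """Follow is_a edges upward to a term with no parents; ties between
    multiple roots are broken by the smallest id."""
    roots = set()
    seen = set()
    frontier = [term_id]
    while frontier:
        node = frontier.pop()
        if node in seen:
            continue
        seen.add(node)
        parents = [
            p for _, p, key in multi.out_edges(node, keys=True) if key == "is_a"
        ]
        if not parents:
            roots.add(node)
        else:
            frontier.extend(parents)
    return min(roots)


def obo_to_items(obo_source, collection: str = "") -> list[DataItem]:
    """One DataItem per non-obsolete term: the body concatenates name,
    definition, comment, synonyms, parent names, and top-ancestor name."""
    multi = _read_obo(obo_source)
    items: list[DataItem] = []
    skipped = 0
    names = {n: d.get("name", "") for n, d in multi.nodes(data=True)}
    for term_id, data in sorted(multi.nodes(data=True)):
        if data.get("is_obsolete") == "true":
            continue
        name = data.get("name")
        if name is None:
            skipped += 1
            continue
        parts = [name]
        if data.get("def"):
            parts.append(_clean_def(data["def"]))
        for comment in ([data["comment"]] if data.get("comment") else []):
            parts.append(comment)
        for syn in data.get("synonym", []):
            parts.append(_clean_def(syn))
        parent_names = [
            names.get(p, "")
            for _, p, key in multi.out_edges(term_id, keys=True)
            if key == "is_a"
        ]
        parts.extend(pn for pn in sorted(parent_names) if pn)
        parts.append(names.get(top_ancestor(multi, term_id), ""))
        items.append(
            DataItem(
                id=term_id,
                title=name,
                body=" ".join(p for p in parts if p),
                collection=collection,
            )
        )
    if skipped:
        logger.warning("skipped %d malformed ontology stanzas", skipped)
    return items


def path_length(graph: nx.Graph, a: str, b: str) -> float:
    """Shortest undirected is_a path length; UNREACHABLE (inf) for
    disconnected pairs."""
    if a not in graph or b not in graph:
        raise KeyError(f"term not in graph: {a if a not in graph else b}")
    try:
        return float(nx.shortest_path_length(graph, a, b))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def evaluate_translation(
    queries: Sequence[DataItem],
    kb: KnowledgeBase,
    expected: Mapping[str, str],
    graph: nx.Graph,
    collection: str,
    diffusion_settings: DiffusionSettings | None = None,
    n: int = 5,
    method: str = "plain",
) -> tuple[dict[str, float], pd.DataFrame]:
    """Translate each query into the target collection and score it.

    Returns a summary (mean precision at rank 1 and within top-n, mean path
    length at rank 1 and best-of-top-n over reachable pairs, plus the count
    of unreachable or empty results) and a per-query table with columns
    id, name, expected, expected_name, target, target_name, target_N,
    method, precision, pathlen, precision_bestN, pathlen_bestN.
    """
    rows = []
    for q in queries:
        if q.id not in expected:
            raise KeyError(f"no expected translation for query {q.id!r}")
        exp_id = expected[q.id]
        try:
            exp_name = kb.get_item(exp_id).title
        except KeyError:
            exp_name = ""
        hits = search(kb, q.text, collection, n=n, diffusion_settings=diffusion_settings)
        hit_ids = [h.item_id for h in hits]
        top_id = hit_ids[0] if hit_ids else ""
        precision = float(top_id == exp_id)
        precision_best = float(exp_id in hit_ids)
        if top_id:
            path1 = path_length(graph, top_id, exp_id)
        else:
            path1 = UNREACHABLE
        paths = [path_length(graph, h, exp_id) for h in hit_ids]
        best_path = min(paths) if paths else UNREACHABLE
        rows.append(
            {
                "id": q.id,
                "name": q.title,
                "expected": exp_id,
                "expected_name": exp_name,
                "target": top_id,
                "target_name": kb.get_item(top_id).title if top_id else "",
                "target_N": ";".join(hit_ids),
                "method": method,
                "precision": precision,
                "pathlen": path1,
                "precision_bestN": precision_best,
                "pathlen_bestN": best_path,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "id",
            "name",
            "expected",
            "expected_name",
            "target",
            "target_name",
            "target_N",
            "method",
            "precision",
            "pathlen",
            "precision_bestN",
            "pathlen_bestN",
        ],
    )
    reach1 = table["pathlen"][table["pathlen"] < UNREACHABLE]
    reachN = table["pathlen_bestN"][table["pathlen_bestN"] < UNREACHABLE]
    summary = {
        "precision_top1": float(table["precision"].mean()) if len(table) else 0.0,
        "precision_top5": float(table["precision_bestN"].mean()) if len(table) else 0.0,
        "mean_path_top1": float(reach1.mean()) if len(reach1) else UNREACHABLE,
        "mean_path_best5": float(reachN.mean()) if len(reachN) else UNREACHABLE,
        "n_unreachable": int((table["pathlen"] >= UNREACHABLE).sum()),
        "n_queries": len(table),
    }
    return summary, table
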