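"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and sample metadata travel as TSV, gene sets as GMT,
PPI networks as two-column edge lists or SIF, and gene lists as one symbol
per line.  All writers are deterministic (fixed column order, lexicographic
sorting where the producing stage does not define an order) so pipeline
reruns under a fixed seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .bundle import ExpressionBundle, ProbeMap

# ---------------------------------------------------------------------------
# expression bundles


def write_expression_tsv(bundle: ExpressionBundle, path: str | Path) -> None:
    bundle.matrix.to_csv(path, sep="\t", index_label="gene")


def write_metadata_tsv(bundle: ExpressionBundle, path: str | Path) -> None:
    bundle.metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_expression_bundle(
    expression_path: str | Path, metadata_path: str | Path, disease: str = ""
) -> ExpressionBundle:
    matrix = pd.read_csv(expression_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str).str.upper()
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return ExpressionBundle(matrix=matrix, metadata=metadata, disease=disease)


# ---------------------------------------------------------------------------
# gene lists and probe maps


def read_gene_list(path: str | Path) -> list[str]:
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.upper())
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_probe_map(path: str | Path) -> ProbeMap:
    """Two-column TSV (probe_id, gene symbol); blank symbol = unmapped."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        probe = parts[0].strip()
        symbol = parts[1].strip() if len(parts) > 1 else ""
        if probe in mapping:
            raise ValueError(f"duplicate probe id in map: {probe}")
        if symbol:
            mapping[probe] = symbol
    return ProbeMap(mapping)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name <TAB> description <TAB> member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line!r}")
        name = fields[0]
        members = [g.strip().upper() for g in fields[2:] if g.strip()]
        if name in sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions=None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("".join(f"{l}\n" for l in lines))


# ---------------------------------------------------------------------------
# graphs


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column undirected edge list TSV; self-loops dropped."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed edge-list line: {line!r}")
        a, b = parts[0].strip().upper(), parts[1].strip().upper()
        if a != b:
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = sorted(tuple(sorted(e)) for e in graph.edges())
    Path(path).write_text("".join(f"{a}\t{b}\n" for a, b in lines))


def read_sif(path: str | Path) -> nx.Graph:
    """SIF: node <TAB/space> relation <TAB/space> node [node ...]."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            graph.add_node(parts[0].upper())
        else:
            src = parts[0].upper()
            for target in parts[2:]:
                if target and target.upper() != src:
                    graph.add_edge(src, target.upper())
    return graph


def write_sif(edges, path: str | Path, relation: str = "pp") -> None:
    """Write (a, b) or (a, b, attr) tuples as SIF; attr appended to relation."""
    lines = []
    for edge in edges:
        if len(edge) == 2:
            a, b = edge
            lines.append(f"{a}\t{relation}\t{b}")
        else:
            a, b, attr = edge
            lines.append(f"{a}\t{relation}={attr}\t{b}")
    Path(path).write_text("".join(f"{l}\n" for l in lines))


# ---------------------------------------------------------------------------
# misc


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
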