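"""Signed digraph construction from the interaction matrix.

Filtering keeps the strongest interactions *within each sign class*
(by default the 100 largest positive and the 100 most negative weights,
i.e. a top-200 network). Hubs are nodes with more than five retained
interactions (total degree >= 6 by default). Ego interactomes extract the
strongest edges incident to a focal probe. Networks export to SIF
("activates"/"inhibits" relations), GraphML (weight and sign attributes)
and a round-trippable edge TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from luminet.exceptions import FormatError, PanelError
from luminet.interaction_inference import InteractionMatrix

__all__ = [
    "Edge",
    "Network",
    "filter_top_edges",
    "find_hubs",
    "ego_interactome",
    "export_network",
    "import_edge_tsv",
    "to_networkx",
]


@dataclass(frozen=True)
class Edge:
    """One signed directed interaction."""

    source: str
    target: str
    weight: float

    @property
    def sign(self) -> int:
        return 1 if self.weight > 0 else (-1 if self.weight < 0 else 0)


@dataclass
class Network:
    """A filtered signed weighted digraph with hub annotations."""

    nodes: list[str] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    hubs: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def degree(self, node: str) -> int:
        """Total degree: in + out, each retained edge counted once."""
        return sum(1 for e in self.edges if node in (e.source, e.target))


def _as_pair_rows(pairs) -> list[tuple[str, str, float]]:
    if isinstance(pairs, pd.DataFrame):
        return [
            (str(s), str(t), float(w))
            for s, t, w in pairs[["source", "target", "weight"]].itertuples(
                index=False
            )
        ]
    return [(str(s), str(t), float(w)) for s, t, w in pairs]


def filter_top_edges(
    pairs, n_positive: int = 100, n_negative: int = 100
) -> Network:
    """Keep the strongest interactions of each sign.

    The ``n_positive`` largest positive weights and the ``n_negative`` most
    negative weights are retained; ties break by (|weight| desc, source ID,
    target ID). If a sign class has fewer entries than requested, all of it
    is kept and a warning is recorded on the network. Zero weights are
    never retained.
    """
    rows = _as_pair_rows(pairs)
    positives = [r for r in rows if r[2] > 0]
    negatives = [r for r in rows if r[2] < 0]
    positives.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    negatives.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))

    warnings = []
    if len(positives) < n_positive:
        warnings.append(
            f"only {len(positives)} positive interactions available "
            f"(requested {n_positive})"
        )
    if len(negatives) < n_negative:
        warnings.append(
            f"only {len(negatives)} negative interactions available "
            f"(requested {n_negative})"
        )
    kept = positives[:n_positive] + negatives[:n_negative]
    edges = [Edge(s, t, w) for s, t, w in kept]
    nodes = sorted({n for e in edges for n in (e.source, e.target)})
    return Network(nodes=nodes, edges=edges, warnings=warnings)


def find_hubs(net: Network, min_interactions: int = 6) -> set[str]:
    """Nodes with at least ``min_interactions`` retained interactions.

    The default of 6 implements the "more than five interactions"
    hub convention. The result is also stored on ``net.hubs``.
    """
    hubs = {n for n in net.nodes if net.degree(n) >= min_interactions}
    net.hubs = hubs
    return hubs


def ego_interactome(matrix: InteractionMatrix, focal: str, k: int) -> Network:
    """The ``k`` strongest-|weight| interactions incident to a focal probe.

    Edges in either direction count; signs and directions are preserved.
    ``k`` at least twice the panel size minus two returns every incident
    edge; ``k = 0`` returns the focal node alone.
    """
    if focal not in matrix.panel:
        raise PanelError(
            f"focal probe {focal!r} is not in the panel"
        )
    if k < 0:
        raise PanelError("k must be >= 0")
    fi = matrix.panel.index(focal)
    incident = []
    for i, pid in enumerate(matrix.panel):
        if pid == focal:
            continue
        incident.append((pid, focal, float(matrix.scores[i, fi])))
        incident.append((focal, pid, float(matrix.scores[fi, i])))
    incident.sort(key=lambda r: (-abs(r[2]), r[0], r[1]))
    edges = [Edge(s, t, w) for s, t, w in incident[:k]]
    nodes = sorted({focal} | {n for e in edges for n in (e.source, e.target)})
    return Network(nodes=nodes, edges=edges)


def to_networkx(net: Network) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for n in net.hubs:
        g.nodes[n]["hub"] = True
    for e in net.edges:
        g.add_edge(e.source, e.target, weight=e.weight, sign=e.sign)
    return g


def export_network(net: Network, path: str | Path, format: str) -> Path:
    """Write the network as SIF, GraphML or edge TSV.

    SIF uses the relation tokens ``activates`` (positive weight) and
    ``inhibits`` (negative weight). The edge TSV round-trips exactly via
    :func:`import_edge_tsv`.
    """
    path = Path(path)
    fmt = format.lower().replace("-", "_")
    if fmt == "sif":
        lines = [
            f"{e.source}\t{'activates' if e.weight > 0 else 'inhibits'}\t{e.target}"
            for e in net.edges
        ]
        connected = {n for e in net.edges for n in (e.source, e.target)}
        lines += [n for n in net.nodes if n not in connected]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif fmt in ("edge_tsv", "tsv"):
        with path.open("w") as fh:
            fh.write("source\ttarget\tweight\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.weight!r}\n")
    else:
        raise FormatError(
            f"unknown format {format!r}; expected SIF, GraphML or edge-TSV"
        )
    return path


def import_edge_tsv(path: str | Path) -> Network:
    """Read an edge TSV written by :func:`export_network` (exact round-trip)."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"source": str, "target": str},
        float_precision="round_trip",
    )
    edges = [
        Edge(str(s), str(t), float(w))
        for s, t, w in frame.itertuples(index=False)
    ]
    nodes = sorted({n for e in edges for n in (e.source, e.target)})
    return Network(nodes=nodes, edges=edges)
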