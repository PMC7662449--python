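"""Wright path diagrams: tracing, compound paths, determinations.

A diagram is a DAG of causal edges carrying path coefficients, plus
undirected correlation arcs between exogenous nodes. Following Wright's
tracing rules for the two-layer diagrams used in breed-composition
pedigrees, a traced path from a source to a sink is either a directed
chain, or exactly one correlation arc leaving the source followed by a
directed chain; no node is revisited. The coefficient of a compound
path is the product of its segment coefficients, and the determination
of a sink by a source sums the squared directed-path coefficients plus
the cross terms between directed paths and arc-initiated paths.

Diagrams serialize to a small JSON schema::

    {"nodes": ["A", "B", "C", "D"],
     "edges": [{"from": "A", "to": "C", "coeff": 0.7906}, ...],
     "arcs":  [{"between": ["A", "B"], "r": 0.0}]}
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "PathDiagram",
    "WrightPath",
    "trace_wright_paths",
    "compound_path_coefficient",
    "determination_from_diagram",
    "diagram_composition",
    "ultrablack_diagram",
    "read_diagram",
    "write_diagram",
]

# segment kinds
EDGE = "edge"
ARC = "arc"


@dataclass(frozen=True)
class WrightPath:
    """An ordered chain of segments (kind, from, to, coefficient)."""

    segments: tuple[tuple[str, str, str, float], ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.segments[0][1],) + tuple(s[2] for s in self.segments)

    @property
    def coefficient(self) -> float:
        return compound_path_coefficient(list(self.segments))

    @property
    def starts_with_arc(self) -> bool:
        return self.segments[0][0] == ARC

    def __repr__(self) -> str:  # e.g. A~B->C->D
        parts = [self.segments[0][1]]
        for kind, _, dst, _ in self.segments:
            parts.append(("~" if kind == ARC else "->") + dst)
        return "".join(parts)


@dataclass
class PathDiagram:
    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    arcs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for src, dst, c in self.edges:
            if src not in known or dst not in known:
                raise ValueError(f"edge {src}->{dst} references unknown node")
            if not math.isfinite(c):
                raise ValueError(f"edge {src}->{dst} has non-finite coefficient")
        for a, b, r in self.arcs:
            if a not in known or b not in known:
                raise ValueError(f"arc {a}~{b} references unknown node")
            if not math.isfinite(r):
                raise ValueError(f"arc {a}~{b} has non-finite correlation")
        self._check_dag()
        endogenous = {dst for _, dst, _ in self.edges}
        for a, b, _ in self.arcs:
            if a in endogenous or b in endogenous:
                raise ValueError(
                    f"correlation arc {a}~{b} touches an endogenous node"
                )

    def _check_dag(self) -> None:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for src, dst, _ in self.edges:
            children[src].append(dst)
            indeg[dst] += 1
        queue = [n for n in self.nodes if indeg[n] == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.nodes):
            raise ValueError("causal edges contain a cycle; diagram must be a DAG")

    def children(self, node: str) -> list[tuple[str, float]]:
        return [(dst, c) for src, dst, c in self.edges if src == node]

    def arcs_from(self, node: str) -> list[tuple[str, float]]:
        out = []
        for a, b, r in self.arcs:
            if a == node:
                out.append((b, r))
            elif b == node:
                out.append((a, r))
        return out

    def exogenous(self) -> list[str]:
        endo = {dst for _, dst, _ in self.edges}
        connected = {n for e in self.edges for n in e[:2]}
        return [n for n in self.nodes if n not in endo and n in connected]


def _directed_chains(d: PathDiagram, source: str, sink: str) -> list[WrightPath]:
    chains: list[WrightPath] = []

    def dfs(node: str, segs: list, visited: set) -> None:
        if node == sink:
            if segs:
                chains.append(WrightPath(tuple(segs)))
            return
        for child, coeff in d.children(node):
            if child in visited:
                continue
            segs.append((EDGE, node, child, coeff))
            dfs(child, segs, visited | {child})
            segs.pop()

    dfs(source, [], {source})
    return chains


def trace_wright_paths(d: PathDiagram, source: str, sink: str) -> list[WrightPath]:
    """All admissible paths from source to sink: directed chains, plus
    chains opening with a single correlation arc from the source
    (when that arc's correlation is nonzero)."""
    for node in (source, sink):
        if node not in d.nodes:
            raise KeyError(f"unknown node {node!r}")
    paths = _directed_chains(d, source, sink)
    for other, r in d.arcs_from(source):
        if r == 0 or other == sink:
            continue
        for chain in _directed_chains(d, other, sink):
            if source in chain.nodes:
                continue
            paths.append(WrightPath(((ARC, source, other, r),) + chain.segments))
    return paths


def compound_path_coefficient(path: list[tuple[str, str, str, float]]) -> float:
    """Product of segment coefficients along a connected chain."""
    if not path:
        raise ValueError("empty path has no compound coefficient")
    coeff = 1.0
    prev_end = None
    for kind, src, dst, c in path:
        if prev_end is not None and src != prev_end:
            raise ValueError(f"path is not connected at {src!r}")
        if kind not in (EDGE, ARC):
            raise ValueError(f"unknown segment kind {kind!r}")
        coeff *= c
        prev_end = dst
    return coeff


def determination_from_diagram(d: PathDiagram, source: str, sink: str) -> float:
    """Determination of the sink by the source: the sum of squared
    directed compound-path coefficients, plus cross terms between each
    directed path and each path beginning with a correlation arc from
    the source."""
    paths = trace_wright_paths(d, source, sink)
    direct = [p.coefficient for p in paths if not p.starts_with_arc]
    arc_initiated = [p.coefficient for p in paths if p.starts_with_arc]
    det = sum(c * c for c in direct)
    det += sum(c * a for c in direct for a in arc_initiated)
    return det


def diagram_composition(d: PathDiagram, sink: str) -> dict[str, float]:
    """Determination of the sink by every exogenous source (the diagram
    analogue of per-breed combined determination)."""
    return {src: determination_from_diagram(d, src, sink) for src in d.exogenous()}


def ultrablack_diagram(
    p_CA2: float = 0.625,
    p_CB2: float = 0.375,
    p_DA2: float = 0.5,
    p_DC2: float = 0.5,
    r_AB: float = 0.0,
) -> PathDiagram:
    """Two-layer diagram of a first-generation Brangus x Angus cross.

    Angus (A) and Brahman (B) determine Brangus (C); Angus and Brangus
    determine the Ultrablack (D). Arguments are squared path
    coefficients, defaulting to the pedigree expectation (Brangus 5/8
    Angus + 3/8 Brahman; Ultrablack = 1/2 Brangus x 1/2 Angus).
    """
    return PathDiagram(
        nodes=["Angus", "Brahman", "Brangus", "Ultrablack"],
        edges=[
            ("Angus", "Brangus", math.sqrt(p_CA2)),
            ("Brahman", "Brangus", math.sqrt(p_CB2)),
            ("Angus", "Ultrablack", math.sqrt(p_DA2)),
            ("Brangus", "Ultrablack", math.sqrt(p_DC2)),
        ],
        arcs=[("Angus", "Brahman", r_AB)],
    )


def read_diagram(path: str | Path) -> PathDiagram:
    data = json.loads(Path(path).read_text())
    edges = [(e["from"], e["to"], float(e["coeff"])) for e in data.get("edges", [])]
    arcs = [
        (a["between"][0], a["between"][1], float(a["r"])) for a in data.get("arcs", [])
    ]
    return PathDiagram(list(data["nodes"]), edges, arcs)


def write_diagram(d: PathDiagram, path: str | Path) -> None:
    data = {
        "nodes": d.nodes,
        "edges": [{"from": s, "to": t, "coeff": c} for s, t, c in d.edges],
        "arcs": [{"between": [a, b], "r": r} for a, b, r in d.arcs],
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
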