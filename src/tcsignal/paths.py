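"""All-shortest signaling paths from primary drivers to significant TFs.

Paths are searched by breadth-first search in the directed path view of
the PKN (regulatory, metabolic and virtual edges forward; PPI edges in
both directions; correlation edges excluded; low-confidence edges
excluded by default).  For every (driver, TF) pair ALL minimum-length
directed paths are retained — downstream temporal statistics count path
multiplicity — and unreachable pairs are recorded with a reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .dysregulation import GeneDysregulation
from .pkn import KnowledgeNetwork, path_view_graph
from .regulator_enrichment import RegulatorCall

logger = logging.getLogger(__name__)


@dataclass
class PathConfig:
    include_low_confidence: bool = False
    driver_alpha: float = 0.05
    tf_alpha: float = 0.05
    max_paths_per_pair: Optional[int] = None


@dataclass(frozen=True)
class SignalPath:
    segment: Tuple[str, str]
    nodes: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"repeated node in path {self.nodes}")

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def terminus(self) -> str:
        return self.nodes[-1]


@dataclass
class PathSet:
    segment: Tuple[str, str]
    paths: List[SignalPath] = field(default_factory=list)
    unreachable: List[Tuple[str, str, str]] = field(default_factory=list)  # (driver, tf, reason)


def _bfs_predecessors(g: nx.DiGraph, source: str) -> Tuple[Dict[str, int], Dict[str, List[str]]]:
    """Single-source BFS: distances and ALL shortest-path predecessors."""
    dist = {source: 0}
    preds: Dict[str, List[str]] = {source: []}
    frontier = [source]
    while frontier:
        nxt: List[str] = []
        for u in frontier:
            du = dist[u]
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = du + 1
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == du + 1:
                    preds[v].append(u)
        frontier = nxt
    return dist, preds


def _enumerate_paths(preds: Dict[str, List[str]], target: str,
                     cap: Optional[int]) -> List[Tuple[str, ...]]:
    """Backtrack every shortest path ending at *target* (lexicographic order)."""
    out: List[Tuple[str, ...]] = []
    stack: List[Tuple[str, Tuple[str, ...]]] = [(target, (target,))]
    while stack:
        node, suffix = stack.pop()
        ps = preds[node]
        if not ps:
            out.append(suffix)
            if cap is not None and len(out) >= cap:
                break
            continue
        for p in sorted(ps, reverse=True):
            stack.append((p, (p,) + suffix))
    return sorted(out)


def all_shortest_paths(net: KnowledgeNetwork, sources: Iterable[str],
                       targets: Iterable[str],
                       config: Optional[PathConfig] = None,
                       segment: Tuple[str, str] = ("", "")) -> PathSet:
    """All minimum-length directed paths between every (source, target) pair."""
    cfg = config or PathConfig()
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    if not sources or not targets:
        raise ValueError("sources and targets must be non-empty")
    g = path_view_graph(net, include_low_confidence=cfg.include_low_confidence)
    result = PathSet(segment)
    for s in sources:
        if s not in g:
            for t in targets:
                result.unreachable.append((s, t, "missing_source"))
            continue
        dist, preds = _bfs_predecessors(g, s)
        for t in targets:
            if t == s:
                result.paths.append(SignalPath(segment, (s,)))
                continue
            if t not in g:
                result.unreachable.append((s, t, "missing_target"))
                continue
            if t not in dist:
                result.unreachable.append((s, t, "unreachable"))
                continue
            for nodes in _enumerate_paths(preds, t, cfg.max_paths_per_pair):
                result.paths.append(SignalPath(segment, nodes))
    return result


def collect_segment_paths(driver_results: Sequence[GeneDysregulation],
                          tf_results: Sequence[RegulatorCall],
                          net: KnowledgeNetwork,
                          config: Optional[PathConfig] = None,
                          segment: Tuple[str, str] = ("", "")) -> PathSet:
    """Bind significant drivers (sources) and TF calls (targets) to the search."""
    cfg = config or PathConfig()
    sources: Set[str] = {d.gene for d in driver_results if d.p <= cfg.driver_alpha}
    targets: Set[str] = {c.regulator for c in tf_results if c.fdr <= cfg.tf_alpha}
    if not sources or not targets:
        logger.warning("segment %s: no significant %s; empty path set", segment,
                       "drivers" if not sources else "TFs")
        return PathSet(segment)
    return all_shortest_paths(net, sources, targets, cfg, segment)
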