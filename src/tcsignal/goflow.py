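"""GO information-flow view: greedy term selection and cross-segment flow.

Per segment, biological-process GO terms (with annotations propagated up
to ancestors) summarize that segment's DEGs through a greedy set cover:
overly general terms above a coverage ceiling are excluded, then terms
are picked iteratively by how many not-yet-covered DEGs they add,
stopping when the best candidate adds too few new genes or overlaps the
covered set too much.  Selected terms become (term, segment) nodes;
adjacent-segment nodes are linked with weight = number of shared covered
genes, giving a flow view of how biological processes hand genes to one
another over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class GOFlowConfig:
    coverage_ceiling: float = 0.5  # max fraction of DEGs a candidate term may cover
    min_new: int = 3               # minimum newly covered genes per accepted term
    max_overlap: float = 0.5       # max fraction of a term's DEGs already covered


@dataclass
class TermAnnotation:
    term_to_genes: Dict[str, Set[str]]
    term_to_parents: Dict[str, Set[str]]


@dataclass
class GOFlowNetwork:
    nodes: List[Tuple[str, int, FrozenSet[str]]] = field(default_factory=list)
    # (term, segment index, covered genes)
    edges: List[Tuple[str, int, str, int, int]] = field(default_factory=list)
    # (term1, segment s, term2, segment s+1, weight)


# ---------------------------------------------------------------------------
# Annotation I/O and ancestor propagation
# ---------------------------------------------------------------------------

def read_annotation_tsv(path: str) -> Dict[str, Set[str]]:
    """term_id <tab> gene_id rows (header tolerated)."""
    ann: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or fields[0] in ("term_id", "term"):
                continue
            ann.setdefault(fields[0], set()).add(fields[1])
    return ann


def read_gaf(path: str) -> Dict[str, Set[str]]:
    """Minimal GAF 2.x reader: maps GO id (col 5) -> object symbols (col 3)."""
    ann: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            ann.setdefault(fields[4], set()).add(fields[2])
    return ann


def read_parents_tsv(path: str) -> Dict[str, Set[str]]:
    parents: Dict[str, Set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or fields[0] in ("term_id", "term"):
                continue
            parents.setdefault(fields[0], set()).add(fields[1])
    return parents


def propagate_ancestors(raw: Dict[str, Set[str]],
                        parents: Dict[str, Set[str]]) -> TermAnnotation:
    """Close annotations under the parent relation (gene -> all ancestors)."""
    g = nx.DiGraph()  # edge child -> parent
    terms = set(raw) | set(parents) | {p for ps in parents.values() for p in ps}
    g.add_nodes_from(terms)
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(child, p)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise ValueError(f"parent graph has a cycle through edge {cycle[0][:2]}") from None
    closed: Dict[str, Set[str]] = {t: set(raw.get(t, ())) for t in terms}
    for t in order:  # children precede parents
        for p in g.successors(t):
            closed[p] |= closed[t]
    return TermAnnotation(closed, {t: set(parents.get(t, ())) for t in terms})


# ---------------------------------------------------------------------------
# Greedy term selection
# ---------------------------------------------------------------------------

def greedy_select_terms(degs: Set[str], ann: TermAnnotation,
                        config: Optional[GOFlowConfig] = None) -> List[str]:
    """Iterative max-new-coverage term selection with the documented tie rule.

    Ties on newly added genes break by smaller total term size, then by
    lexicographic term id.  Selection stops when the best candidate adds
    fewer than ``min_new`` genes or more than ``max_overlap`` of its DEGs
    are already covered.
    """
    if not degs:
        raise ValueError("degs must be non-empty")
    cfg = config or GOFlowConfig()
    candidates = {
        t: genes & degs for t, genes in ann.term_to_genes.items()
        if genes & degs and len(genes & degs) / len(degs) <= cfg.coverage_ceiling
    }
    if not candidates:
        logger.warning("no admissible GO terms for this DEG set")
        return []
    selected: List[str] = []
    covered: Set[str] = set()
    while candidates:
        best = min(candidates,
                   key=lambda t: (-len(candidates[t] - covered),
                                  len(ann.term_to_genes[t]), t))
        new = candidates[best] - covered
        overlap = len(candidates[best] & covered) / len(candidates[best])
        if len(new) < cfg.min_new or overlap > cfg.max_overlap:
            break
        selected.append(best)
        covered |= candidates[best]
        del candidates[best]
    return selected


def build_flow_network(selections: Sequence[Sequence[str]],
                       ann: TermAnnotation,
                       degs_per_segment: Sequence[Set[str]]) -> GOFlowNetwork:
    """(term, segment) nodes; adjacent-segment edges weighted by shared genes."""
    if len(selections) < 2:
        raise ValueError("need >=2 segments")
    if len(selections) != len(degs_per_segment):
        raise ValueError("selections and DEG sets must align")
    net = GOFlowNetwork()
    covered: List[Dict[str, FrozenSet[str]]] = []
    for seg_idx, (terms, degs) in enumerate(zip(selections, degs_per_segment), start=1):
        seg_cov = {t: frozenset(ann.term_to_genes[t] & degs) for t in terms}
        covered.append(seg_cov)
        for t in terms:
            net.nodes.append((t, seg_idx, seg_cov[t]))
    for s in range(len(covered) - 1):
        for t1, c1 in sorted(covered[s].items()):
            for t2, c2 in sorted(covered[s + 1].items()):
                w = len(c1 & c2)
                if w >= 1:
                    net.edges.append((t1, s + 1, t2, s + 2, w))
    return net
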