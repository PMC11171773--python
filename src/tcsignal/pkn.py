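"""Signed prior knowledge network (PKN): data model, I/O and views.

The PKN is a directed, mechanism-typed multigraph over genes, proteins,
complexes and metabolites.  Each edge carries a regulatory sign
(activation / repression / unknown), an interaction mechanism and a
literature-derived influence-factor (IF) reliability score.  Edges whose
IF score falls below a confidence threshold (default 0.86) are *flagged*
as low-confidence rather than removed, so the network keeps its
integrity while downstream path search can skip unreliable conduits.

Complex nodes are decomposed into their basic units by *virtual* edges
(member -> complex, activation), which preserves connectivity through
multi-protein assemblies without special-casing them in graph searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_IF_THRESHOLD = 0.86


class Sign(str, Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    UNKNOWN = "unknown"


class Mechanism(str, Enum):
    TRANSCRIPTIONAL = "transcriptional_regulation"
    PPI = "ppi"
    METABOLIC = "metabolic"
    CORRELATION = "correlation"
    VIRTUAL = "virtual"


class NodeKind(str, Enum):
    GENE = "gene"
    PROTEIN = "protein"
    COMPLEX = "complex"
    METABOLITE = "metabolite"


#: mechanisms whose edges are causal, directed conduits
DIRECTED_MECHANISMS = {Mechanism.TRANSCRIPTIONAL, Mechanism.METABOLIC, Mechanism.VIRTUAL}
#: default mechanisms admitted into signaling-path search
PATH_MECHANISMS = {Mechanism.TRANSCRIPTIONAL, Mechanism.PPI, Mechanism.METABOLIC, Mechanism.VIRTUAL}

# accepted spellings for the sign column
_SIGN_ALIASES = {
    "activation": Sign.ACTIVATION,
    "+": Sign.ACTIVATION,
    "repression": Sign.REPRESSION,
    "-": Sign.REPRESSION,
    "unknown": Sign.UNKNOWN,
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Structurally invalid network (dangling endpoint, bad complex, ...)."""


@dataclass
class Node:
    id: str
    kind: NodeKind = NodeKind.GENE
    members: Tuple[str, ...] = ()
    annotations: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind is not NodeKind.COMPLEX and self.members:
            raise ValidationError(f"node {self.id!r}: members only allowed for complexes")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: Sign = Sign.UNKNOWN
    mechanism: Mechanism = Mechanism.TRANSCRIPTIONAL
    if_score: float = 1.0
    reference: str = ""
    low_confidence: bool = False

    @property
    def directed(self) -> bool:
        return self.mechanism in DIRECTED_MECHANISMS

    def pair(self) -> Tuple[str, str]:
        """Unordered endpoint pair (canonical ordering)."""
        return (self.source, self.target) if self.source <= self.target else (self.target, self.source)


@dataclass
class KnowledgeNetwork:
    """Signed, mechanism-typed PKN; edges form a multiset."""

    nodes: Dict[str, Node] = field(default_factory=dict)
    edges: List[Edge] = field(default_factory=list)
    if_threshold: Optional[float] = None

    # -- construction -------------------------------------------------
    def add_node(self, node: Node) -> None:
        self.nodes[node.id] = node

    def ensure_node(self, node_id: str, kind: NodeKind = NodeKind.GENE) -> Node:
        if node_id not in self.nodes:
            self.nodes[node_id] = Node(node_id, kind)
        return self.nodes[node_id]

    def add_edge(self, edge: Edge) -> None:
        self.ensure_node(edge.source)
        self.ensure_node(edge.target)
        self.edges.append(edge)

    def add_complex(self, complex_id: str, members: Iterable[str]) -> None:
        members = tuple(members)
        if not members:
            raise ValidationError(f"complex {complex_id!r} has no members")
        self.nodes[complex_id] = Node(complex_id, NodeKind.COMPLEX, members)

    # -- queries ------------------------------------------------------
    def validate(self) -> None:
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise ValidationError(f"edge {e.source}->{e.target}: dangling endpoint {endpoint!r}")
            if e.mechanism is Mechanism.CORRELATION and e.source == e.target:
                raise ValidationError(f"correlation self-loop on {e.source!r}")

    def out_edges(self, node_id: str, mechanism: Optional[Mechanism] = None) -> List[Edge]:
        return [e for e in self.edges
                if e.source == node_id and (mechanism is None or e.mechanism is mechanism)]

    def node_ids(self) -> Set[str]:
        return set(self.nodes)

    def copy(self) -> "KnowledgeNetwork":
        net = KnowledgeNetwork(if_threshold=self.if_threshold)
        net.nodes = {nid: Node(n.id, n.kind, n.members, dict(n.annotations))
                     for nid, n in self.nodes.items()}
        net.edges = list(self.edges)
        return net


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["source", "target", "sign", "mechanism", "if_score", "reference"]


def _parse_sign(raw: str, lineno: int) -> Sign:
    key = raw.strip().lower()
    if key in _SIGN_ALIASES:
        return _SIGN_ALIASES[key]
    logger.warning("line %d: unknown sign %r mapped to 'unknown'", lineno, raw)
    return Sign.UNKNOWN


def read_network(path: str, dialect: str = "tsv") -> KnowledgeNetwork:
    """Load a PKN from an edge table (``tsv``), ``sif`` or ``graphml`` file."""
    if dialect == "tsv":
        net = _read_tsv(path)
    elif dialect == "sif":
        net = _read_sif(path)
    elif dialect == "graphml":
        net = _read_graphml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    net.validate()
    return net


def _read_tsv(path: str) -> KnowledgeNetwork:
    net = KnowledgeNetwork()
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            return net  # empty file -> empty network
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _TSV_COLUMNS[:4] if c not in header]
        if missing:
            raise ParseError(f"{path}:1: missing required columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
            try:
                mechanism = Mechanism(fields[idx["mechanism"]].strip())
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if_score = 1.0
            if "if_score" in idx and fields[idx["if_score"]].strip():
                try:
                    if_score = float(fields[idx["if_score"]])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric if_score "
                                     f"{fields[idx['if_score']]!r}") from None
            net.add_edge(Edge(
                source=fields[idx["source"]].strip(),
                target=fields[idx["target"]].strip(),
                sign=_parse_sign(fields[idx["sign"]], lineno),
                mechanism=mechanism,
                if_score=if_score,
                reference=fields[idx["reference"]].strip() if "reference" in idx and len(fields) > idx["reference"] else "",
            ))
    return net


def _read_sif(path: str) -> KnowledgeNetwork:
    # SIF: source <tab> relation <tab> target [target ...]; relation doubles
    # as "sign:mechanism" or a bare sign with transcriptional mechanism.
    net = KnowledgeNetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: SIF row needs >=3 fields")
            source, relation = fields[0], fields[1]
            if ":" in relation:
                sign_raw, mech_raw = relation.split(":", 1)
                try:
                    mechanism = Mechanism(mech_raw)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
            else:
                sign_raw, mechanism = relation, Mechanism.TRANSCRIPTIONAL
            for target in fields[2:]:
                net.add_edge(Edge(source, target, _parse_sign(sign_raw, lineno), mechanism))
    return net


def _read_graphml(path: str) -> KnowledgeNetwork:
    g = nx.read_graphml(path)
    net = KnowledgeNetwork()
    for nid, data in g.nodes(data=True):
        members = tuple(m for m in data.get("members", "").split(",") if m)
        kind = NodeKind(data.get("kind", "gene"))
        net.add_node(Node(str(nid), kind, members))
    for u, v, data in g.edges(data=True):
        net.add_edge(Edge(
            source=str(u), target=str(v),
            sign=_parse_sign(data.get("sign", "unknown"), 0),
            mechanism=Mechanism(data.get("mechanism", "transcriptional_regulation")),
            if_score=float(data.get("if_score", 1.0)),
            reference=str(data.get("reference", "")),
            low_confidence=bool(data.get("low_confidence", False)),
        ))
    return net


def write_network(net: KnowledgeNetwork, path: str, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.sign.value}\t{e.mechanism.value}"
                         f"\t{e.if_score!r}\t{e.reference}\n")
    elif dialect == "graphml":
        g = to_nx(net)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported write dialect {dialect!r}")


def read_complexes(path: str) -> Dict[str, Tuple[str, ...]]:
    """Complex table: complex_id <tab> comma-separated members."""
    out: Dict[str, Tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected complex_id<TAB>members")
            out[fields[0]] = tuple(m for m in fields[1].split(",") if m)
    return out


def read_regulons(path: str) -> Dict[str, List[str]]:
    """Regulon table: regulator <tab> target rows."""
    out: Dict[str, List[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2:
                out.setdefault(fields[0], []).append(fields[1])
    return out


def to_nx(net: KnowledgeNetwork) -> nx.MultiDiGraph:
    """networkx view with full attributes (undirected mechanisms kept as one arc)."""
    g = nx.MultiDiGraph()
    for nid, node in net.nodes.items():
        g.add_node(nid, kind=node.kind.value, members=",".join(node.members))
    for e in net.edges:
        g.add_edge(e.source, e.target, sign=e.sign.value, mechanism=e.mechanism.value,
                   if_score=e.if_score, reference=e.reference, low_confidence=e.low_confidence)
    return g


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def filter_by_if(net: KnowledgeNetwork, threshold: float = DEFAULT_IF_THRESHOLD) -> KnowledgeNetwork:
    """Flag (never delete) edges whose IF score is strictly below *threshold*."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = net.copy()
    out.if_threshold = threshold
    out.edges = [replace(e, low_confidence=e.if_score < threshold) for e in out.edges]
    return out


def expand_virtual(net: KnowledgeNetwork) -> KnowledgeNetwork:
    """Connect each complex to its members by member->complex virtual edges.

    Direction member -> complex lets signals flow from components into the
    assembled regulator.  Original edges are untouched.
    """
    out = net.copy()
    for node in sorted(net.nodes.values(), key=lambda n: n.id):
        if node.kind is not NodeKind.COMPLEX:
            continue
        if not node.members:
            raise ValidationError(f"complex {node.id!r} has no members")
        for member in node.members:
            if member not in net.nodes:
                raise ValidationError(f"complex {node.id!r}: unknown member {member!r}")
            out.edges.append(Edge(member, node.id, Sign.ACTIVATION, Mechanism.VIRTUAL))
    return out


def mechanism_view(net: KnowledgeNetwork, mechanisms: Iterable[Mechanism]) -> KnowledgeNetwork:
    """Subnetwork of edges with mechanism in *mechanisms* plus their endpoints."""
    mechanisms = set(mechanisms)
    if not mechanisms:
        raise ValueError("mechanisms must be non-empty")
    out = KnowledgeNetwork(if_threshold=net.if_threshold)
    kept = [e for e in net.edges if e.mechanism in mechanisms]
    for e in kept:
        for endpoint in (e.source, e.target):
            n = net.nodes[endpoint]
            out.nodes.setdefault(endpoint, Node(n.id, n.kind, n.members, dict(n.annotations)))
    out.edges = kept
    return out


def path_view_graph(net: KnowledgeNetwork,
                    mechanisms: Optional[Set[Mechanism]] = None,
                    include_low_confidence: bool = False) -> nx.DiGraph:
    """Directed simple graph used for signaling-path search.

    PPI edges are traversed in both directions; parallel edges collapse to
    the max-IF representative.  Correlation edges never enter this view.
    """
    mechanisms = PATH_MECHANISMS if mechanisms is None else mechanisms
    g = nx.DiGraph()
    for e in net.edges:
        if e.mechanism not in mechanisms or e.mechanism is Mechanism.CORRELATION:
            continue
        if e.low_confidence and not include_low_confidence:
            continue
        arcs = [(e.source, e.target)]
        if not e.directed:
            arcs.append((e.target, e.source))
        for u, v in arcs:
            old = g.get_edge_data(u, v)
            if old is None or e.if_score > old["if_score"]:
                g.add_edge(u, v, sign=e.sign.value, if_score=e.if_score,
                           mechanism=e.mechanism.value)
    return g
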