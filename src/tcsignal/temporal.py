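"""Cross-segment temporal statistics: frequencies, callbacks and pruning.

A node's observed frequency in a segment is its number of path
memberships among that segment's collected shortest paths (multiplicity,
not binary presence).  Across segments each node gets a mean and a
population standard deviation of its frequencies; the per-segment
Z-score (observed - mean) / sd with a one-sided upper-tail normal
p-value tests whether a node is used significantly more than its own
baseline.

A *callback regulator* is a node that terminates a path in one segment
and originates a path in a later segment at most ``window`` (default 5)
segments ahead — a downstream effect turning into an upstream cause.

Pruning keeps a node if it ranks in the top decile of total path
frequency (ceiling count, boundary ties kept) or if it is a callback
regulator whose reuse-segment Z-test is significant (p < 0.05).  Kept
edges are the path-view edges lying on at least one collected path with
both endpoints kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from scipy.special import erfc

from .paths import PathSet
from .pkn import KnowledgeNetwork, path_view_graph

DEFAULT_WINDOW = 5
DEFAULT_TOP_FRAC = 0.10
DEFAULT_ALPHA = 0.05


@dataclass
class NodeTemporalStats:
    node: str
    freq_by_segment: Dict[int, int]
    mean_freq: float
    sd_freq: float
    z_by_segment: Dict[int, float] = field(default_factory=dict)
    p_by_segment: Dict[int, float] = field(default_factory=dict)
    is_top_decile: bool = False
    callback_segments: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def total_freq(self) -> int:
        return sum(self.freq_by_segment.values())


@dataclass
class PrunedNetwork:
    kept_nodes: Set[str]
    kept_edges: Dict[Tuple[str, str], str]  # (u, v) -> sign
    keep_reason: Dict[str, Set[str]]


def node_frequencies(pathsets: Sequence[PathSet]) -> Dict[str, NodeTemporalStats]:
    """Per-node path-membership counts per segment, with mean and population sd.

    Segments are indexed 1..len(pathsets) in list order; segments where a
    node is absent count as zero.
    """
    if not pathsets:
        raise ValueError("need >=1 PathSet")
    n_seg = len(pathsets)
    counts: Dict[str, Dict[int, int]] = {}
    for seg_idx, ps in enumerate(pathsets, start=1):
        for path in ps.paths:
            for node in path.nodes:
                counts.setdefault(node, {})[seg_idx] = counts.get(node, {}).get(seg_idx, 0) + 1
    stats: Dict[str, NodeTemporalStats] = {}
    for node in sorted(counts):
        freqs = {s: counts[node].get(s, 0) for s in range(1, n_seg + 1)}
        vals = list(freqs.values())
        mean = sum(vals) / n_seg
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / n_seg)
        stats[node] = NodeTemporalStats(node, freqs, mean, sd)
    return stats


def detect_callbacks(pathsets: Sequence[PathSet],
                     window: int = DEFAULT_WINDOW) -> Dict[str, List[Tuple[int, int]]]:
    """(end_segment, reuse_segment) pairs per node with 0 < reuse - end <= window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    end_segments: Dict[str, Set[int]] = {}
    source_segments: Dict[str, Set[int]] = {}
    for seg_idx, ps in enumerate(pathsets, start=1):
        for path in ps.paths:
            end_segments.setdefault(path.terminus, set()).add(seg_idx)
            source_segments.setdefault(path.source, set()).add(seg_idx)
    callbacks: Dict[str, List[Tuple[int, int]]] = {}
    for node in sorted(set(end_segments) & set(source_segments)):
        pairs = [(e, r) for e in sorted(end_segments[node])
                 for r in sorted(source_segments[node]) if 0 < r - e <= window]
        if pairs:
            callbacks[node] = pairs
    return callbacks


def zscore_test(stats: NodeTemporalStats, segment: int) -> Tuple[float, float]:
    """Z = (observed - mean)/sd; one-sided upper-tail normal p (sd=0 -> z=0, p=1)."""
    observed = stats.freq_by_segment.get(segment, 0)
    if stats.sd_freq == 0:
        return 0.0, 1.0
    z = (observed - stats.mean_freq) / stats.sd_freq
    p = 0.5 * erfc(z / math.sqrt(2.0))
    return z, p


def annotate_stats(stats: Dict[str, NodeTemporalStats],
                   pathsets: Sequence[PathSet],
                   window: int = DEFAULT_WINDOW) -> None:
    """Fill per-segment z/p and callback pairs in place."""
    callbacks = detect_callbacks(pathsets, window)
    for node, st in stats.items():
        for seg in st.freq_by_segment:
            st.z_by_segment[seg], st.p_by_segment[seg] = zscore_test(st, seg)
        st.callback_segments = callbacks.get(node, [])


def prune_network(stats: Dict[str, NodeTemporalStats],
                  pathsets: Sequence[PathSet],
                  net: KnowledgeNetwork,
                  top_frac: float = DEFAULT_TOP_FRAC,
                  window: int = DEFAULT_WINDOW,
                  alpha: float = DEFAULT_ALPHA,
                  include_low_confidence: bool = False) -> PrunedNetwork:
    """Keep top-decile-frequency nodes and significant callback regulators."""
    if not stats:
        raise ValueError("need >=1 node")
    annotate_stats(stats, pathsets, window)

    totals = sorted((st.total_freq for st in stats.values()), reverse=True)
    n_keep = math.ceil(top_frac * len(totals))
    cutoff = totals[n_keep - 1] if n_keep >= 1 else math.inf

    kept: Set[str] = set()
    reasons: Dict[str, Set[str]] = {}
    for node, st in stats.items():
        r: Set[str] = set()
        if st.total_freq >= cutoff:
            r.add("top_decile")
            st.is_top_decile = True
        if any(zscore_test(st, reuse)[1] < alpha for _, reuse in st.callback_segments):
            r.add("callback_significant")
        if r:
            kept.add(node)
            reasons[node] = r

    g = path_view_graph(net, include_low_confidence=include_low_confidence)
    on_path: Set[Tuple[str, str]] = set()
    for ps in pathsets:
        for path in ps.paths:
            on_path.update(zip(path.nodes[:-1], path.nodes[1:]))
    kept_edges = {
        (u, v): g[u][v]["sign"]
        for (u, v) in sorted(on_path)
        if u in kept and v in kept and g.has_edge(u, v)
    }
    return PrunedNetwork(kept, kept_edges, reasons)
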