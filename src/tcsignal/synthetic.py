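"""Synthetic PKNs and time courses with planted drivers, cascades and callbacks.

The generator emulates the study conditions end to end: a signed
scale-free regulatory core built by preferential attachment (activation
0.7 / repression 0.3, IF scores Uniform(0.5, 1)), a gene-gene
correlation layer over co-regulated siblings, regulons (out-
neighborhoods of high-degree regulators) and small protein complexes.

Expression is log2 scale with per-gene baselines Normal(10, 1) —
matching the global mean-10 convention — i.i.d. Normal(0, noise_sd)
replicate noise, and a planted signal: at an onset segment each planted
driver steps by +delta and pushes a sign-aware step of the same
magnitude into its targets and along a planted driver -> intermediate ->
TF shortest path, including the terminal TF's regulon.  With the default
``lag=0`` the whole cascade fires within the onset segment (signaling is
fast relative to the sampling interval); ``lag>0`` spreads it one edge
per *lag* segments.  A callback event is planted by re-perturbing, at a
later onset, the regulon of the first cascade's terminal TF, so that the
TF reappears as an upstream source a few segments after having been a
downstream terminus.

The returned truth manifest is sufficient to score drivers, TF calls,
paths and callbacks without re-reading generator internals.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .expression import ExpressionSeries, write_expression
from .paths import SignalPath
from .pkn import Edge, KnowledgeNetwork, Mechanism, NodeKind, Sign, write_network

SIGN_P_ACTIVATION = 0.7


@dataclass
class SyntheticTruth:
    planted_drivers: Dict[int, Set[str]]
    planted_paths: List[SignalPath]
    planted_callbacks: List[Tuple[str, int, int]]  # (node, end_segment, reuse_segment)
    effect_size: float
    noise_sd: float
    seed: int
    onset_segment: int = 1
    regulons: Dict[str, List[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "planted_drivers": {str(k): sorted(v) for k, v in self.planted_drivers.items()},
            "planted_paths": [list(p.nodes) for p in self.planted_paths],
            "planted_callbacks": [list(c) for c in self.planted_callbacks],
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "onset_segment": self.onset_segment,
        }, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def generate_network(n_genes: int = 200, n_edges: int = 600,
                     regulon_count: int = 10, complex_count: int = 3,
                     n_corr_edges: int = 200, seed: int = 0,
                     topology: str = "scale_free",
                     ) -> Tuple[KnowledgeNetwork, Dict[str, List[str]], List[List[str]]]:
    """Signed regulatory core + correlation layer, regulons and complexes.

    ``topology="scale_free"`` (default) grows a preferential-attachment
    core with heavy-tailed out-degrees, as in curated regulatory
    networks; ``topology="uniform"`` places the same number of edges
    between uniformly random pairs, which keeps node degrees homogeneous
    (useful for calibration experiments where hub genes would couple
    many edge statistics).  Returns (network, regulons, complexes); the
    network holds exactly *n_edges* transcriptional edges over *n_genes*
    gene nodes, plus the correlation layer, complex nodes and
    intra-complex PPI cliques.
    """
    if n_edges < n_genes - 1:
        raise ValueError("need n_edges >= n_genes - 1 for a connected-ish core")
    if n_edges > n_genes * (n_genes - 1) // 2:
        raise ValueError("too many edges for a simple directed core")
    if topology not in ("scale_free", "uniform"):
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    net = KnowledgeNetwork()
    for g in genes:
        net.ensure_node(g)

    m0 = min(3, n_genes - 1)
    out_deg = np.zeros(n_genes, dtype=float)
    adj: Set[Tuple[int, int]] = set()
    edge_list: List[Tuple[int, int]] = []
    if topology == "uniform":
        while len(edge_list) < n_edges:
            i, j = (int(x) for x in rng.integers(0, n_genes, 2))
            if i == j or (i, j) in adj:
                continue
            edge_list.append((i, j))
            adj.add((i, j))
            out_deg[i] += 1
        new_nodes: List[int] = []
    else:
        new_nodes = list(range(m0, n_genes))
    base, extra = divmod(n_edges, len(new_nodes)) if new_nodes else (0, 0)
    surplus = 0
    for pos, j in enumerate(new_nodes):
        want = base + (1 if pos < extra else 0) + surplus
        k = min(want, j)  # at most one in-edge per prior node
        surplus = want - k
        weights = out_deg[:j] + 1.0
        probs = weights / weights.sum()
        sources = rng.choice(j, size=k, replace=False, p=probs)
        for s in sources:
            edge_list.append((int(s), j))
            adj.add((int(s), j))
            out_deg[s] += 1
    # place any surplus between random unconnected pairs, preferential source
    while surplus > 0:
        weights = out_deg + 1.0
        s = int(rng.choice(n_genes, p=weights / weights.sum()))
        t = int(rng.integers(0, n_genes))
        if s == t or (s, t) in adj:
            continue
        edge_list.append((s, t))
        adj.add((s, t))
        out_deg[s] += 1
        surplus -= 1

    for s, t in edge_list:
        sign = Sign.ACTIVATION if rng.random() < SIGN_P_ACTIVATION else Sign.REPRESSION
        net.add_edge(Edge(genes[s], genes[t], sign, Mechanism.TRANSCRIPTIONAL,
                          if_score=float(rng.uniform(0.5, 1.0)), reference="synthetic"))

    # correlation layer over co-regulated siblings
    targets_of: Dict[int, List[int]] = {}
    for s, t in edge_list:
        targets_of.setdefault(s, []).append(t)
    sibling_pairs = sorted({
        (min(x, y), max(x, y))
        for ts in targets_of.values() if len(ts) >= 2
        for i, x in enumerate(ts) for y in ts[i + 1:] if x != y
    } - {(min(s, t), max(s, t)) for s, t in adj})
    if sibling_pairs:
        n_pick = min(n_corr_edges, len(sibling_pairs))
        picked = rng.choice(len(sibling_pairs), size=n_pick, replace=False)
        for idx in sorted(picked):
            x, y = sibling_pairs[idx]
            net.add_edge(Edge(genes[x], genes[y], Sign.UNKNOWN, Mechanism.CORRELATION,
                              if_score=float(rng.uniform(0.5, 1.0)), reference="synthetic"))

    order = np.argsort(-out_deg, kind="stable")
    regulons = {genes[i]: sorted(genes[t] for t in targets_of[i])
                for i in order[:regulon_count] if i in targets_of}

    complexes: List[List[str]] = []
    for c in range(complex_count):
        size = int(rng.integers(2, 4))
        members = sorted(genes[i] for i in rng.choice(n_genes, size=size, replace=False))
        complexes.append(members)
        cid = f"C{c + 1:02d}"
        net.add_complex(cid, members)
        for i, x in enumerate(members):
            for y in members[i + 1:]:
                net.add_edge(Edge(x, y, Sign.UNKNOWN, Mechanism.PPI,
                                  if_score=float(rng.uniform(0.5, 1.0)), reference="synthetic"))
    net.validate()
    return net, regulons, complexes


# ---------------------------------------------------------------------------
# Time-course simulation with planted signal
# ---------------------------------------------------------------------------

def _sign_value(sign: Sign) -> float:
    return -1.0 if sign is Sign.REPRESSION else 1.0


def _pick_cascade(g: nx.DiGraph, driver: str, degree_cap: int,
                  rng: np.random.Generator,
                  tf_out: Tuple[int, int] = (3, 3)) -> Optional[List[str]]:
    """A driver -> intermediate -> TF path through modest-degree nodes.

    The returned path is a shortest path in the regulatory view (so the
    path search can rediscover it); falls back to driver -> TF length 1.
    The terminal TF's regulon is kept small (out-degree within *tf_out*)
    so the planted signal stays sparse.
    """
    def deg(n: str) -> int:
        return g.out_degree(n) + g.in_degree(n)

    mids = [m for m in sorted(g.successors(driver)) if deg(m) <= degree_cap]
    rng.shuffle(mids)
    # prefer a TF with a small but testable regulon; relax if the network
    # is too sparse to offer one
    for lo, hi in ((tf_out[0], tf_out[1]), (2, tf_out[1]), (1, degree_cap)):
        def tf_ok(t: str) -> bool:
            return lo <= g.out_degree(t) <= hi and deg(t) <= degree_cap

        for mid in mids:
            tfs = [t for t in sorted(g.successors(mid))
                   if t != driver and t not in g.successors(driver) and tf_ok(t)]
            if tfs:
                return [driver, mid, tfs[0]]
        tfs = [t for t in sorted(g.successors(driver)) if tf_ok(t)]
        if tfs:
            return [driver, tfs[0]]
    return None


def simulate_series(net: KnowledgeNetwork, n_timepoints: int = 8,
                    replicates: int = 3, delta: float = 2.0,
                    noise_sd: float = 0.25, n_drivers: int = 5,
                    n_cascades: int = 1, onset_segment: int = 2,
                    callback_gap: int = 2, lag: int = 0, seed: int = 0,
                    ) -> Tuple[ExpressionSeries, SyntheticTruth]:
    """Simulate a replicated log2 time course with the planted signal."""
    if n_timepoints < 3:
        raise ValueError("need n_timepoints >= 3")
    n_segments = n_timepoints - 1
    if not 1 <= onset_segment <= n_segments:
        raise ValueError("onset_segment out of range")
    rng = np.random.default_rng(seed)

    g = nx.DiGraph()
    for e in net.edges:
        if e.mechanism is Mechanism.TRANSCRIPTIONAL:
            g.add_edge(e.source, e.target, sign=e.sign)
    genes = sorted(n.id for n in net.nodes.values() if n.kind is not NodeKind.COMPLEX)
    gene_idx = {x: i for i, x in enumerate(genes)}

    out_degree = {x: (g.out_degree(x) if x in g else 0) for x in genes}
    # Drivers are the largest regulators: only the driver gene itself steps,
    # so a high out-degree gives it a broad multi-edge dysregulation
    # signature without entangling the rest of the transcriptome.
    drivers = sorted(genes, key=lambda x: (-out_degree[x], x))[:n_drivers]
    degree_cap = max(3, min(out_degree[d] for d in drivers) // 2) if drivers else 3

    # shift[g, t] = planted offset of gene g at timepoint index t (0-based)
    shift = np.zeros((len(genes), n_timepoints))
    shifted_at: Dict[Tuple[str, int], bool] = {}

    def apply_step(gene: str, segment: int, offset: float) -> None:
        if segment > n_segments or (gene, segment) in shifted_at:
            return
        shifted_at[(gene, segment)] = True
        shift[gene_idx[gene], segment:] += offset  # timepoint T_{segment+1} onward

    planted_paths: List[SignalPath] = []
    planted_callbacks: List[Tuple[str, int, int]] = []
    planted_drivers: Dict[int, Set[str]] = {}
    callback_tf: Optional[str] = None

    if delta != 0.0 and drivers:
        # Perturb each driver itself (+delta step); the effect runs along the
        # planted driver -> intermediate -> TF path and into the terminal
        # TF's regulon, sign-aware.  Nothing else shifts, so the permutation
        # null (random non-adjacent pairs) stays largely uncontaminated.
        planted_drivers[onset_segment] = set(drivers)
        seg_label = (f"T{onset_segment}", f"T{onset_segment + 1}")
        for d_idx, d in enumerate(drivers):
            apply_step(d, onset_segment, delta)
            if d_idx >= n_cascades:
                continue
            cascade = _pick_cascade(g, d, degree_cap, rng) if d in g else None
            if cascade is None:
                continue
            planted_paths.append(SignalPath(seg_label, tuple(cascade)))
            carry = delta
            for depth, (u, v) in enumerate(zip(cascade[:-1], cascade[1:]), start=1):
                carry *= _sign_value(g[u][v]["sign"])
                apply_step(v, onset_segment + lag * depth, carry)
            tf = cascade[-1]
            tf_depth = len(cascade) - 1
            for t in sorted(g.successors(tf)):
                apply_step(t, onset_segment + lag * (tf_depth + 1),
                           carry * _sign_value(g[tf][t]["sign"]))
            if callback_tf is None:
                callback_tf = tf

        reuse = onset_segment + callback_gap
        if callback_tf is not None and reuse <= n_segments:
            planted_drivers.setdefault(reuse, set()).add(callback_tf)
            planted_callbacks.append((callback_tf, onset_segment, reuse))
            apply_step(callback_tf, reuse, delta)
            for t in sorted(g.successors(callback_tf)):
                apply_step(t, reuse + lag, -delta * _sign_value(g[callback_tf][t]["sign"]))

    for path in planted_paths:
        for u, v in zip(path.nodes[:-1], path.nodes[1:]):
            if not g.has_edge(u, v):
                raise ValueError(f"planted path edge {u}->{v} absent from network")

    baseline = rng.normal(10.0, 1.0, size=len(genes))
    timepoints = [f"T{t + 1}" for t in range(n_timepoints)]
    samples, groups = [], {}
    cols = []
    for t, tp in enumerate(timepoints):
        for r in range(1, replicates + 1):
            name = f"{tp}_r{r}"
            samples.append(name)
            groups[name] = tp
            cols.append(baseline + shift[:, t] + rng.normal(0.0, noise_sd, size=len(genes)))
    values = np.column_stack(cols)

    series = ExpressionSeries(genes, samples, values, groups, timepoints)
    truth = SyntheticTruth(planted_drivers, planted_paths, planted_callbacks,
                           delta, noise_sd, seed, onset_segment)
    return series, truth


# ---------------------------------------------------------------------------
# Fixture dumping (round-trips through the pkn / expression readers)
# ---------------------------------------------------------------------------

def write_fixture(outdir: str, net: KnowledgeNetwork,
                  regulons: Dict[str, List[str]], complexes: Sequence[Sequence[str]],
                  series: ExpressionSeries, truth: SyntheticTruth) -> Dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "network": "pkn.tsv", "expression": "expression.tsv", "groups": "groups.tsv",
        "regulons": "regulons.tsv", "complexes": "complexes.tsv", "truth": "truth.json",
    }.items()}
    write_network(net, paths["network"])
    write_expression(series, paths["expression"], paths["groups"])
    with open(paths["regulons"], "w", encoding="utf-8") as fh:
        for r, targets in sorted(regulons.items()):
            for t in targets:
                fh.write(f"{r}\t{t}\n")
    with open(paths["complexes"], "w", encoding="utf-8") as fh:
        for i, members in enumerate(complexes, start=1):
            fh.write(f"C{i:02d}\t{','.join(members)}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(truth.to_json() + "\n")
    return paths
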