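"""End-to-end orchestration of the temporal causal signaling analysis.

For each adjacent timepoint pair (segment): DEG calling, primary-driver
dysregulation analysis, TF enrichment and driver->TF shortest-path
collection.  Across segments: temporal frequency/callback statistics,
network pruning, hypernode clustering and (optionally) the GO
information-flow view.  Every output is a fixed-name text file in the
run directory plus a manifest recording the configuration and derived
seeds, which makes a rerun byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import yaml

from . import __version__
from .dysregulation import DriverConfig, DriverResult, run_driver_analysis
from .expression import DEFAULT_FC, DEFAULT_FDR, DEGSet, ExpressionSeries, call_degs
from .goflow import (GOFlowConfig, TermAnnotation, build_flow_network,
                     greedy_select_terms, propagate_ancestors)
from .hypergraph import (DEFAULT_BOOST, DEFAULT_RESOLUTION, aggregate_hyperedges,
                         louvain_hypernodes, weight_for_clustering)
from .paths import PathConfig, PathSet, collect_segment_paths
from .pkn import (DEFAULT_IF_THRESHOLD, KnowledgeNetwork, expand_virtual,
                  filter_by_if)
from .regulator_enrichment import RegulatorCall, run_enrichment
from .temporal import (DEFAULT_ALPHA, DEFAULT_TOP_FRAC, DEFAULT_WINDOW,
                       node_frequencies, prune_network)

logger = logging.getLogger(__name__)

_SEED_MOD = 2 ** 31


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults follow the published protocol."""
    if_threshold: float = DEFAULT_IF_THRESHOLD
    fdr: float = DEFAULT_FDR
    fc: float = DEFAULT_FC
    null_draws: int = 10_000
    driver_alpha: float = 0.05
    tf_alpha: float = 0.05
    window: int = DEFAULT_WINDOW
    top_frac: float = DEFAULT_TOP_FRAC
    prune_alpha: float = DEFAULT_ALPHA
    boost: float = DEFAULT_BOOST
    resolution: float = DEFAULT_RESOLUTION
    seed: int = 0
    include_low_confidence: bool = False
    goflow: GOFlowConfig = field(default_factory=GOFlowConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        go = GOFlowConfig(**raw.pop("goflow", {}))
        return cls(goflow=go, **raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(root: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (root * 1_000_003 + stage_index) % _SEED_MOD


# ---------------------------------------------------------------------------
# TSV writers (fixed schemas, deterministic row order)
# ---------------------------------------------------------------------------

def _seg_tag(segment: Tuple[str, str]) -> str:
    return f"{segment[0]}{segment[1]}"


def write_degs(degs: DEGSet, path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tlog2fc\tp\tfdr\tstatus\n")
        n = 0
        for gene in degs.stats.index:
            row = degs.stats.loc[gene]
            status = degs.direction(gene) or "ns"
            n += status != "ns"
            fh.write(f"{gene}\t{row.log2fc:.6g}\t{row.p:.6g}\t{row.fdr:.6g}\t{status}\n")
    return n


def write_drivers(result: DriverResult, path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tchi2\tdf\tp\tn_edges\tis_driver\n")
        for g in result.genes:
            fh.write(f"{g.gene}\t{g.chi2:.6g}\t{g.df:.6g}\t{g.p:.6g}\t{g.n_edges}"
                     f"\t{int(g.is_driver)}\n")
    return len(result.genes)


def write_tfs(calls: Sequence[RegulatorCall], path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\tstate\ta\tb\tc\td\tp\tfdr\tsignificant\n")
        for c in calls:
            t = c.table
            fh.write(f"{c.regulator}\t{c.pseudo_state}\t{t.a}\t{t.b}\t{t.c}\t{t.d}"
                     f"\t{c.p:.6g}\t{c.fdr:.6g}\t{int(c.significant)}\n")
    return len(calls)


def write_paths(ps: PathSet, path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("segment\tdriver\ttf\tlength\tpath\n")
        tag = f"{ps.segment[0]}:{ps.segment[1]}"
        for p in sorted(ps.paths, key=lambda p: (p.source, p.terminus, p.nodes)):
            fh.write(f"{tag}\t{p.source}\t{p.terminus}\t{p.length}\t{'>'.join(p.nodes)}\n")
    return len(ps.paths)


def write_temporal_stats(stats, path: str) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tsegment\tfreq\tz\tp\ttotal_freq\tmean_freq\tsd_freq"
                 "\tis_top_decile\tcallbacks\n")
        n = 0
        for node in sorted(stats):
            st = stats[node]
            cbs = ";".join(f"{e}-{r}" for e, r in st.callback_segments)
            for seg in sorted(st.freq_by_segment):
                fh.write(f"{node}\t{seg}\t{st.freq_by_segment[seg]}"
                         f"\t{st.z_by_segment.get(seg, 0.0):.6g}"
                         f"\t{st.p_by_segment.get(seg, 1.0):.6g}"
                         f"\t{st.total_freq}\t{st.mean_freq:.6g}\t{st.sd_freq:.6g}"
                         f"\t{int(st.is_top_decile)}\t{cbs}\n")
                n += 1
    return n


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def run_all(series: ExpressionSeries, net: KnowledgeNetwork, outdir: str,
            config: Optional[RunConfig] = None,
            annotation: Optional[TermAnnotation] = None,
            regulons: Optional[Dict[str, List[str]]] = None,
            complexes: Optional[Sequence[Sequence[str]]] = None) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    cfg = config or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg.to_dict(),
                      "stages": {}, "stage_seeds": {}}

    net = filter_by_if(net, cfg.if_threshold)
    net = expand_virtual(net)

    segments = series.segments()
    pathsets: List[PathSet] = []
    degsets: List[DEGSet] = []
    pcfg = PathConfig(include_low_confidence=cfg.include_low_confidence,
                      driver_alpha=cfg.driver_alpha, tf_alpha=cfg.tf_alpha)
    for i, segment in enumerate(segments):
        t0 = time.perf_counter()
        tag = _seg_tag(segment)
        try:
            degs = call_degs(series, segment, cfg.fdr, cfg.fc)
            seed = stage_seed(cfg.seed, i)
            dcfg = DriverConfig(null_draws=cfg.null_draws,
                                driver_alpha=cfg.driver_alpha, seed=seed)
            drivers = run_driver_analysis(series, segment, net, dcfg)
            tfs = run_enrichment(degs, net, cfg.tf_alpha)
            ps = collect_segment_paths(drivers.genes, tfs, net, pcfg, segment)
        except Exception:
            logger.exception("stage failed: segment %s", segment)
            raise RuntimeError(f"stage failed: segment {segment}") from None
        degsets.append(degs)
        pathsets.append(ps)
        manifest["stage_seeds"][tag] = seed
        manifest["stages"][tag] = {
            "degs": write_degs(degs, os.path.join(outdir, f"degs_{tag}.tsv")),
            "drivers": write_drivers(drivers, os.path.join(outdir, f"drivers_{tag}.tsv")),
            "tfs": write_tfs(tfs, os.path.join(outdir, f"tfs_{tag}.tsv")),
            "paths": write_paths(ps, os.path.join(outdir, f"paths_{tag}.tsv")),
        }
        logger.info("segment %s done in %.1fs", segment, time.perf_counter() - t0)

    stats = node_frequencies(pathsets) if any(ps.paths for ps in pathsets) else {}
    if stats:
        pruned = prune_network(stats, pathsets, net, cfg.top_frac, cfg.window,
                               cfg.prune_alpha, cfg.include_low_confidence)
        g = nx.DiGraph()
        g.add_nodes_from(sorted(pruned.kept_nodes))
        for (u, v), sign in sorted(pruned.kept_edges.items()):
            g.add_edge(u, v, sign=sign)
        for node in g.nodes:
            g.nodes[node]["keep_reason"] = ",".join(sorted(pruned.keep_reason[node]))
        nx.write_graphml(g, os.path.join(outdir, "pruned.graphml"))
        manifest["stages"]["temporal"] = {
            "stats_rows": write_temporal_stats(stats, os.path.join(outdir, "temporal_stats.tsv")),
            "kept_nodes": len(pruned.kept_nodes),
            "kept_edges": len(pruned.kept_edges),
        }

        if pruned.kept_nodes:
            hseed = stage_seed(cfg.seed, len(segments) + 1)
            wg = weight_for_clustering(pruned, regulons, complexes, cfg.boost)
            hypernodes = louvain_hypernodes(wg, seed=hseed, resolution=cfg.resolution)
            hnet = aggregate_hyperedges(pruned, hypernodes)
            hg = nx.DiGraph()
            for h in hnet.hypernodes:
                hg.add_node(h.id, label=h.label, members=",".join(sorted(h.members)))
            for hu, hv, sign, weight in hnet.hyperedges:
                hg.add_edge(hu, hv, sign=sign, weight=weight)
            nx.write_graphml(hg, os.path.join(outdir, "hypergraph.graphml"))
            with open(os.path.join(outdir, "hypergraph.json"), "w", encoding="utf-8") as fh:
                json.dump({"hypernodes": [{"id": h.id, "label": h.label,
                                           "members": sorted(h.members)}
                                          for h in hnet.hypernodes],
                           "hyperedges": [list(e) for e in hnet.hyperedges]},
                          fh, indent=2, sort_keys=True)
            manifest["stage_seeds"]["hypergraph"] = hseed
            manifest["stages"]["hypergraph"] = {"hypernodes": len(hnet.hypernodes),
                                                "hyperedges": len(hnet.hyperedges)}

    if annotation is not None and len(segments) >= 2:
        selections = []
        for degs in degsets:
            degs_set = degs.all_degs
            selections.append(greedy_select_terms(degs_set, annotation, cfg.goflow)
                              if degs_set else [])
        flow = build_flow_network(selections, annotation,
                                  [d.all_degs for d in degsets])
        with open(os.path.join(outdir, "goflow_edges.tsv"), "w", encoding="utf-8") as fh:
            fh.write("term1\tsegment1\tterm2\tsegment2\tweight\n")
            for t1, s1, t2, s2, w in flow.edges:
                fh.write(f"{t1}\t{s1}\t{t2}\t{s2}\t{w}\n")
        with open(os.path.join(outdir, "goflow_nodes.tsv"), "w", encoding="utf-8") as fh:
            fh.write("term\tsegment\tn_covered\tgenes\n")
            for term, seg, genes in flow.nodes:
                fh.write(f"{term}\t{seg}\t{len(genes)}\t{','.join(sorted(genes))}\n")
        manifest["stages"]["goflow"] = {"nodes": len(flow.nodes), "edges": len(flow.edges)}

    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
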