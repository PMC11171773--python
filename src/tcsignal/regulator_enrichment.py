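"""Upstream-regulator analysis: Fisher's exact test over pseudo activation states.

Every regulator with outgoing transcriptional edges is evaluated twice,
once as if activated and once as if repressed.  Under a pseudo-state the
sign of each regulator->target edge predicts the target's expression
direction (activated x activation -> up, activated x repression -> down,
and symmetrically for the repressed state; unknown signs match either
direction).  A 2x2 contingency table over the PKN node universe counts

    a  targets of r that are DEGs matching the predicted direction
    b  other PKN DEGs matching the predicted pattern
    c  remaining targets of r
    d  everything else (n - a - b - c)

and the one-sided Fisher exact p-value (hypergeometric upper tail,
computed in log-factorial space) scores the regulator/state call.
FDR control (Benjamini-Hochberg) runs across the doubled
regulator x state family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .expression import DEGSet
from .pkn import Edge, KnowledgeNetwork, Mechanism, Sign, mechanism_view

logger = logging.getLogger(__name__)

ACTIVATED = "activated"
REPRESSED = "repressed"
#: mechanisms defining the regulatory node universe (after virtual expansion)
UNIVERSE_MECHANISMS = {Mechanism.TRANSCRIPTIONAL, Mechanism.VIRTUAL}


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class RegulatorCall:
    regulator: str
    pseudo_state: str
    table: ContingencyTable
    p: float
    fdr: float = float("nan")
    significant: bool = False


def predicted_direction(pseudo_state: str, edge_sign: Sign) -> str:
    """Expected DEG direction of a target given regulator state and edge sign."""
    if edge_sign is Sign.UNKNOWN:
        return "either"
    positive = (pseudo_state == ACTIVATED) == (edge_sign is Sign.ACTIVATION)
    return "up" if positive else "down"


def _matches(direction: Optional[str], predicted: str) -> bool:
    if direction is None:
        return False
    return predicted == "either" or direction == predicted


def _regulator_edges(net: KnowledgeNetwork, regulator: str) -> List[Edge]:
    return net.out_edges(regulator, Mechanism.TRANSCRIPTIONAL)


def build_table(regulator: str, pseudo_state: str, degs: DEGSet,
                net: KnowledgeNetwork,
                universe: Optional[Set[str]] = None) -> ContingencyTable:
    """ABCD contingency table for one regulator under one pseudo-state.

    DEGs outside the PKN universe are discarded first.  The global
    "pattern-matching" DEG pool combines targets matching their own edge's
    prediction with non-target DEGs matching any direction the regulator's
    edge signs predict, which keeps every cell non-negative.
    """
    edges = _regulator_edges(net, regulator)
    if not edges:
        raise ValueError(f"regulator {regulator!r} has no outgoing regulatory edge")
    universe = net.node_ids() if universe is None else universe
    n = len(universe)

    by_target: Dict[str, List[Sign]] = {}
    for e in edges:
        by_target.setdefault(e.target, []).append(e.sign)
    targets = set(by_target)

    matching_targets = {
        t for t, signs in by_target.items()
        if t in universe and any(_matches(degs.direction(t), predicted_direction(pseudo_state, s))
                                 for s in signs)
    }
    global_dirs = {predicted_direction(pseudo_state, s) for signs in by_target.values() for s in signs}
    pool_nontargets = {
        g for g in (degs.all_degs & universe) - targets
        if any(_matches(degs.direction(g), d) for d in global_dirs)
    }
    a = len(matching_targets)
    b = len(pool_nontargets)
    c = len(targets & universe) - a
    d = n - a - b - c
    return ContingencyTable(a, b, c, d)


def fet_pvalue(t: ContingencyTable) -> float:
    """One-sided Fisher exact p (hypergeometric upper tail), log-factorial space.

    Sums the point probabilities of tables (a+k, b-k, c-k, d+k) for
    k = 0 .. min(b, c); every summand with a negative factorial argument
    is excluded by that bound.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    log_margins = (gammaln(a + b + 1) + gammaln(c + d + 1)
                   + gammaln(a + c + 1) + gammaln(b + d + 1) - gammaln(n + 1))
    ks = np.arange(0, min(b, c) + 1)
    log_terms = log_margins - (gammaln(a + ks + 1) + gammaln(b - ks + 1)
                               + gammaln(c - ks + 1) + gammaln(d + ks + 1))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def run_enrichment(degs: DEGSet, net: KnowledgeNetwork,
                   tf_alpha: float = 0.05) -> List[RegulatorCall]:
    """Evaluate every regulator under both pseudo-states; BH FDR over all calls."""
    view = mechanism_view(net, UNIVERSE_MECHANISMS) if any(
        e.mechanism in UNIVERSE_MECHANISMS for e in net.edges) else net
    universe = view.node_ids()
    if not (degs.all_degs & universe):
        logger.warning("no DEGs intersect the PKN universe; empty enrichment")
        return []
    regulators = sorted({e.source for e in view.edges if e.mechanism is Mechanism.TRANSCRIPTIONAL})
    calls: List[RegulatorCall] = []
    for r in regulators:
        for state in (ACTIVATED, REPRESSED):
            table = build_table(r, state, degs, view, universe)
            calls.append(RegulatorCall(r, state, table, fet_pvalue(table)))
    if calls:
        _, fdrs, _, _ = multipletests([c.p for c in calls], method="fdr_bh")
        for call, fdr in zip(calls, fdrs):
            call.fdr = float(fdr)
            call.significant = call.fdr <= tf_alpha
    calls.sort(key=lambda c: (c.p, c.regulator, c.pseudo_state))
    return calls
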