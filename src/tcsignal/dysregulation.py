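"""Primary regulatory drivers via per-edge dysregulation analysis.

For every network edge (gene *i*, gene *j*) the expression samples of the
two timepoints form two clouds of 2-D points (x_i, x_j).  Each cloud is
turned into a Gaussian-mixture density (one isotropic kernel per sample,
Silverman bandwidth per axis on the pooled points), both densities are
evaluated on a common grid, floored and renormalized, and the edge's
dysregulation score is the symmetrized Kullback-Leibler divergence

    KLD(P1, P2) = (KL(P1 || P2) + KL(P2 || P1)) / 2.

A permutation null is built by scoring random gene pairs that share no
edge; the empirical p-value of an edge is the add-one-smoothed fraction
of null scores at least as large.  Per-gene evidence is combined over
the gene's incident edges with Fisher's method, corrected for dependent
edges with Brown's method (Kost-McDermott covariance approximation on
the Pearson correlation of the partner genes' expression profiles).
Genes below ``driver_alpha`` are called primary regulatory drivers.

Because replicate counts in dense time courses are small, each timepoint
group is augmented with a pseudo-sample equal to the group mean (and,
for unreplicated data, the midpoint of the two timepoints) so that both
groups carry at least three points.  Degenerate clouds (collinear or
constant) are rotated to principal axes and jittered before density
estimation to avoid singular covariance structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .expression import ExpressionSeries, Segment
from .pkn import KnowledgeNetwork, Mechanism, mechanism_view

logger = logging.getLogger(__name__)

#: mechanisms whose edges enter the dysregulation analysis by default:
#: the gene-gene correlation layer plus the directed regulatory layer.
DRIVER_MECHANISMS = (Mechanism.CORRELATION, Mechanism.TRANSCRIPTIONAL)


@dataclass
class DriverConfig:
    mechanisms: Tuple[Mechanism, ...] = DRIVER_MECHANISMS
    null_draws: int = 10_000
    driver_alpha: float = 0.05
    bandwidth_scale: float = 1.0
    grid: str = "sample"          # "sample" (M x M sample-pair grid) or "regular"
    grid_bins: int = 40           # per axis, regular mode only
    grid_pad: float = 3.0         # pad in bandwidths, regular mode only
    density_floor: float = 1e-12
    cond_tol: float = 1e8
    jitter_eps: float = 1e-3
    seed: int = 0


@dataclass
class SampleCloud:
    """Per-edge 2-D sample clouds plus the density evaluation grid."""
    edge: Tuple[str, str]
    points1: np.ndarray  # n1 x 2
    points2: np.ndarray  # n2 x 2
    grid_x: np.ndarray   # sorted pooled coordinate values, axis i
    grid_y: np.ndarray   # sorted pooled coordinate values, axis j

    @property
    def grid(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class EdgeDysregulation:
    edge: Tuple[str, str]
    kld: float
    p: float


@dataclass
class GeneDysregulation:
    gene: str
    chi2: float
    df: float
    p: float
    n_edges: int
    is_driver: bool = False


@dataclass
class DriverResult:
    segment: Segment
    genes: List[GeneDysregulation]
    edges: List[EdgeDysregulation] = field(default_factory=list)
    null: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Sample augmentation
# ---------------------------------------------------------------------------

def augment_with_mean_group(series: ExpressionSeries, segment: Segment) -> Tuple[np.ndarray, np.ndarray]:
    """Append a per-gene mean pseudo-sample to each timepoint group.

    Returns two genes x (n+1) arrays.  With a single replicate per side the
    cross-timepoint midpoint is appended as well so both groups reach three
    points.
    """
    t1, t2 = segment
    x1 = series.matrix_for(t1)
    x2 = series.matrix_for(t2)
    m1 = x1.mean(axis=1, keepdims=True)
    m2 = x2.mean(axis=1, keepdims=True)
    a1 = np.hstack([x1, m1])
    a2 = np.hstack([x2, m2])
    if x1.shape[1] == 1 or x2.shape[1] == 1:
        mid = (m1 + m2) / 2.0
        a1 = np.hstack([a1, mid])
        a2 = np.hstack([a2, mid])
    return a1, a2


# ---------------------------------------------------------------------------
# Cloud construction and regularization
# ---------------------------------------------------------------------------

def build_cloud(edge: Tuple[str, str], xi1: np.ndarray, xj1: np.ndarray,
                xi2: np.ndarray, xj2: np.ndarray) -> SampleCloud:
    p1 = np.column_stack([xi1, xj1])
    p2 = np.column_stack([xi2, xj2])
    pooled = np.vstack([p1, p2])
    return SampleCloud(edge, p1, p2,
                       grid_x=np.sort(pooled[:, 0]), grid_y=np.sort(pooled[:, 1]))


def regularize_cloud(cloud: SampleCloud, cond_tol: float = 1e8,
                     jitter_eps: float = 1e-3,
                     rng: Optional[np.random.Generator] = None) -> SampleCloud:
    """Rotate to principal axes and jitter degenerate directions.

    Applied when the pooled 2x2 covariance is rank-deficient or has a
    condition number above *cond_tol*; well-conditioned clouds pass through
    unchanged.  Jitter is ``jitter_eps * sigma_max`` Gaussian noise on the
    degenerate axis (both axes when all points coincide), seeded.
    """
    pooled = np.vstack([cloud.points1, cloud.points2])
    cov = np.cov(pooled, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    lam_min, lam_max = float(evals[0]), float(evals[1])
    if lam_max > 0 and lam_min > 0 and lam_max / lam_min <= cond_tol:
        return cloud
    rng = np.random.default_rng(0) if rng is None else rng
    p1 = cloud.points1 @ evecs
    p2 = cloud.points2 @ evecs
    sigma_max = math.sqrt(lam_max) if lam_max > 0 else 1.0
    scale = jitter_eps * sigma_max
    n1 = len(p1)
    if lam_max <= 0:  # every point identical in both coordinates
        noise = rng.normal(0.0, scale, size=(n1 + len(p2), 2))
        p1 = p1 + noise[:n1]
        p2 = p2 + noise[n1:]
    else:
        # eigh returns ascending eigenvalues: axis 0 is the degenerate one
        noise = rng.normal(0.0, scale, size=n1 + len(p2))
        p1 = p1.copy()
        p2 = p2.copy()
        p1[:, 0] += noise[:n1]
        p2[:, 0] += noise[n1:]
    pooled = np.vstack([p1, p2])
    return SampleCloud(cloud.edge, p1, p2,
                       grid_x=np.sort(pooled[:, 0]), grid_y=np.sort(pooled[:, 1]))


# ---------------------------------------------------------------------------
# Kernel density and KLD
# ---------------------------------------------------------------------------

def _silverman(values: np.ndarray) -> float:
    n = len(values)
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.349) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread <= 0:
        spread = max(abs(float(values.mean())), 1.0) * 1e-6
    return 0.9 * spread * n ** (-0.2)


def _axis_density(grid: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    """len(grid) x len(centers) Gaussian kernel matrix along one axis."""
    z = (grid[:, None] - centers[None, :]) / h
    return np.exp(-0.5 * z * z) / (h * math.sqrt(2.0 * math.pi))


def _mixture_on_grid(points: np.ndarray, gx: np.ndarray, gy: np.ndarray,
                     hx: float, hy: float) -> np.ndarray:
    # separable kernels on a Cartesian grid: density = Ax @ Ay.T / n
    ax = _axis_density(gx, points[:, 0], hx)
    ay = _axis_density(gy, points[:, 1], hy)
    return (ax @ ay.T) / len(points)


def _floor_normalize(d: np.ndarray, floor: float) -> np.ndarray:
    d = np.maximum(d, floor)
    return d / d.sum()


def edge_kld(cloud: SampleCloud, bandwidth_scale: float = 1.0,
             density_floor: float = 1e-12) -> float:
    """Symmetrized KLD between the two timepoint densities on the cloud grid."""
    pooled = np.vstack([cloud.points1, cloud.points2])
    hx = _silverman(pooled[:, 0]) * bandwidth_scale
    hy = _silverman(pooled[:, 1]) * bandwidth_scale
    d1 = _floor_normalize(_mixture_on_grid(cloud.points1, cloud.grid_x, cloud.grid_y, hx, hy),
                          density_floor)
    d2 = _floor_normalize(_mixture_on_grid(cloud.points2, cloud.grid_x, cloud.grid_y, hx, hy),
                          density_floor)
    log_ratio = np.log(d1) - np.log(d2)
    kl_12 = float((d1 * log_ratio).sum())
    kl_21 = float((d2 * -log_ratio).sum())
    return (kl_12 + kl_21) / 2.0


def _regular_grid(pooled: np.ndarray, hx: float, hy: float,
                  bins: int, pad: float) -> Tuple[np.ndarray, np.ndarray]:
    gx = np.linspace(pooled[:, 0].min() - pad * hx, pooled[:, 0].max() + pad * hx, bins)
    gy = np.linspace(pooled[:, 1].min() - pad * hy, pooled[:, 1].max() + pad * hy, bins)
    return gx, gy


def _kld_pair(xi1, xj1, xi2, xj2, cfg: DriverConfig,
              rng: Optional[np.random.Generator] = None) -> float:
    cloud = build_cloud(("", ""), xi1, xj1, xi2, xj2)
    cloud = regularize_cloud(cloud, cfg.cond_tol, cfg.jitter_eps, rng)
    if cfg.grid == "regular":
        pooled = np.vstack([cloud.points1, cloud.points2])
        hx = _silverman(pooled[:, 0]) * cfg.bandwidth_scale
        hy = _silverman(pooled[:, 1]) * cfg.bandwidth_scale
        gx, gy = _regular_grid(pooled, hx, hy, cfg.grid_bins, cfg.grid_pad)
        cloud = SampleCloud(cloud.edge, cloud.points1, cloud.points2, gx, gy)
    return edge_kld(cloud, cfg.bandwidth_scale, cfg.density_floor)


# ---------------------------------------------------------------------------
# Permutation null and empirical p
# ---------------------------------------------------------------------------

def _view_pairs(net: KnowledgeNetwork, mechanisms: Sequence[Mechanism],
                expressed: Set[str]) -> List[Tuple[str, str]]:
    """Unique unordered expressed gene pairs joined by an edge in the view."""
    view = mechanism_view(net, set(mechanisms))
    pairs = {e.pair() for e in view.edges
             if e.source in expressed and e.target in expressed and e.source != e.target}
    return sorted(pairs)


def null_kld_distribution(series: ExpressionSeries, segment: Segment,
                          net: KnowledgeNetwork, n_draws: int = 10_000,
                          seed: int = 0,
                          config: Optional[DriverConfig] = None) -> np.ndarray:
    """KLD scores of *n_draws* random non-adjacent gene pairs (the null model)."""
    cfg = config or DriverConfig()
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    expressed = set(series.genes)
    genes = sorted(expressed & net.node_ids())
    if len(genes) < 2:
        raise ValueError("need >=2 expressed network genes for the null")
    edge_pairs = set(_view_pairs(net, cfg.mechanisms, expressed))
    n = len(genes)
    n_admissible = n * (n - 1) // 2 - len(edge_pairs)
    if n_admissible <= 0:
        raise ValueError("no null pairs: every expressed gene pair shares an edge")
    if n_admissible < n_draws:
        logger.warning("only %d admissible null pairs for %d draws; sampling with replacement",
                       n_admissible, n_draws)
    rng = np.random.default_rng(seed)
    a1, a2 = augment_with_mean_group(series, segment)
    rows = {g: series.gene_row(g) for g in genes}
    out = np.empty(n_draws)
    k = 0
    while k < n_draws:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        gi, gj = genes[i], genes[j]
        pair = (gi, gj) if gi <= gj else (gj, gi)
        if pair in edge_pairs:
            continue
        ri, rj = rows[gi], rows[gj]
        out[k] = _kld_pair(a1[ri], a1[rj], a2[ri], a2[rj], cfg, rng)
        k += 1
    return out


def empirical_pvalue(observed: float, null: Sequence[float]) -> float:
    """Add-one-smoothed permutation p: (1 + #{null >= observed}) / (1 + |null|)."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + int((null >= observed).sum())) / (1 + null.size))


# ---------------------------------------------------------------------------
# Fisher / Brown aggregation
# ---------------------------------------------------------------------------

def _kost_mcdermott(rho: float) -> float:
    """Polynomial approximation of cov(-2 ln p_i, -2 ln p_j) from Pearson rho."""
    rho = float(np.clip(rho, -1.0, 1.0))
    cov = 3.263 * rho + 0.710 * rho ** 2 + 0.027 * rho ** 3
    return float(np.clip(cov, -4.0, 4.0))  # |cov| bounded by the chi2_2 variance


def aggregate_gene(gene: str, edge_results: Sequence[EdgeDysregulation],
                   correlations: Optional[np.ndarray] = None) -> GeneDysregulation:
    """Combine a gene's edge p-values with Fisher's method + Brown's correction.

    *correlations* is the k x k Pearson correlation matrix of the partner
    genes' expression profiles (k = number of edges); omitted or all-zero
    off-diagonals reduce the statistic to plain Fisher with df = 2k.
    """
    if not edge_results:
        raise ValueError("aggregate_gene needs >=1 edge result")
    pvals = np.array([e.p for e in edge_results])
    if (pvals <= 0).any():
        raise ValueError("edge p-values must be > 0")
    k = len(pvals)
    chi2 = float((-2.0 * np.log(pvals)).sum())
    mean = 2.0 * k
    var = 4.0 * k
    if correlations is not None and k > 1:
        corr = np.asarray(correlations, dtype=float)
        for i in range(k):
            for j in range(i + 1, k):
                var += 2.0 * _kost_mcdermott(corr[i, j])
    var = max(var, 1e-9)
    c = var / (2.0 * mean)
    df = 2.0 * mean ** 2 / var
    p = float(stats.chi2.sf(chi2 / c, df))
    return GeneDysregulation(gene, chi2, df, max(p, np.finfo(float).tiny), k)


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def run_driver_analysis(series: ExpressionSeries, segment: Segment,
                        net: KnowledgeNetwork,
                        config: Optional[DriverConfig] = None,
                        null: Optional[np.ndarray] = None) -> DriverResult:
    """Score every edge of the selected view, aggregate per gene, rank by p.

    A precomputed *null* vector may be supplied (e.g. shared across edge
    scans); otherwise one is drawn with ``config.null_draws`` pairs.
    """
    cfg = config or DriverConfig()
    expressed = set(series.genes)
    pairs = _view_pairs(net, cfg.mechanisms, expressed)
    if not pairs:
        logger.warning("segment %s: no expressed edge endpoints in the selected view", segment)
        return DriverResult(segment, [], [], None)

    if null is None:
        null = null_kld_distribution(series, segment, net, cfg.null_draws, cfg.seed, cfg)

    a1, a2 = augment_with_mean_group(series, segment)
    rng = np.random.default_rng(cfg.seed + 1)
    edge_results: List[EdgeDysregulation] = []
    incident: Dict[str, List[int]] = {}
    for idx, (gi, gj) in enumerate(pairs):
        ri, rj = series.gene_row(gi), series.gene_row(gj)
        kld = _kld_pair(a1[ri], a1[rj], a2[ri], a2[rj], cfg, rng)
        edge_results.append(EdgeDysregulation((gi, gj), kld, empirical_pvalue(kld, null)))
        incident.setdefault(gi, []).append(idx)
        incident.setdefault(gj, []).append(idx)

    # partner-profile correlations estimated across the full series: the
    # few samples inside one segment would make the Brown covariance
    # estimate dominated by sampling noise
    raw = series.values
    genes_out: List[GeneDysregulation] = []
    for gene in sorted(incident):
        idxs = incident[gene]
        results = [edge_results[i] for i in idxs]
        partners = [r.edge[0] if r.edge[1] == gene else r.edge[1] for r in results]
        corr = None
        if len(partners) > 1:
            prof = raw[[series.gene_row(p) for p in partners]]
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(prof)
            corr = np.nan_to_num(corr, nan=0.0)
        g = aggregate_gene(gene, results, corr)
        g.is_driver = g.p <= cfg.driver_alpha
        genes_out.append(g)
    genes_out.sort(key=lambda g: (g.p, g.gene))
    return DriverResult(segment, genes_out, edge_results, null)
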