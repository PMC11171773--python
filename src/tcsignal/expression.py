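"""Time-series expression I/O, normalization and DEG calling.

Expression is a genes x samples matrix of log2 intensities with a
sample -> timepoint grouping.  Differential expression between two
adjacent timepoints (a *segment*) uses a per-gene Welch t-test with
Benjamini-Hochberg FDR control; defaults FDR <= 0.1 and fold change
>= 1.5, threshold comparisons inclusive.  When a side has fewer than
two replicates the t-test is undefined and fold-change-only mode
engages (p and FDR are reported as NaN).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.1
DEFAULT_FC = 1.5

Segment = Tuple[str, str]


def _timepoint_key(label: str):
    m = re.search(r"(\d+)$", label)
    return (0, int(m.group(1))) if m else (1, label)


@dataclass
class ExpressionSeries:
    genes: List[str]
    samples: List[str]
    values: np.ndarray  # genes x samples, log2
    sample_groups: Dict[str, str]  # sample -> timepoint
    timepoints: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timepoints:
            self.timepoints = sorted(set(self.sample_groups.values()), key=_timepoint_key)
        missing = [s for s in self.samples if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a timepoint group: {missing}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def columns_for(self, timepoint: str) -> List[int]:
        cols = [i for i, s in enumerate(self.samples) if self.sample_groups[s] == timepoint]
        if not cols:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        return cols

    def matrix_for(self, timepoint: str) -> np.ndarray:
        return self.values[:, self.columns_for(timepoint)]

    def gene_row(self, gene: str) -> int:
        return self._gene_index[gene]

    def segments(self) -> List[Segment]:
        return list(zip(self.timepoints[:-1], self.timepoints[1:]))


@dataclass
class DEGSet:
    segment: Segment
    up: set
    down: set
    stats: pd.DataFrame  # index gene; columns log2fc, p, fdr

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def all_degs(self) -> set:
        return self.up | self.down

    def direction(self, gene: str) -> Optional[str]:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return None


def read_expression(path: str, group_map: str) -> ExpressionSeries:
    """Load a genes x samples TSV plus a sample -> timepoint TSV map."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated gene ids: {dupes}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
    groups_df = pd.read_csv(group_map, sep="\t", header=None, names=["sample", "timepoint"],
                            dtype=str, comment="#")
    if str(groups_df.iloc[0, 0]).lower() == "sample":  # tolerate a header row
        groups_df = groups_df.iloc[1:]
    groups = dict(zip(groups_df["sample"], groups_df["timepoint"]))
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValueError(f"group map missing samples: {missing}")
    return ExpressionSeries(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        sample_groups={s: groups[s] for s in df.columns},
    )


def write_expression(series: ExpressionSeries, path: str, group_path: str) -> None:
    df = pd.DataFrame(series.values, index=series.genes, columns=series.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    with open(group_path, "w", encoding="utf-8") as fh:
        for s in series.samples:
            fh.write(f"{s}\t{series.sample_groups[s]}\n")


def normalize_global_mean(series: ExpressionSeries, target: float = 10.0) -> ExpressionSeries:
    """Additively shift the whole matrix so its grand mean equals *target*.

    The shift preserves every pairwise difference exactly, so fold changes
    and t statistics are invariant under this normalization.
    """
    if series.values.size == 0:
        raise ValueError("empty series")
    shift = target - float(series.values.mean())
    return ExpressionSeries(series.genes, series.samples, series.values + shift,
                            dict(series.sample_groups), list(series.timepoints))


def call_degs(series: ExpressionSeries, segment: Segment,
              fdr_threshold: float = DEFAULT_FDR,
              fc_threshold: float = DEFAULT_FC) -> DEGSet:
    """Welch t + BH DEGs between the two timepoints of *segment* (inclusive thresholds)."""
    t1, t2 = segment
    x1 = series.matrix_for(t1)
    x2 = series.matrix_for(t2)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    lfc_cut = np.log2(fc_threshold)

    if x1.shape[1] >= 2 and x2.shape[1] >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        passes = fdr <= fdr_threshold
    else:
        logger.warning("segment %s: <2 replicates on a side; fold-change-only mode", segment)
        p = np.full(len(series.genes), np.nan)
        fdr = np.full(len(series.genes), np.nan)
        passes = np.ones(len(series.genes), dtype=bool)

    up = {g for g, l, ok in zip(series.genes, log2fc, passes) if ok and l >= lfc_cut}
    down = {g for g, l, ok in zip(series.genes, log2fc, passes) if ok and l <= -lfc_cut}
    table = pd.DataFrame({"log2fc": log2fc, "p": p, "fdr": fdr}, index=series.genes)
    return DEGSet(segment, up, down, table)
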