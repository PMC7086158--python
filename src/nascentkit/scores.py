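"""Per-gene splicing and termination scores and their summaries.

The splicing score of a gene in a sample is

    spliced_norm / pre_mrna,      pre_mrna = intronic_norm + exon_intron

where ``spliced_norm`` is the exon-count-normalized junction-read count and
``intronic_norm`` the intron-length-normalized intronic count (both already
library-scaled). The termination score is

    (tes + tes_rt) / pre_mrna

with the same denominator: reads downstream of the TES relative to pre-mRNA
evidence. Both scores are undefined (NaN, excluded downstream) when the gene
has no pre-mRNA reads in that sample; replicate means are taken over defined
entries only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classify import NormalizedCounts, ReadCategoryCounts, CATEGORIES

#: kernel bandwidth used for score density summaries
DEFAULT_BANDWIDTH = 0.3
#: genes with mean raw read count below this across samples are dropped
EXPRESSION_THRESHOLD = 1.0
#: Signal2Noise floors each group sd at this fraction of |group mean|
SD_FLOOR = 0.2


def score_table(
    norm: NormalizedCounts,
    conditions: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per (gene, sample) splicing and termination scores with components.

    Returns a frame with columns ``condition`` (when a sample->condition map
    is given), ``spliced``, ``pre_mrna``, ``tes``, ``tes_rt``,
    ``splicing_score`` and ``termination_score``. Scores are NaN where
    ``pre_mrna`` is zero or undefined.
    """
    t = norm.table
    out = pd.DataFrame(index=t.index)
    if conditions is not None:
        out["condition"] = [
            conditions[s] for s in t.index.get_level_values("sample")
        ]
    out["spliced"] = t["spliced"]
    out["pre_mrna"] = t["intronic"] + t["exon_intron"]
    out["tes"] = t["tes"]
    out["tes_rt"] = t["tes_rt"]
    denom = out["pre_mrna"].where(out["pre_mrna"] > 0)
    out["splicing_score"] = out["spliced"] / denom
    out["termination_score"] = (out["tes"] + out["tes_rt"]) / denom
    return out


def condition_means(
    table: pd.DataFrame,
    columns: Sequence[str] = ("splicing_score", "termination_score"),
) -> pd.DataFrame:
    """Replicate means per gene x condition, skipping undefined entries."""
    if "condition" not in table.columns:
        raise ValueError("score table lacks a 'condition' column")
    return (
        table.groupby([pd.Grouper(level="gene_id"), table["condition"]])[
            list(columns)
        ].mean()
    )


def filter_expressed(
    counts: ReadCategoryCounts, threshold: float = EXPRESSION_THRESHOLD
) -> pd.Index:
    """Genes whose mean per-sample read count is >= threshold.

    The per-sample count of a gene is its total over the six categories; a
    mean strictly below the threshold drops the gene (the boundary is kept).
    """
    totals = counts.gene_totals().unstack("sample")
    mean = totals.mean(axis=1)
    return mean.index[mean >= threshold]


@dataclass
class DensitySummary:
    """A Gaussian kernel density of (log) scores over an evaluation grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    log10: bool

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def density_summary(
    values: Sequence[float] | np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
    log10: bool = True,
    n_grid: int = 512,
    cut: float = 3.0,
) -> DensitySummary:
    """Kernel density of scores with a fixed bandwidth.

    NaNs are dropped; with ``log10`` (the default) non-positive scores are
    dropped too and the density is computed on log10 values — genes without
    spliced reads are thereby removed before a splicing-score density. The
    grid extends ``cut`` bandwidths beyond the data range. Fewer than two
    usable values is an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if log10:
        x = x[x > 0]
        x = np.log10(x)
    if x.size < 2:
        raise ValueError(f"need at least 2 usable values, got {x.size}")
    lo, hi = x.min() - cut * bandwidth, x.max() + cut * bandwidth
    grid = np.linspace(lo, hi, n_grid)
    dens = norm.pdf(grid[:, None], loc=x[None, :], scale=bandwidth).mean(axis=1)
    return DensitySummary(
        grid=grid, density=dens, bandwidth=bandwidth, n=int(x.size), log10=log10
    )


def signal2noise(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    sd_floor: float = SD_FLOOR,
) -> pd.DataFrame:
    """Signal2Noise statistic per gene between two replicate groups.

    ``matrix`` is genes x replicate columns (e.g. per-replicate splicing
    scores). s2n = (mean_A - mean_B) / (sd_A + sd_B) with each sd floored at
    ``sd_floor * |its group mean|`` (and at ``sd_floor`` when the mean is 0),
    the convention of the ranked-list enrichment tool this feeds. Genes with
    any undefined replicate value are dropped. The result is sorted by
    descending s2n with gene id as the tie-break.
    """
    cols = list(group_a) + list(group_b)
    m = matrix[cols].dropna()
    a = m[list(group_a)].to_numpy(dtype=float)
    b = m[list(group_b)].to_numpy(dtype=float)

    def _stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        floor = sd_floor * np.abs(mean)
        floor = np.where(floor == 0, sd_floor, floor)
        return mean, np.maximum(sd, floor)

    mean_a, sd_a = _stats(a)
    mean_b, sd_b = _stats(b)
    out = pd.DataFrame(
        {"s2n": (mean_a - mean_b) / (sd_a + sd_b)}, index=m.index
    )
    # stable sort after an index sort: ties break on gene id, deterministically
    out = out.sort_index().sort_values("s2n", ascending=False, kind="mergesort")
    return out


def write_rnk(ranked: pd.DataFrame, path) -> None:
    """Write a ranked gene list in the two-column .rnk format."""
    with open(path, "w") as fh:
        for gid, row in ranked.iterrows():
            fh.write(f"{gid}\t{row['s2n']:.10g}\n")
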