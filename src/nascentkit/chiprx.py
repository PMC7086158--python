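"""Spike-in-normalized ChIP analysis.

ChIP-RX adds a fixed amount of foreign-genome chromatin to every sample, so
that global occupancy changes — invisible to library-size normalization —
can be recovered. Reads are mapped separately to the primary and spike-in
genomes; the per-sample normalization factor

    rx_factor_s = min_j(spikein_j) / spikein_s

equalizes spike-in totals across samples. Applying it to coverage tracks and
metagene profiles makes a genuine global 2x signal loss appear as a 2x drop,
whereas scaling by primary-library size would mask it.

The module also annotates peaks to promoters (nearest TSS, flagged when the
summit lies within TSS +/- 1 kb), defines promoter-proximal pause sites from
RNAPII peaks (input-overlapping peaks removed, survivors with a summit in
TSS to TSS+250 bp kept, strand-aware), and computes anchored metagene
profiles with per-position mean and SEM across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import DerivedRegions

#: promoter half-width used for peak annotation (bp)
PROMOTER_HALFWIDTH = 1_000
#: pause window extent downstream of the TSS (bp)
PAUSE_EXTENT = 250


def rx_factors(accounting: pd.DataFrame) -> pd.Series:
    """Per-sample spike-in normalization factors.

    ``accounting`` needs columns ``sample``, ``primary_mapped`` and
    ``spikein_mapped`` (or a ``sample`` index). Factors are
    ``min(spikein) / spikein_s``: the sample with the fewest spike-in reads
    gets factor 1 and scaled spike-in totals are equal across samples.
    """
    acc = accounting.set_index("sample") if "sample" in accounting.columns else accounting
    spike = acc["spikein_mapped"].astype(float)
    if (spike <= 0).any() or (acc["primary_mapped"] <= 0).any():
        raise ValueError("read counts must be positive for every sample")
    return spike.min() / spike


def library_size_factors(accounting: pd.DataFrame) -> pd.Series:
    """Naive factors from primary-genome totals (the RX counter-example)."""
    acc = accounting.set_index("sample") if "sample" in accounting.columns else accounting
    primary = acc["primary_mapped"].astype(float)
    if (primary <= 0).any():
        raise ValueError("read counts must be positive for every sample")
    return primary.min() / primary


def _tss_table(genes: Iterable[DerivedRegions]) -> pd.DataFrame:
    rows = [
        {"gene_id": dr.gene_id, "chrom": dr.chrom, "tss": dr.tss, "strand": dr.strand}
        for dr in genes
    ]
    return pd.DataFrame(rows).sort_values(["chrom", "tss", "gene_id"])


def annotate_peaks_to_promoters(
    peaks: pd.DataFrame,
    genes: Iterable[DerivedRegions],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> pd.DataFrame:
    """Assign each peak to its nearest TSS and flag promoter proximity.

    ``peaks`` needs ``chrom`` and ``summit`` columns (see
    :func:`nascentkit.io.read_narrowpeak`). The returned copy gains
    ``gene_id``, ``tss_distance`` (signed, summit - TSS) and ``promoter``
    (|distance| <= halfwidth). Peaks on contigs without genes get no
    assignment. Equidistant TSS ties break on gene id.
    """
    tss = _tss_table(genes)
    out = peaks.copy()
    out["gene_id"] = pd.NA
    out["tss_distance"] = np.nan
    out["promoter"] = False
    for chrom, sub in out.groupby("chrom"):
        t = tss[tss["chrom"] == chrom]
        if t.empty:
            continue
        pos = t["tss"].to_numpy()
        gids = t["gene_id"].to_numpy()
        for i, summit in sub["summit"].items():
            d = np.abs(pos - summit)
            best = np.flatnonzero(d == d.min())
            j = best[np.argsort(gids[best])[0]] if len(best) > 1 else best[0]
            out.at[i, "gene_id"] = gids[j]
            out.at[i, "tss_distance"] = float(summit - pos[j])
    out["promoter"] = out["tss_distance"].abs() <= promoter_halfwidth
    out.loc[out["gene_id"].isna(), "promoter"] = False
    return out


def _any_overlap(peak_row, other: pd.DataFrame) -> bool:
    sub = other[other["chrom"] == peak_row["chrom"]]
    return bool(
        ((sub["start"] < peak_row["end"]) & (peak_row["start"] < sub["end"])).any()
    )


def define_pause_sites(
    rnapii_peaks: pd.DataFrame,
    input_peaks: pd.DataFrame,
    genes: Iterable[DerivedRegions],
    pause_extent: int = PAUSE_EXTENT,
) -> pd.DataFrame:
    """Promoter-proximal pause anchors from RNAPII peaks.

    RNAPII peaks overlapping any input peak (>= 1 bp) are discarded;
    survivors are annotated to their nearest TSS and kept when the summit
    falls within the strand-aware pause window [TSS, TSS + pause_extent).
    Returns one row per pause anchor: gene_id, chrom, summit, strand.
    """
    genes = list(genes)
    kept = rnapii_peaks[
        ~rnapii_peaks.apply(lambda row: _any_overlap(row, input_peaks), axis=1)
    ]
    if kept.empty:
        return pd.DataFrame(columns=["gene_id", "chrom", "summit", "strand"])
    annotated = annotate_peaks_to_promoters(kept, genes)
    windows = {dr.gene_id: (dr.pause_window, dr.strand) for dr in genes}
    rows = []
    for _, row in annotated.iterrows():
        gid = row["gene_id"]
        if pd.isna(gid):
            continue
        (lo, hi), strand = windows[gid]
        if lo <= row["summit"] < hi:
            rows.append(
                {
                    "gene_id": gid,
                    "chrom": row["chrom"],
                    "summit": int(row["summit"]),
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "summit", "strand"])


@dataclass
class MetageneProfile:
    """Mean +/- SEM coverage around aligned anchors."""

    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def total(self) -> float:
        return float(self.mean.sum())


def extract_profile(
    cov: np.ndarray, pos: int, strand: str, lo: int, hi: int
) -> np.ndarray:
    """Strand-aware coverage vector at offsets [lo, hi) around ``pos``.

    Offsets count in the direction of transcription; positions outside the
    contig contribute zero.
    """
    if strand == "+":
        idx = np.arange(pos + lo, pos + hi)
    else:
        idx = np.arange(pos - lo, pos - hi, -1)
    out = np.zeros(hi - lo, dtype=float)
    valid = (idx >= 0) & (idx < len(cov))
    out[valid] = cov[idx[valid]]
    return out


def profile_matrix(
    coverage: Mapping[str, np.ndarray],
    anchors: Sequence[tuple[str, int, str]],
    window: tuple[int, int] = (-1000, 1000),
) -> np.ndarray:
    """Anchor x offset coverage matrix (rows in anchor order)."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    rows = []
    for chrom, pos, strand in anchors:
        cov = coverage.get(chrom)
        if cov is None:
            rows.append(np.zeros(hi - lo))
        else:
            rows.append(extract_profile(cov, pos, strand, lo, hi))
    return np.asarray(rows)


def metagene(
    coverage: Mapping[str, np.ndarray],
    anchors: Sequence[tuple[str, int, str]],
    window: tuple[int, int] = (-1000, 1000),
    scale: float = 1.0,
) -> MetageneProfile:
    """Average coverage profile around anchors, scaled (e.g. by an RX factor).

    Per-position SEM is the standard deviation across anchors over sqrt(n);
    it is zero when all extracted vectors are identical or when n == 1.
    """
    if not anchors:
        raise ValueError("no anchors given")
    mat = profile_matrix(coverage, anchors, window) * scale
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
    lo, hi = window
    return MetageneProfile(offsets=np.arange(lo, hi), mean=mean, sem=sem, n=n)


def track_difference(
    track_a: Mapping[str, np.ndarray], track_b: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Signed per-position difference a - b of (already normalized) tracks."""
    out: dict[str, np.ndarray] = {}
    for chrom in set(track_a) | set(track_b):
        a = np.asarray(track_a.get(chrom, ()), dtype=float)
        b = np.asarray(track_b.get(chrom, ()), dtype=float)
        n = max(a.size, b.size)
        diff = np.zeros(n)
        diff[: a.size] += a
        diff[: b.size] -= b
        out[chrom] = diff
    return out
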