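"""AP-MS enrichment and differential phosphoproteomics statistics.

The enrichment caller reproduces the binned-boxplot scheme used for
co-immunoprecipitation screens: missing control intensities are imputed from
a narrow normal distribution near the detection floor, mean log2 bait/control
ratios are computed per protein, proteins are partitioned into consecutive
abundance bins of at least 300, and within each bin ratios beyond 1.5x IQR
(potential) or 3x IQR (extreme) of the quartiles are called enriched.

The differential test is the SAM-style moderated two-sample t-test
t_s0 = (mean_A - mean_B) / (SE + s0) with a permutation-based FDR: the null
tail is pooled over balanced group-label permutations, q-values are the
step-up-monotone ratio of expected false positives to observed positives at
each cut, and sites are flagged at q <= FDR (1% by default, s0 = 0.1).

Set-overlap significance between two protein lists from a stated universe is
the upper-tail hypergeometric probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil, comb
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ColumnMap:
    """Column names in a search-engine export table (MaxQuant-style)."""

    id: str = "id"
    score: str = "Score"
    localization_prob: str = "Localization prob"
    pep: str = "PEP"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    razor_unique: str = "Razor + unique peptides"


@dataclass(frozen=True)
class FilterThresholds:
    """Row-quality thresholds; a row failing any present criterion is dropped.

    Boundary conventions: identification score must be >= min_score (rows
    with score < 40 are removed), localization probability must be strictly
    > min_localization_prob (<= 0.75 removed), posterior error probability
    strictly < max_pep (>= 0.05 removed), razor/unique peptides >= min_razor.
    """

    min_score: float = 40.0
    min_localization_prob: float = 0.75
    max_pep: float = 0.05
    min_razor_unique: int = 2


def _flagged(col: pd.Series) -> pd.Series:
    return col.fillna("").astype(str).str.strip().isin(("+", "True", "true", "1"))


def _valid(values: pd.DataFrame, zero_is_missing: bool) -> pd.DataFrame:
    ok = values.notna()
    if zero_is_missing:
        ok &= values != 0
    return ok


def filter_rows(
    table: pd.DataFrame,
    columns: ColumnMap = ColumnMap(),
    thresholds: FilterThresholds = FilterThresholds(),
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    min_valid: Optional[int] = None,
    zero_is_missing: bool = True,
) -> pd.DataFrame:
    """Apply quality filters; criteria whose column is absent are skipped.

    ``groups`` maps group names to intensity columns; a row is kept only if
    at least one group has ``min_valid`` quantified values (all of them when
    ``min_valid`` is None — the "all valid values in at least one group"
    rule). The retained set is independent of criterion order.
    """
    keep = pd.Series(True, index=table.index)
    c, t = columns, thresholds
    if c.reverse in table.columns:
        keep &= ~_flagged(table[c.reverse])
    if c.contaminant in table.columns:
        keep &= ~_flagged(table[c.contaminant])
    if c.score in table.columns:
        keep &= table[c.score] >= t.min_score
    if c.localization_prob in table.columns:
        keep &= table[c.localization_prob] > t.min_localization_prob
    if c.pep in table.columns:
        keep &= table[c.pep] < t.max_pep
    if c.razor_unique in table.columns:
        keep &= table[c.razor_unique] >= t.min_razor_unique
    if groups:
        any_group = pd.Series(False, index=table.index)
        for cols in groups.values():
            need = len(cols) if min_valid is None else min_valid
            any_group |= (
                _valid(table[list(cols)], zero_is_missing).sum(axis=1) >= need
            )
        keep &= any_group
    return table[keep].copy()


def impute_missing(
    table: pd.DataFrame,
    impute_columns: Sequence[str],
    quantile_columns: Optional[Sequence[str]] = None,
    q: float = 0.05,
    sd: float = 0.1,
    seed: int | np.random.Generator = 0,
    zero_is_missing: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing intensities near the detection floor.

    Each missing cell in ``impute_columns`` draws a log10 intensity from
    Normal(q05, sd) where q05 is the 5% quantile of the combined observed
    log10 intensities over ``quantile_columns`` (default: the impute
    columns). Observed values are never overwritten; the same seed gives a
    bit-identical table. Returns ``(imputed_table, mask)`` with the mask True
    exactly at imputed cells.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    qcols = list(quantile_columns) if quantile_columns is not None else list(impute_columns)
    observed = table[qcols].to_numpy(dtype=float).ravel()
    if zero_is_missing:
        observed = observed[observed != 0]
    observed = observed[np.isfinite(observed)]
    if observed.size == 0:
        raise ValueError("no observed intensities to anchor the imputation")
    if (observed <= 0).any():
        raise ValueError("intensities must be positive for log10 imputation")
    q05 = np.quantile(np.log10(observed), q)
    out = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=list(impute_columns))
    for col in impute_columns:
        vals = out[col].astype(float)
        missing = ~_valid(vals.to_frame(), zero_is_missing)[col]
        draws = 10.0 ** rng.normal(q05, sd, size=int(missing.sum()))
        vals.loc[missing] = draws
        out[col] = vals
        mask[col] = missing
    return out, mask


@dataclass
class BinnedIqrParams:
    """Knobs of the binned-boxplot enrichment caller."""

    min_bin: int = 300
    k_potential: float = 1.5
    k_extreme: float = 3.0
    strict: bool = True  # a ratio exactly on the fence is NOT an outlier


def binned_iqr_outliers(
    table: pd.DataFrame,
    bait_columns: Sequence[str],
    control_columns: Sequence[str],
    id_column: Optional[str] = None,
    params: BinnedIqrParams = BinnedIqrParams(),
) -> pd.DataFrame:
    """Boxplot-outlier enrichment calls in abundance bins.

    ``bait_columns`` and ``control_columns`` pair replicate experiments
    position-wise. Per protein the mean log2(bait/control) ratio over pairs
    and the mean log10 intensity over all columns are computed; proteins are
    sorted by abundance and split into consecutive bins of
    ceil(n / floor(n / min_bin)) rows, each >= min_bin (a single bin, with a
    warning, when n < min_bin). Within each bin, ratios outside
    Q3 + k*IQR / Q1 - k*IQR are flagged ``potential`` (k=1.5) or ``extreme``
    (k=3); the fences themselves are not outliers. ``enriched`` marks
    upper-tail (bait-enriched) calls.
    """
    if len(bait_columns) != len(control_columns):
        raise ValueError("bait and control column lists must pair replicates")
    bait = table[list(bait_columns)].to_numpy(dtype=float)
    ctrl = table[list(control_columns)].to_numpy(dtype=float)
    if (bait <= 0).any() or (ctrl <= 0).any():
        raise ValueError("intensities must be positive (impute first)")
    log2_ratio = np.log2(bait / ctrl).mean(axis=1)
    intensity = np.log10(
        np.concatenate([bait, ctrl], axis=1)
    ).mean(axis=1)
    n = len(table)
    if n == 0:
        raise ValueError("empty table")
    if n < params.min_bin:
        warnings.warn(
            f"{n} rows < min_bin={params.min_bin}; using a single bin"
        )
        n_bins = 1
    else:
        n_bins = n // params.min_bin
    size = ceil(n / n_bins)

    ids = (
        table[id_column].to_numpy()
        if id_column is not None
        else table.index.to_numpy()
    )
    order = np.argsort(-intensity, kind="stable")
    bin_of = np.empty(n, dtype=int)
    status = np.full(n, "none", dtype=object)
    direction = np.full(n, ".", dtype=object)
    for b in range(n_bins):
        members = order[b * size : (b + 1) * size]
        bin_of[members] = b
        ratios = log2_ratio[members]
        q1, q3 = np.percentile(ratios, [25, 75])
        iqr = q3 - q1
        for k, label in (
            (params.k_potential, "potential"),
            (params.k_extreme, "extreme"),
        ):
            if params.strict:
                up = ratios > q3 + k * iqr
                down = ratios < q1 - k * iqr
            else:
                up = ratios >= q3 + k * iqr
                down = ratios <= q1 - k * iqr
            status[members[up | down]] = label
            direction[members[up]] = "up"
            direction[members[down]] = "down"
    out = pd.DataFrame(
        {
            "protein_id": ids,
            "mean_log2_ratio": log2_ratio,
            "mean_log10_intensity": intensity,
            "bin": bin_of,
            "status": status,
            "direction": direction,
        },
        index=table.index,
    )
    out["enriched"] = (out["status"] != "none") & (out["direction"] == "up")
    return out


def _t_s0(
    x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float
) -> np.ndarray:
    a, b = x[:, idx_a], x[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return (a.mean(axis=1) - b.mean(axis=1)) / (se + s0)


def permutation_fdr_ttest(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    s0: float = 0.1,
    n_perm: int = 250,
    fdr: float = 0.01,
    seed: int | np.random.Generator = 0,
    max_exact: int = 500,
) -> pd.DataFrame:
    """Two-sided moderated t-test with permutation-FDR truncation.

    Values must be on a log scale and complete in the test columns. All
    balanced group-label permutations are enumerated when their number is at
    most ``max_exact``, otherwise ``n_perm`` random splits are sampled. For a
    cut at |t|, the expected false-positive count is the mean number of
    permuted |t| values beyond the cut per permutation; q-values are the
    monotone step-up of expected-FP / observed-positives, and ``significant``
    flags q <= fdr. s0 stabilizes small-variance rows and enters observed and
    permuted statistics alike.
    """
    cols = list(group_a) + list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    x = table[cols].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("test columns contain missing values; filter first")
    na = len(group_a)
    n_cols = len(cols)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    idx_a = np.arange(na)
    idx_b = np.arange(na, n_cols)
    t_obs = _t_s0(x, idx_a, idx_b, s0)

    if comb(n_cols, na) <= max_exact:
        splits = [np.array(c) for c in combinations(range(n_cols), na)]
    else:
        splits = []
        for _ in range(n_perm):
            perm = rng.permutation(n_cols)
            splits.append(np.sort(perm[:na]))
    all_idx = np.arange(n_cols)
    null_abs = np.concatenate(
        [
            np.abs(_t_s0(x, s, np.setdiff1d(all_idx, s), s0))
            for s in splits
        ]
    )
    null_sorted = np.sort(null_abs)
    n_splits = len(splits)

    abs_obs = np.abs(t_obs)
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    n_rows = len(sorted_abs)
    expected_fp = (
        null_sorted.size - np.searchsorted(null_sorted, sorted_abs, side="left")
    ) / n_splits
    observed_pos = np.arange(1, n_rows + 1)
    raw = np.minimum(expected_fp / observed_pos, 1.0)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(n_rows)
    q[order] = q_sorted

    out = pd.DataFrame(
        {
            "mean_a": x[:, idx_a].mean(axis=1),
            "mean_b": x[:, idx_b].mean(axis=1),
            "t_s0": t_obs,
            "q": q,
            "significant": q <= fdr,
        },
        index=table.index,
    )
    out["difference"] = out["mean_a"] - out["mean_b"]
    return out


def overlap_significance(
    set_a: Iterable, set_b: Iterable, universe: int | Iterable
) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two sets.

    ``universe`` is either its size or the universe collection itself (then
    both sets must be subsets). Returns P[X >= |A & B|] when |B| items are
    drawn from a universe containing |A| marked items.
    """
    a, b = set(set_a), set(set_b)
    if isinstance(universe, (int, np.integer)):
        m = int(universe)
    else:
        u = set(universe)
        if not a <= u or not b <= u:
            raise ValueError("sets must be subsets of the universe")
        m = len(u)
    if len(a) > m or len(b) > m:
        raise ValueError("set larger than universe")
    k = len(a & b)
    return float(hypergeom.sf(k - 1, m, len(a), len(b)))
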