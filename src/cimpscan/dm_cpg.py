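"""SAM-style per-CpG differential methylation.

The modified t-statistic is ``d = (mean_tumour - mean_normal) / (s + s0)``
where ``s`` is the pooled standard error of the group difference and
``s0`` a small exchangeability ("fudge") constant that damps the
statistic at probes with tiny variance. Significance is assessed by
permuting group labels and, for each |d| threshold, comparing the mean
number of permuted statistics exceeding it with the observed count,
which yields a per-probe q value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


@dataclass
class SamParameters:
    s0_mode: str = "cv_min"  # "cv_min" | "median" | "fixed"
    s0: float | None = None  # used when s0_mode == "fixed"
    n_permutations: int = 200
    seed: int = 0
    paired: bool = False

    def __post_init__(self) -> None:
        if self.s0_mode not in ("cv_min", "median", "fixed"):
            raise ValueError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "fixed" and (self.s0 is None or self.s0 < 0):
            raise ValueError("fixed s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class SamResult:
    table: pd.DataFrame  # probe_id, d, s, rank, q (q optional until FDR run)
    s0: float
    params: SamParameters
    exhaustive: bool = False

    @property
    def d(self) -> pd.Series:
        return self.table["d"]


def _group_arrays(beta: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(beta.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    bad = ~labels.isin(("tumour", "normal"))
    if bad.any():
        raise ValueError("labels must be 'tumour' or 'normal'")
    X = beta.values.astype(float)
    return X[:, (labels == "tumour").values], X[:, (labels == "normal").values]


def _num_and_s(T: np.ndarray, N: np.ndarray, paired: bool) -> tuple[np.ndarray, np.ndarray]:
    """Raw numerator (group mean difference) and its pooled standard error."""
    if paired:
        if T.shape[1] != N.shape[1]:
            raise ValueError("paired mode requires equal group sizes in pair order")
        D = T - N
        n = D.shape[1]
        if n < 2:
            raise ValueError("paired mode needs at least two pairs")
        num = D.mean(axis=1)
        s = D.std(axis=1, ddof=1) / np.sqrt(n)
    else:
        n1, n2 = T.shape[1], N.shape[1]
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs at least two samples")
        num = T.mean(axis=1) - N.mean(axis=1)
        ss = T.var(axis=1, ddof=1) * (n1 - 1) + N.var(axis=1, ddof=1) * (n2 - 1)
        s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return num, s


def _d_and_s(
    T: np.ndarray, N: np.ndarray, s0: float, paired: bool
) -> tuple[np.ndarray, np.ndarray]:
    num, s = _num_and_s(T, N, paired)
    denom = s + s0
    if (denom == 0).any():
        # constant probes with s0 = 0: the statistic is 0 by convention
        denom = np.where(denom == 0, 1.0, denom)
        num = np.where(s == 0, np.where(num == 0, 0.0, num), num)
    return num / denom, s


def choose_s0(s: np.ndarray, raw_d_numerators: np.ndarray, mode: str = "cv_min") -> float:
    """Pick the exchangeability constant from the spread of per-probe errors.

    ``cv_min`` follows the original procedure: candidate s0 values are
    percentiles of ``s``; for each candidate the coefficient of variation
    of the damped statistic is computed across s-quantile windows and the
    candidate with the smallest CV wins. ``median`` simply returns
    median(s).
    """
    s = np.asarray(s, float)
    num = np.asarray(raw_d_numerators, float)
    if s.size == 0:
        raise ValueError("empty s vector")
    if np.all(s == 0):
        return 1e-8
    if mode == "median":
        return float(np.median(s))
    if mode != "cv_min":
        raise ValueError(f"unknown mode {mode!r}")
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, percentiles)
    n_windows = min(10, max(2, s.size // 5))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = num / (s + s0)
        mads = np.array([_mad(d[w]) for w in windows if w.size])
        mads = mads[mads > 0]
        if mads.size < 2:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))) / 0.6745) if x.size else 0.0


def sam_d_statistic(
    beta: pd.DataFrame, labels: pd.Series, params: SamParameters
) -> SamResult:
    """Compute the modified t-statistic for every probe.

    ``beta`` is probes x samples; ``labels`` maps sample id to
    tumour/normal. In paired mode the tumour and normal columns must be
    ordered so that position k in each group belongs to subject k.
    """
    T, N = _group_arrays(beta, labels)
    num, s = _num_and_s(T, N, params.paired)
    if params.s0_mode == "fixed":
        s0 = float(params.s0)
    else:
        s0 = choose_s0(s, num, mode=params.s0_mode)
    d, s = _d_and_s(T, N, s0, params.paired)
    table = pd.DataFrame({"probe_id": beta.index, "d": d, "s": s}, index=beta.index)
    order = np.lexsort((table["probe_id"].values, -np.abs(d)))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return SamResult(table=table, s0=s0, params=params)


def _balanced_assignments(n1: int, n2: int):
    """All distinct tumour-index subsets of size n1 out of n1+n2 samples."""
    return combinations(range(n1 + n2), n1)


def sam_permutation_fdr(
    beta: pd.DataFrame, labels: pd.Series, params: SamParameters
) -> SamResult:
    """Modified t-statistics plus permutation-based q values.

    For each observed |d| threshold the expected number of false positives
    is the mean count of permuted |d*| above the threshold; the q value of
    a probe is the minimum ratio expected/observed over thresholds at or
    below its own |d|, then capped at 1. If the number of requested
    permutations is at least the number of distinct label assignments the
    enumeration is exhaustive instead of sampled.
    """
    res = sam_d_statistic(beta, labels, params)
    T, N = _group_arrays(beta, labels)
    n1, n2 = T.shape[1], N.shape[1]
    X = np.hstack([T, N])

    n_distinct = comb(n1 + n2, n1)
    rng = np.random.default_rng(params.seed)
    if params.paired:
        assignments = None  # sign-flip permutations
        exhaustive = params.n_permutations >= 2**n1
        if exhaustive:
            flips = ((np.arange(2**n1)[:, None] >> np.arange(n1)) & 1) * 2 - 1
        else:
            flips = rng.choice([-1, 1], size=(params.n_permutations, n1))
    else:
        exhaustive = params.n_permutations >= n_distinct
        if exhaustive:
            assignments = list(_balanced_assignments(n1, n2))
        else:
            assignments = [
                tuple(rng.choice(n1 + n2, size=n1, replace=False))
                for _ in range(params.n_permutations)
            ]

    abs_perm = []
    if params.paired:
        D = T - N
        for row in flips:
            Dp = D * row[None, :]
            n = Dp.shape[1]
            num = Dp.mean(axis=1)
            s = Dp.std(axis=1, ddof=1) / np.sqrt(n)
            abs_perm.append(np.abs(num / (s + res.s0)))
    else:
        all_idx = np.arange(n1 + n2)
        for tumour_idx in assignments:
            tumour_idx = np.asarray(tumour_idx)
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[tumour_idx] = True
            dp, _ = _d_and_s(X[:, mask], X[:, all_idx[~mask]], res.s0, False)
            abs_perm.append(np.abs(dp))
    abs_perm = np.sort(np.concatenate(abs_perm))
    n_perm = len(flips) if params.paired else len(assignments)

    abs_d = np.abs(res.table["d"].values)
    order = np.argsort(-abs_d, kind="stable")
    sorted_abs = abs_d[order]
    # expected FP at threshold |d_(i)|: mean permuted count >= threshold
    exceed = len(abs_perm) - np.searchsorted(abs_perm, sorted_abs, side="left")
    expected = exceed / n_perm
    observed = np.arange(1, len(sorted_abs) + 1)
    ratio = np.minimum(expected / observed, 1.0)
    # q_i = min over thresholds <= |d_i| (i.e. positions at or after i)
    q_sorted = np.minimum.accumulate(ratio[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    res.table["q"] = q
    res.exhaustive = exhaustive
    return res


def select_top_k(result: SamResult, k: int = 20000) -> list[str]:
    """The k probes with largest |d|, ties broken lexicographically by id."""
    table = result.table
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(table):
        raise ValueError(f"k={k} exceeds probe count {len(table)}")
    order = np.lexsort((table["probe_id"].values, -np.abs(table["d"].values)))
    return table["probe_id"].values[order[:k]].tolist()
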