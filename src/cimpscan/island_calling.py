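"""Gene-level island+shore hypermethylation calling in matched pairs.

For every (gene, tumour/normal pair) the per-probe beta differences over
the gene's island and shore probes are tested with the Wilcoxon
signed-rank test. Raw p values are Benjamini-Hochberg adjusted across
genes (per tumour by default), and a gene is called *hyper* in a tumour
when the adjusted p is below ``p_adj_max`` (default 0.005) and the mean
tumour-minus-normal beta difference is at least ``delta_min`` (default
0.1); *hypo* uses the mirrored criterion. The delta threshold itself can
be selected by scanning a grid for the value that maximises the
difference in mean per-tumour hyper counts between CIMP-H and CIMP-N
tumours.

The signed-rank test drops zero differences, assigns average ranks to
tied absolute differences, uses the exact null distribution up to
``exact_limit`` pairs (when untied) and a normal approximation with
continuity and tie correction beyond.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .preprocess import BetaMatrix, SampleSheet
from .subtyping import CIMP_H, CIMP_N, CimpAssignment

EXACT_LIMIT_DEFAULT = 25


@dataclass
class CallParameters:
    p_adj_max: float = 0.005
    delta_min: float = 0.1
    min_probes: int = 3
    adjust_scope: str = "per_tumour"  # or "global"
    exact_limit: int = EXACT_LIMIT_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.p_adj_max < 1:
            raise ValueError("p_adj_max must be in (0, 1)")
        if self.delta_min <= 0:
            raise ValueError("delta_min must be positive")
        if self.adjust_scope not in ("per_tumour", "global"):
            raise ValueError("adjust_scope must be 'per_tumour' or 'global'")


# -- Wilcoxon signed-rank -----------------------------------------------------

@lru_cache(maxsize=64)
def _signed_rank_counts(n: int) -> np.ndarray:
    """Number of rank subsets of {1..n} summing to each W+ value."""
    m = n * (n + 1) // 2
    c = np.zeros(m + 1, dtype=np.int64)
    c[0] = 1
    for r in range(1, n + 1):
        c[r:] = c[r:] + c[:-r]
    return c


def _average_ranks(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="stable")
    sa = a[order]
    ranks = np.empty(a.size, dtype=float)
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def signed_rank_p(diffs: np.ndarray, exact_limit: int = EXACT_LIMIT_DEFAULT) -> float:
    """Two-sided Wilcoxon signed-rank p for a vector of paired differences.

    Zero differences are dropped; if all differences are zero the p value
    is 1 by convention. With at most ``exact_limit`` untied non-zero
    differences the exact null distribution is used, otherwise a normal
    approximation with tie correction and continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    ranks = _average_ranks(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n <= exact_limit and not has_ties:
        m = n * (n + 1) // 2
        counts = _signed_rank_counts(n)
        w = int(round(w_plus))
        w_hi = max(w, m - w)
        p = 2.0 * counts[w_hi:].sum() / float(2**n)
        return min(p, 1.0)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(2.0 * norm.sf(abs(z)), 1.0))


def paired_signed_rank(
    tumour_betas: np.ndarray,
    normal_betas: np.ndarray,
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> float:
    """Two-sided signed-rank p over a gene's probes in one matched pair."""
    t = np.asarray(tumour_betas, dtype=float)
    n = np.asarray(normal_betas, dtype=float)
    if t.shape != n.shape:
        raise ValueError("tumour and normal vectors must have equal length")
    return signed_rank_p(t - n, exact_limit=exact_limit)


# -- multiple testing ---------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- gene x pair calling ------------------------------------------------------

CALL_HYPER, CALL_HYPO, CALL_NONE = "hyper", "hypo", "none"


@dataclass
class IslandCallMatrix:
    """Per-(gene, tumour) test results; columns are tumour sample ids."""

    p: pd.DataFrame
    p_adj: pd.DataFrame
    delta_beta: pd.DataFrame
    params: CallParameters
    pairs: pd.DataFrame  # tumour_sample, subject_id, normal_sample

    def calls_at(self, delta_min: float | None = None, p_adj_max: float | None = None) -> pd.DataFrame:
        """Categorical call matrix at the given (or configured) thresholds."""
        dmin = self.params.delta_min if delta_min is None else delta_min
        pmax = self.params.p_adj_max if p_adj_max is None else p_adj_max
        sig = self.p_adj.values < pmax
        out = np.full(self.p.shape, CALL_NONE, dtype=object)
        out[sig & (self.delta_beta.values >= dmin)] = CALL_HYPER
        out[sig & (self.delta_beta.values <= -dmin)] = CALL_HYPO
        return pd.DataFrame(out, index=self.p.index, columns=self.p.columns)

    @property
    def call(self) -> pd.DataFrame:
        return self.calls_at()

    def hyper_mask(self, delta_min: float | None = None) -> pd.DataFrame:
        dmin = self.params.delta_min if delta_min is None else delta_min
        return (self.p_adj < self.params.p_adj_max) & (self.delta_beta >= dmin)

    def to_frame(self) -> pd.DataFrame:
        call = self.call
        rows = []
        for tumour in self.p.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.p.index,
                        "tumour_sample": tumour,
                        "p": self.p[tumour].values,
                        "p_adj": self.p_adj[tumour].values,
                        "delta_beta": self.delta_beta[tumour].values,
                        "call": call[tumour].values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def call_island_dm(
    beta: BetaMatrix,
    gene_map: dict[str, list[str]],
    sheet: SampleSheet,
    params: CallParameters | None = None,
) -> IslandCallMatrix:
    """Test every gene in every matched pair and call hyper/hypo methylation.

    ``gene_map`` maps gene symbol to its island+shore probe ids (see
    :func:`cimpscan.annotation.build_gene_island_map`). BH adjustment runs
    across genes within each tumour (``adjust_scope='per_tumour'``) or over
    the whole gene x tumour matrix (``'global'``).
    """
    params = params or CallParameters()
    if not gene_map:
        raise ValueError("empty gene map")
    pairs = sheet.matched_pairs()
    if not pairs:
        raise ValueError("no complete tumour/normal pairs in sample sheet")
    B = beta.beta
    col_idx = {s: i for i, s in enumerate(B.columns)}
    missing = [s for _, t, n in pairs for s in (t, n) if s not in col_idx]
    if missing:
        raise ValueError(f"paired samples missing from beta matrix: {missing[:5]}")
    V = B.values
    genes = sorted(gene_map)
    t_cols = np.array([col_idx[t] for _, t, _ in pairs])
    n_cols = np.array([col_idx[n] for _, _, n in pairs])

    p_mat = np.empty((len(genes), len(pairs)))
    delta_mat = np.empty_like(p_mat)
    row_index = {pid: i for i, pid in enumerate(B.index)}
    for gi, gene in enumerate(genes):
        probes = gene_map[gene]
        try:
            rows = [row_index[p] for p in probes]
        except KeyError as exc:
            raise ValueError(f"gene {gene}: probe {exc} not in beta matrix") from exc
        if len(rows) < params.min_probes:
            raise ValueError(f"gene {gene}: fewer than min_probes probes")
        diffs = V[np.ix_(rows, t_cols)] - V[np.ix_(rows, n_cols)]
        delta_mat[gi] = diffs.mean(axis=0)
        for pi in range(len(pairs)):
            p_mat[gi, pi] = signed_rank_p(diffs[:, pi], exact_limit=params.exact_limit)

    if params.adjust_scope == "per_tumour":
        p_adj = np.column_stack([bh_adjust(p_mat[:, j]) for j in range(p_mat.shape[1])])
    else:
        p_adj = bh_adjust(p_mat.ravel()).reshape(p_mat.shape)

    tumour_ids = [t for _, t, _ in pairs]
    pair_table = pd.DataFrame(
        {
            "tumour_sample": tumour_ids,
            "subject_id": [s for s, _, _ in pairs],
            "normal_sample": [n for _, _, n in pairs],
        }
    )
    mk = lambda a: pd.DataFrame(a, index=genes, columns=tumour_ids)
    return IslandCallMatrix(
        p=mk(p_mat), p_adj=mk(p_adj), delta_beta=mk(delta_mat),
        params=params, pairs=pair_table,
    )


def tumour_call_counts(
    calls: IslandCallMatrix, labels: CimpAssignment
) -> tuple[pd.Series, pd.DataFrame]:
    """Hyper-call count per tumour and per-CIMP-group summaries."""
    hyper = calls.hyper_mask()
    counts = hyper.sum(axis=0)
    counts.name = "n_hyper"
    lab = labels.labels.reindex(counts.index)
    rows = []
    for group, grp_counts in counts.groupby(lab):
        rows.append(
            {
                "group": group,
                "n_tumours": len(grp_counts),
                "mean": float(grp_counts.mean()),
                "min": int(grp_counts.min()),
                "max": int(grp_counts.max()),
            }
        )
    return counts, pd.DataFrame(rows)


def scan_delta_threshold(
    calls: IslandCallMatrix,
    grid,
    labels: CimpAssignment,
) -> tuple[float, pd.DataFrame]:
    """Choose the delta-beta threshold maximising CIMP-H vs CIMP-N separation.

    For each candidate threshold the objective is the mean per-tumour
    hyper count in CIMP-H minus that in CIMP-N; the smallest argmax wins.
    Returns the chosen threshold and the full objective curve.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("empty threshold grid")
    h_tumours = [t for t in calls.p.columns if labels.labels.get(t) == CIMP_H]
    n_tumours = [t for t in calls.p.columns if labels.labels.get(t) == CIMP_N]
    if not h_tumours or not n_tumours:
        raise ValueError("need at least one CIMP-H and one CIMP-N tumour")
    rows = []
    for delta in grid:
        hyper = calls.hyper_mask(delta_min=delta)
        counts = hyper.sum(axis=0)
        objective = float(counts[h_tumours].mean() - counts[n_tumours].mean())
        rows.append({"delta": delta, "objective": objective})
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["objective"].idxmax(), "delta"]  # idxmax -> first max
    return float(best), curve
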