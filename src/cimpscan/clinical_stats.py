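"""Clinical association statistics and five-gene-panel CIMP classification.

Binary clinical variables are compared between subtypes with the
two-sided Fisher exact test (minimum-likelihood definition: the p value
sums the probabilities of all tables with the observed margins whose
point probability does not exceed that of the observed table).
Continuous variables use the Welch t test from group summaries. The
marker panel classifier follows the usual convention for the five-gene
panel (CACNA1G, NEUROG1, RUNX3, SOCS1, IGF2): more than 3/5 methylated
-> CIMP-H, 1/5 to 3/5 -> CIMP-L, 0/5 -> CIMP-N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PANEL_GENES = ("CACNA1G", "NEUROG1", "RUNX3", "SOCS1", "IGF2")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one positive margin required")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def fisher_exact_two_sided(table: ContingencyTable2x2, method: str = "min_likelihood") -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    ``min_likelihood`` (default) is the conventional definition; the
    ``doubled`` alternative doubles the smaller one-sided tail (capped
    at 1).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("empty margin: Fisher p is 1 by convention")
        return 1.0
    if method == "min_likelihood":
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])
    if method == "doubled":
        less = stats.fisher_exact(arr, alternative="less")[1]
        greater = stats.fisher_exact(arr, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(less, greater)))
    raise ValueError(f"unknown method {method!r}")


def welch_t_summary(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Welch t test from group summaries: (t, Welch-Satterthwaite df, p)."""
    if g1.sd == 0 and g2.sd == 0 and g1.mean == g2.mean:
        return 0.0, float(g1.n + g2.n - 2), 1.0
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(t), float(df), float(p)


def panel_cimp_classify(methylated_flags) -> str:
    """CIMP status from the five marker-gene methylation flags."""
    flags = list(methylated_flags)
    if len(flags) != len(PANEL_GENES):
        raise ValueError(f"expected {len(PANEL_GENES)} flags, got {len(flags)}")
    count = sum(bool(f) for f in flags)
    if count >= 4:
        return "CIMP-H"
    if count >= 1:
        return "CIMP-L"
    return "CIMP-N"


def label_concordance(cluster_labels: pd.Series, panel_labels: pd.Series) -> pd.Series:
    """Per cluster-derived class, the fraction of samples whose panel label agrees."""
    cluster_labels = pd.Series(cluster_labels)
    panel_labels = pd.Series(panel_labels).reindex(cluster_labels.index)
    if panel_labels.isna().any():
        raise ValueError("panel labels missing for some samples")
    agree = (cluster_labels == panel_labels).groupby(cluster_labels).mean()
    agree.name = "concordance"
    return agree


def truncate_p(p: float, decimals: int) -> float:
    """Truncate (not round) a p value to a number of decimals, as printed tables do."""
    scale = 10**decimals
    return np.floor(p * scale) / scale
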