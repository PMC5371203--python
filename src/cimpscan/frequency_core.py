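"""Hypermethylation-frequency scoring and core gene set extraction.

Each gene is scored for how often it is called hypermethylated within
each CIMP group and across all labelled tumours. A "core" set at
threshold t contains the genes hypermethylated in more than a fraction t
of a group's tumours (strictly more below 100%; exactly all tumours at
t = 1), and the frequency curve counts qualifying genes over a threshold
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .island_calling import IslandCallMatrix
from .subtyping import CimpAssignment

GROUP_ALL = "all"


@dataclass
class FrequencyProfile:
    """Per gene, per group: hyper-call count, group size and fraction."""

    counts: pd.DataFrame  # genes x groups
    group_sizes: dict[str, int]

    @property
    def fractions(self) -> pd.DataFrame:
        sizes = pd.Series(self.group_sizes)
        nonempty = sizes[sizes > 0]
        return self.counts[nonempty.index] / nonempty

    def empty_groups(self) -> list[str]:
        return [g for g, n in self.group_sizes.items() if n == 0]


def gene_frequency(calls: IslandCallMatrix, labels: CimpAssignment) -> FrequencyProfile:
    """Count hyper calls per gene within each CIMP group and overall."""
    hyper = calls.hyper_mask()
    lab = labels.labels.reindex(hyper.columns)
    if lab.isna().any():
        missing = hyper.columns[lab.isna()].tolist()
        raise ValueError(f"tumours without CIMP label: {missing[:5]}")
    groups = sorted(lab.unique())
    counts = pd.DataFrame(index=hyper.index)
    sizes: dict[str, int] = {}
    for g in groups:
        cols = hyper.columns[lab == g]
        counts[g] = hyper[cols].sum(axis=1)
        sizes[g] = len(cols)
    counts[GROUP_ALL] = hyper.sum(axis=1)
    sizes[GROUP_ALL] = hyper.shape[1]
    return FrequencyProfile(counts=counts, group_sizes=sizes)


def core_gene_set(freq: FrequencyProfile, group: str, threshold: float) -> set[str]:
    """Genes hypermethylated in more than ``threshold`` of a group's tumours.

    The boundary is strict below 1 and equality at exactly 1, so that a
    100% threshold means "in every tumour of the group".
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if group not in freq.counts.columns:
        raise ValueError(f"unknown group {group!r}")
    if freq.group_sizes[group] == 0:
        raise ValueError(f"group {group!r} has no tumours; fraction undefined")
    frac = freq.fractions[group]
    if threshold == 1:
        sel = frac == 1.0
    else:
        sel = frac > threshold
    return set(frac.index[sel])


def frequency_curve(freq: FrequencyProfile, thresholds) -> pd.DataFrame:
    """Number of qualifying genes per group over a threshold grid."""
    thresholds = [float(t) for t in thresholds]
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must be in [0, 1]")
    groups = [g for g in freq.counts.columns if freq.group_sizes[g] > 0]
    rows = []
    for t in sorted(thresholds):
        row = {"threshold": t}
        for g in groups:
            row[g] = len(core_gene_set(freq, g, t))
        rows.append(row)
    return pd.DataFrame(rows)
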