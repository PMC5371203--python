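"""Intensity-to-beta conversion and probe/sample QC.

The processing order follows the usual array workflow: detection-p filter,
per-sample rescaling to a common internal-control mean, beta computation
(``M / (M + U + offset)`` with offset 100), blacklist removal (sex
chromosomes, cross-reactive probes) and finally batch adjustment
(:mod:`cimpscan.combat`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import ProbeManifest

BETA_OFFSET = 100.0

TISSUES = ("tumour", "normal")


@dataclass
class SampleSheet:
    """Sample-level metadata: identity, tissue, chip/batch and clinical fields.

    Each subject may contribute at most one tumour and one normal sample;
    matched pairs share ``subject_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "tissue", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        bad = ~t["tissue"].isin(TISSUES)
        if bad.any():
            raise ValueError(f"tissue must be one of {TISSUES}")
        dup = t.groupby(["subject_id", "tissue"]).size()
        if (dup > 1).any():
            raise ValueError("a subject has more than one sample of the same tissue")
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_of(self, tissue: str) -> list[str]:
        return self.table.index[self.table["tissue"] == tissue].tolist()

    def matched_pairs(self) -> list[tuple[str, str, str]]:
        """(subject_id, tumour_sample, normal_sample) for complete pairs."""
        pairs = []
        for subject, grp in self.table.groupby("subject_id", sort=True):
            by_tissue = dict(zip(grp["tissue"], grp["sample_id"]))
            if "tumour" in by_tissue and "normal" in by_tissue:
                pairs.append((subject, by_tissue["tumour"], by_tissue["normal"]))
        return pairs

    def batches(self) -> pd.Series:
        return self.table["batch"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype={"sample_id": str, "subject_id": str, "batch": str}))


@dataclass
class IntensityDataset:
    """Raw probe-level input: methylated/unmethylated intensities + detection p."""

    M: pd.DataFrame
    U: pd.DataFrame
    detection_p: pd.DataFrame
    sample_sheet: SampleSheet

    def __post_init__(self) -> None:
        for name, m in (("M", self.M), ("U", self.U), ("detection_p", self.detection_p)):
            if not m.index.equals(self.M.index) or not m.columns.equals(self.M.columns):
                raise ValueError(f"{name} matrix index/columns mismatch")
        if (self.M.values < 0).any() or (self.U.values < 0).any():
            raise ValueError("negative intensities")
        p = self.detection_p.values
        if ((p < 0) | (p > 1)).any():
            raise ValueError("detection p-values outside [0, 1]")
        sheet_ids = set(self.sample_sheet.sample_ids)
        if set(self.M.columns) != sheet_ids:
            raise ValueError("intensity columns do not match sample sheet")

    @property
    def probe_ids(self) -> pd.Index:
        return self.M.index

    def subset_probes(self, probe_ids) -> "IntensityDataset":
        return IntensityDataset(
            self.M.loc[probe_ids],
            self.U.loc[probe_ids],
            self.detection_p.loc[probe_ids],
            self.sample_sheet,
        )

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.M.to_csv(out / "M.tsv", sep="\t")
        self.U.to_csv(out / "U.tsv", sep="\t")
        self.detection_p.to_csv(out / "detection_p.tsv", sep="\t")
        self.sample_sheet.to_csv(out / "samples.csv")

    @classmethod
    def from_dir(cls, in_dir) -> "IntensityDataset":
        d = Path(in_dir)
        read = lambda name: pd.read_csv(d / name, sep="\t", index_col=0)
        return cls(
            read("M.tsv"),
            read("U.tsv"),
            read("detection_p.tsv"),
            SampleSheet.from_csv(d / "samples.csv"),
        )


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1)."""

    beta: pd.DataFrame
    rescaled: bool = False
    batch_adjusted: bool = False

    def __post_init__(self) -> None:
        v = self.beta.values
        if (v < 0).any() or (v >= 1).any():
            raise ValueError("beta values must lie in [0, 1)")

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[probe_ids], self.rescaled, self.batch_adjusted)


def compute_beta(M, U, offset: float = BETA_OFFSET):
    """Beta value ``M / (M + U + offset)``, elementwise over arrays or frames.

    The positive offset stabilises low-intensity probes and guarantees a
    strict upper bound below 1.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    M_arr = np.asarray(M, dtype=float) if not isinstance(M, pd.DataFrame) else M
    U_arr = np.asarray(U, dtype=float) if not isinstance(U, pd.DataFrame) else U
    if (np.asarray(M_arr) < 0).any() or (np.asarray(U_arr) < 0).any():
        raise ValueError("negative intensities")
    return M_arr / (M_arr + U_arr + offset)


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_detection: int
    removed_sex_chromosome: int
    removed_cross_reactive: int
    removed_control: int

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def filter_probes(
    ds: IntensityDataset,
    manifest: ProbeManifest,
    alpha: float = 0.05,
    max_failure_fraction: float = 0.0,
) -> tuple[list[str], FilterReport]:
    """Select analysable probes and report removals per reason.

    A probe is removed when its detection p exceeds ``alpha`` in more than
    ``max_failure_fraction`` of samples (default 0: any failing sample
    removes the probe), when it maps to a sex chromosome, when it is
    flagged cross-reactive, or when it is a control probe. Reasons are
    assessed in that order and each probe is counted once.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    probe_ids = ds.probe_ids
    man = manifest.table.loc[probe_ids]
    fail_frac = (ds.detection_p.values > alpha).mean(axis=1)
    detection_fail = pd.Series(fail_frac > max_failure_fraction, index=probe_ids)
    # controls are never part of the analysis set; count them first
    is_control = man["is_negative_control"] | man["is_internal_control"]
    detection_fail &= ~is_control
    sex = man["is_sex_chromosome"] & ~detection_fail & ~is_control
    cross = man["cross_reactive"] & ~detection_fail & ~is_control & ~sex
    removed = detection_fail | is_control | sex | cross
    retained = probe_ids[~removed].tolist()
    report = FilterReport(
        n_input=len(probe_ids),
        n_retained=len(retained),
        removed_detection=int(detection_fail.sum()),
        removed_sex_chromosome=int(sex.sum()),
        removed_cross_reactive=int(cross.sum()),
        removed_control=int(is_control.sum()),
    )
    return retained, report


def rescale_to_control_mean(
    ds: IntensityDataset, internal_control_ids: Optional[list[str]] = None
) -> tuple[IntensityDataset, pd.Series]:
    """Rescale each sample's intensities so control probes share a common mean.

    The per-sample factor is ``grand_control_mean / sample_control_mean``
    applied to both channels; after rescaling every sample's internal
    control mean (over M + U) equals the grand mean.
    """
    if internal_control_ids is None:
        raise ValueError("internal control probe ids are required")
    controls = [p for p in internal_control_ids if p in ds.probe_ids]
    if not controls:
        raise ValueError("no internal control probes present in dataset")
    total = ds.M.loc[controls] + ds.U.loc[controls]
    sample_means = total.mean(axis=0)
    bad = sample_means[sample_means <= 0]
    if len(bad):
        raise ValueError(f"non-positive control mean for samples: {bad.index.tolist()}")
    grand = float(sample_means.mean())
    factors = grand / sample_means
    rescaled = IntensityDataset(
        ds.M.mul(factors, axis=1),
        ds.U.mul(factors, axis=1),
        ds.detection_p,
        ds.sample_sheet,
    )
    return rescaled, factors
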