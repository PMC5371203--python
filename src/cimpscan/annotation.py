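"""Probe manifest handling: island geometry, gene maps and feature summaries.

The manifest mirrors the information an array manifest provides for each
probe: genomic position, CpG-island membership, the island/shore/shelf/
open-sea region class, linked gene symbols, feature context (TSS window,
first exon, UTRs, gene body, intergenic, enhancer) and QC flags
(cross-reactive, sex chromosome, control classes).

Coordinates are 1-based closed intervals. A probe is *island* when its
position lies inside an island interval; *shore* when the distance to the
nearest island edge is 1-2000 bp; *shelf* for 2001-3000 bp; *open_sea*
beyond 3000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SHORE_MAX_BP = 2000
SHELF_MAX_BP = 3000

REGION_CLASSES = ("island", "shore", "shelf", "open_sea")
FEATURE_CONTEXTS = (
    "TSS_window",
    "first_exon",
    "UTR5",
    "UTR3",
    "body",
    "intergenic",
    "enhancer",
)

#: 1-based window size upstream of a transcription start site counted as TSS context.
TSS_WINDOW_BP = 1500

MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "island_id",
    "region_class",
    "gene_symbols",
    "feature_context",
    "cross_reactive",
    "is_sex_chromosome",
    "is_negative_control",
    "is_internal_control",
]


@dataclass(frozen=True)
class IslandInterval:
    """A CpG island as a 1-based closed genomic interval."""

    island_id: str
    chromosome: str
    start: int
    end: int
    gene_symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"island {self.island_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"island {self.island_id}: start must be >= 1")


class ProbeManifest:
    """Per-probe annotation table plus the island interval list.

    Parameters
    ----------
    table:
        One row per probe with the columns in :data:`MANIFEST_COLUMNS`.
        ``gene_symbols`` and ``feature_context`` hold semicolon-joined
        strings or python sets.
    islands:
        The CpG island intervals referenced by ``island_id``.
    """

    def __init__(self, table: pd.DataFrame, islands: Iterable[IslandInterval] = ()):
        table = table.copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        for col in ("gene_symbols", "feature_context"):
            table[col] = table[col].apply(_as_set)
        for col in (
            "cross_reactive",
            "is_sex_chromosome",
            "is_negative_control",
            "is_internal_control",
        ):
            table[col] = table[col].astype(bool)
        if table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in manifest")
        table = table.set_index("probe_id", drop=False)
        self.table = table
        island_list = list(islands)
        self.islands = {iv.island_id: iv for iv in island_list}
        if len(self.islands) < len(island_list):
            raise ValueError("duplicate island ids")
        self._validate()

    def _validate(self) -> None:
        t = self.table
        control = t["is_negative_control"] | t["is_internal_control"]
        genomic = t[~control]
        if (genomic["position"] <= 0).any():
            bad = genomic.loc[genomic["position"] <= 0, "probe_id"].tolist()[:5]
            raise ValueError(f"non-control probes need position > 0: {bad}")
        if (genomic["chromosome"].astype(str) == "").any():
            raise ValueError("non-control probes need a chromosome")
        bad_region = ~genomic["region_class"].isin(REGION_CLASSES)
        if bad_region.any():
            raise ValueError(
                f"unknown region_class values: "
                f"{sorted(genomic.loc[bad_region, 'region_class'].unique())}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def genomic_probes(self) -> pd.DataFrame:
        t = self.table
        return t[~(t["is_negative_control"] | t["is_internal_control"])]

    def negative_control_ids(self) -> list[str]:
        return self.table.index[self.table["is_negative_control"]].tolist()

    def internal_control_ids(self) -> list[str]:
        return self.table.index[self.table["is_internal_control"]].tolist()

    def islands_on(self, chromosome: str) -> list[IslandInterval]:
        return [iv for iv in self.islands.values() if iv.chromosome == chromosome]

    # -- I/O -------------------------------------------------------------------
    def to_files(self, manifest_path, islands_path) -> None:
        out = self.table.copy()
        out["gene_symbols"] = out["gene_symbols"].apply(_join_set)
        out["feature_context"] = out["feature_context"].apply(_join_set)
        out.to_csv(manifest_path, sep="\t", index=False)
        rows = [
            {
                "chromosome": iv.chromosome,
                "start": iv.start,
                "end": iv.end,
                "island_id": iv.island_id,
                "gene_symbols": _join_set(iv.gene_symbols),
            }
            for iv in self.islands.values()
        ]
        pd.DataFrame(
            rows, columns=["chromosome", "start", "end", "island_id", "gene_symbols"]
        ).to_csv(islands_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, manifest_path, islands_path) -> "ProbeManifest":
        table = pd.read_csv(
            manifest_path, sep="\t", dtype={"chromosome": str}, keep_default_na=False
        )
        table["position"] = table["position"].astype(int)
        isl = pd.read_csv(
            islands_path, sep="\t", dtype={"chromosome": str}, keep_default_na=False
        )
        islands = [
            IslandInterval(
                island_id=str(r.island_id),
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                gene_symbols=_as_set(r.gene_symbols),
            )
            for r in isl.itertuples()
        ]
        return cls(table, islands)


def _as_set(value) -> frozenset[str]:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(str(v) for v in value if str(v))
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    if not s:
        return frozenset()
    return frozenset(p for p in s.split(";") if p)


def _join_set(value: frozenset[str]) -> str:
    return ";".join(sorted(value))


def classify_region(position: int, islands: Iterable[IslandInterval]) -> str:
    """Classify a genomic position relative to a chromosome's CpG islands.

    Distance to an island is the minimum over its two edges of
    ``|position - edge|``, zero meaning containment. An empty island list
    yields ``open_sea``.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    best = None
    for iv in islands:
        if iv.start <= position <= iv.end:
            return "island"
        d = min(abs(position - iv.start), abs(position - iv.end))
        best = d if best is None else min(best, d)
    if best is None or best > SHELF_MAX_BP:
        return "open_sea"
    if best <= SHORE_MAX_BP:
        return "shore"
    return "shelf"


def build_gene_island_map(
    manifest: ProbeManifest, min_probes: int = 3
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Map each gene to its island and shore probes, ordered by probe id.

    Island and shore probes are pooled per gene; shelf and open-sea probes
    are excluded. Genes with fewer than ``min_probes`` probes are dropped
    and reported in the second return value (gene -> probe count).
    A probe annotated to several genes contributes to each of them.
    """
    genomic = manifest.genomic_probes()
    keep = genomic[genomic["region_class"].isin(("island", "shore"))]
    mapping: dict[str, set[str]] = {}
    for probe_id, genes in zip(keep["probe_id"], keep["gene_symbols"]):
        for g in genes:
            mapping.setdefault(g, set()).add(probe_id)
    result: dict[str, list[str]] = {}
    excluded: dict[str, int] = {}
    for gene in sorted(mapping):
        probes = sorted(mapping[gene])
        if len(probes) >= min_probes:
            result[gene] = probes
        else:
            excluded[gene] = len(probes)
    return result, excluded


def annotate_feature_fractions(
    probe_set: Iterable[str], manifest: ProbeManifest
) -> pd.DataFrame:
    """Summarise where a probe set falls in the genome.

    For each region class and feature context the table reports the number
    of set probes in the feature, the fraction of the set, and the fraction
    of all array probes carrying that feature that are in the set. Probes
    may carry several feature contexts, so fractions over contexts need not
    sum to one; region classes are mutually exclusive.
    """
    probe_set = set(probe_set)
    genomic = manifest.genomic_probes()
    unknown = probe_set - set(genomic["probe_id"])
    if unknown:
        raise ValueError(f"probes not in manifest (or controls): {sorted(unknown)[:5]}")
    in_set = genomic["probe_id"].isin(probe_set)
    n_set = int(in_set.sum())

    rows = []
    for feature in list(REGION_CLASSES):
        mask = genomic["region_class"] == feature
        rows.append(_feature_row("region", feature, mask, in_set, n_set))
    for feature in FEATURE_CONTEXTS:
        mask = genomic["feature_context"].apply(lambda s: feature in s)
        rows.append(_feature_row("context", feature, mask, in_set, n_set))
    return pd.DataFrame(
        rows,
        columns=[
            "feature_kind",
            "feature",
            "count_in_set",
            "fraction_of_set",
            "array_total",
            "fraction_of_array_feature",
        ],
    )


def _feature_row(kind: str, feature: str, mask, in_set, n_set: int) -> dict:
    count = int((mask & in_set).sum())
    total = int(mask.sum())
    return {
        "feature_kind": kind,
        "feature": feature,
        "count_in_set": count,
        "fraction_of_set": count / n_set if n_set else 0.0,
        "array_total": total,
        "fraction_of_array_feature": count / total if total else 0.0,
    }
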