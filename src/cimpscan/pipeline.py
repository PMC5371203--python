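"""End-to-end orchestration: preprocess -> SAM top-K -> subtyping ->
island calls -> threshold scan -> frequency/core sets -> clinical stats.

A single declarative :class:`PipelineConfig` drives the run; every
default is written into the config snapshot so re-running an emitted
snapshot reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, clinical_stats, combat, dm_cpg, frequency_core, island_calling, preprocess
from .annotation import ProbeManifest
from .preprocess import BetaMatrix, IntensityDataset
from . import subtyping as subtyping_mod


@dataclass
class PipelineConfig:
    input_dir: str | None = None  # directory with M/U/detection_p/samples + manifest
    out_dir: str | None = None
    # preprocess
    beta_offset: float = 100.0
    detection_alpha: float = 0.05
    max_failure_fraction: float = 0.0
    # SAM
    sam_s0_mode: str = "cv_min"
    sam_n_permutations: int = 200
    sam_seed: int | None = None
    sam_paired: bool = False
    top_k: int = 20000
    # subtyping
    cut_mode: str = "nested"
    k_tumour_clusters: int = 3
    # island calling
    p_adj_max: float = 0.005
    min_probes: int = 3
    adjust_scope: str = "per_tumour"
    delta_grid: list = field(default_factory=lambda: [0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
    delta_min: float | None = None  # fixed threshold; None -> scan the grid
    # frequency
    frequency_thresholds: list = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 11)]
    )

    def __post_init__(self) -> None:
        if self.sam_seed is None:
            raise ValueError("sam_seed is required: permutation FDR is stochastic")

    def to_dict(self) -> dict:
        return asdict(self)

    def snapshot_dict(self) -> dict:
        """Analysis parameters only: paths do not affect the results."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("input_dir", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.snapshot_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def default_synthetic(cls, sam_seed: int = 0, **overrides) -> "PipelineConfig":
        """Defaults scaled to the standard synthetic cohort (2000 genes)."""
        kwargs = dict(sam_seed=sam_seed, top_k=3000)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_report: preprocess.FilterReport
    rescale_factors: pd.Series
    beta: BetaMatrix
    batch_params: combat.BatchParameters
    sam: dm_cpg.SamResult
    selected_probes: list
    dendrogram: subtyping_mod.Dendrogram
    cimp: subtyping_mod.CimpAssignment
    calls: island_calling.IslandCallMatrix
    chosen_delta: float
    threshold_curve: pd.DataFrame
    tumour_counts: pd.Series
    group_summary: pd.DataFrame
    frequency: frequency_core.FrequencyProfile
    core_sets: dict
    frequency_curve: pd.DataFrame
    concordance: pd.Series | None
    excluded_genes: dict
    log: list

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = self.config.config_hash()
        meta = {"config_hash": h, "stages": self.log}
        (out / "run_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        (out / "config_snapshot.yaml").write_text(
            yaml.safe_dump(self.config.snapshot_dict(), sort_keys=True)
        )
        self.filter_report.as_series().to_csv(out / "qc_report.tsv", sep="\t", header=False)
        self.batch_params.summary().to_csv(out / "batch_params.tsv", sep="\t", index=False)
        self.sam.table.to_csv(out / "sam_results.tsv", sep="\t", index=False)
        pd.Series(self.selected_probes, name="probe_id").to_csv(
            out / "selected_probes.tsv", sep="\t", index=False
        )
        (out / "dendrogram.json").write_text(
            json.dumps(self.dendrogram.to_dict(), sort_keys=True)
        )
        self.cimp.labels.rename_axis("sample_id").to_csv(out / "cimp_labels.tsv", sep="\t")
        self.calls.to_frame().to_csv(out / "island_calls.tsv", sep="\t", index=False)
        self.threshold_curve.to_csv(out / "threshold_curve.tsv", sep="\t", index=False)
        self.tumour_counts.rename_axis("tumour_sample").to_csv(
            out / "tumour_counts.tsv", sep="\t"
        )
        self.group_summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)
        self.frequency.counts.rename_axis("gene").to_csv(out / "gene_frequency.tsv", sep="\t")
        self.frequency_curve.to_csv(out / "frequency_curve.tsv", sep="\t", index=False)
        core_dir = out / "core_sets"
        core_dir.mkdir(exist_ok=True)
        for (group, thr), genes in self.core_sets.items():
            name = f"{group}_{int(round(thr * 100))}.txt"
            (core_dir / name).write_text("\n".join(sorted(genes)) + "\n")
        if self.concordance is not None:
            self.concordance.rename_axis("cluster_label").to_csv(
                out / "concordance.tsv", sep="\t"
            )


def run_pipeline(
    cfg: PipelineConfig,
    ds: IntensityDataset | None = None,
    manifest: ProbeManifest | None = None,
) -> PipelineResult:
    """Execute every stage in order on an in-memory or on-disk dataset."""
    log: list[str] = []
    if ds is None or manifest is None:
        if cfg.input_dir is None:
            raise ValueError("provide a dataset+manifest or cfg.input_dir")
        d = Path(cfg.input_dir)
        manifest = ProbeManifest.from_files(d / "manifest.tsv", d / "islands.tsv")
        ds = IntensityDataset.from_dir(d)
        log.append(f"loaded inputs from {d}")

    retained, report = preprocess.filter_probes(
        ds, manifest, alpha=cfg.detection_alpha,
        max_failure_fraction=cfg.max_failure_fraction,
    )
    log.append(f"probe filter: {report.n_retained}/{report.n_input} retained")

    rescaled, factors = preprocess.rescale_to_control_mean(
        ds, manifest.internal_control_ids()
    )
    beta_frame = preprocess.compute_beta(
        rescaled.M.loc[retained], rescaled.U.loc[retained], offset=cfg.beta_offset
    )
    beta = BetaMatrix(beta_frame, rescaled=True)
    log.append(f"beta computed for {beta_frame.shape[0]} probes")

    beta, batch_params = combat.combat_adjust(beta, ds.sample_sheet.batches())
    log.append(f"batch adjustment over {len(batch_params.batches)} batches")

    labels = ds.sample_sheet.table["tissue"]
    params = dm_cpg.SamParameters(
        s0_mode=cfg.sam_s0_mode, n_permutations=cfg.sam_n_permutations,
        seed=cfg.sam_seed, paired=cfg.sam_paired,
    )
    sam = dm_cpg.sam_permutation_fdr(beta.beta, labels, params)
    k = min(cfg.top_k, len(sam.table))
    selected = dm_cpg.select_top_k(sam, k)
    log.append(f"SAM: s0={sam.s0:.4g}, selected top {k} probes")

    X = beta.beta.loc[selected].T  # samples x probes
    dend = subtyping_mod.complete_linkage_cluster(X)
    cimp = subtyping_mod.assign_cimp_labels(
        dend, ds.sample_sheet, X,
        cut_mode=cfg.cut_mode, k_tumour_clusters=cfg.k_tumour_clusters,
    )
    log.append(
        f"subtyping: {cimp.group_sizes()} "
        f"({len(cimp.excluded_normals)} normals excluded, "
        f"{len(cimp.tumours_in_normal_branch)} tumours in normal branch)"
    )

    gene_map, excluded_genes = annotation.build_gene_island_map(
        manifest, min_probes=cfg.min_probes
    )
    gene_map = {
        g: [p for p in probes if p in beta.beta.index]
        for g, probes in gene_map.items()
    }
    gene_map = {g: p for g, p in gene_map.items() if len(p) >= cfg.min_probes}
    call_params = island_calling.CallParameters(
        p_adj_max=cfg.p_adj_max,
        delta_min=cfg.delta_min if cfg.delta_min is not None else 0.1,
        min_probes=cfg.min_probes,
        adjust_scope=cfg.adjust_scope,
    )
    calls = island_calling.call_island_dm(beta, gene_map, ds.sample_sheet, call_params)
    if cfg.delta_min is None:
        chosen_delta, curve = island_calling.scan_delta_threshold(
            calls, cfg.delta_grid, cimp
        )
        calls.params.delta_min = chosen_delta
    else:
        chosen_delta = cfg.delta_min
        _, curve = island_calling.scan_delta_threshold(calls, cfg.delta_grid, cimp)
    log.append(f"island calling over {len(gene_map)} genes; delta_min={chosen_delta}")

    counts, group_summary = island_calling.tumour_call_counts(calls, cimp)
    freq = frequency_core.gene_frequency(calls, cimp)
    core_sets = {}
    for thr in (1.0, 0.9):
        for group in sorted(set(cimp.labels)):
            core_sets[(group, thr)] = frequency_core.core_gene_set(freq, group, thr)
    curve_freq = frequency_core.frequency_curve(freq, cfg.frequency_thresholds)

    concordance = None
    sheet = ds.sample_sheet.table
    if "panel_cimp" in sheet.columns:
        panel = sheet.loc[cimp.labels.index, "panel_cimp"]
        if panel.notna().all():
            concordance = clinical_stats.label_concordance(cimp.labels, panel)
            log.append("panel concordance computed")

    result = PipelineResult(
        config=cfg,
        filter_report=report,
        rescale_factors=factors,
        beta=beta,
        batch_params=batch_params,
        sam=sam,
        selected_probes=selected,
        dendrogram=dend,
        cimp=cimp,
        calls=calls,
        chosen_delta=chosen_delta,
        threshold_curve=curve,
        tumour_counts=counts,
        group_summary=group_summary,
        frequency=freq,
        core_sets=core_sets,
        frequency_curve=curve_freq,
        concordance=concordance,
        excluded_genes=excluded_genes,
        log=log,
    )
    if cfg.out_dir:
        result.write(cfg.out_dir)
    return result
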