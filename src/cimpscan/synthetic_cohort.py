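"""Synthetic matched tumour/normal 450K-like cohorts with planted truth.

The generator emulates the statistical structure the analysis assumes:

* a probe manifest with CpG islands (plus shores, shelves, open sea,
  sex-chromosome, cross-reactive and control probes),
* matched tumour/normal pairs processed on the same chip (batch),
* a planted CIMP programme at a core gene set, methylated strongly in
  CIMP-H tumours, at an intermediate level in CIMP-L and weakly (below
  the calling threshold) in CIMP-N tumours,
* per-tumour stochastic background hypermethylation with heavy-tailed
  (log-normal) per-tumour rates and group-specific effect-size
  distributions,
* a shared block of tumour hypomethylation at open-sea probes, so that
  even weakly hypermethylated tumours are separable from normal tissue,
* per-probe logit-scale measurement noise, per-sample intensity scale
  factors, chip batch effects and sporadic detection failures.

Betas are converted to intensities via ``M = beta * (T + 100)``,
``U = T - M`` with total intensity ``T``, so the beta formula inverts the
construction exactly. Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import IslandInterval, ProbeManifest
from .clinical_stats import PANEL_GENES, panel_cimp_classify
from .preprocess import IntensityDataset, SampleSheet
from .subtyping import CIMP_H, CIMP_L, CIMP_N

GROUPS = (CIMP_H, CIMP_L, CIMP_N)

BETA_FLOOR = 0.02
BETA_CAP = 0.93


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults define the standard cohort."""

    n_pairs: int = 40
    group_proportions: tuple[float, float, float] = (0.35, 0.15, 0.50)  # H, L, N
    n_genes: int = 2000
    core_set_size: int = 132
    island_probes_range: tuple[int, int] = (10, 14)
    shore_probes_range: tuple[int, int] = (4, 6)
    shelf_probes_per_gene: int = 2
    n_open_sea_probes: int = 6000
    n_hypo_probes: int = 600
    n_sex_probes: int = 400
    n_cross_reactive: int = 300
    n_negative_controls: int = 300
    n_internal_controls: int = 100
    # normal-tissue baselines (beta scale) and their logit-scale spread
    normal_island_beta_mean: float = 0.10
    normal_shelf_beta_mean: float = 0.40
    normal_open_sea_beta_mean: float = 0.75
    baseline_logit_sd: float = 0.3
    subject_logit_sd: float = 0.2
    # planted CIMP programme at the core genes (beta-scale shifts)
    programme_delta_mean: dict = field(
        default_factory=lambda: {CIMP_H: 0.35, CIMP_L: 0.22, CIMP_N: 0.08}
    )
    programme_delta_sd: dict = field(
        default_factory=lambda: {CIMP_H: 0.03, CIMP_L: 0.03, CIMP_N: 0.005}
    )
    programme_delta_bounds: dict = field(
        default_factory=lambda: {
            CIMP_H: (0.15, 0.50),
            CIMP_L: (0.12, 0.32),
            CIMP_N: (0.06, 0.095),
        }
    )
    # stochastic background hypermethylation
    background_rate_mean: dict = field(
        default_factory=lambda: {CIMP_H: 100.0, CIMP_L: 38.0, CIMP_N: 31.0}
    )
    background_rate_sigma: float = 0.8
    background_effect_median: dict = field(
        default_factory=lambda: {CIMP_H: 0.18, CIMP_L: 0.15, CIMP_N: 0.07}
    )
    background_effect_sigma: dict = field(
        default_factory=lambda: {CIMP_H: 0.35, CIMP_L: 0.40, CIMP_N: 0.50}
    )
    background_effect_bounds: tuple[float, float] = (0.02, 0.50)
    # shared tumour hypomethylation block
    hypo_depth_mean: float = 0.60
    hypo_depth_sd: float = 0.03
    n_normal_like: int = 2
    # technical structure
    noise_sd_logit: float = 0.15
    pairs_per_batch: int = 6
    batch_shift_sd: float = 0.01
    batch_probe_sd: float = 0.005
    intensity_scale: float = 5000.0
    intensity_scale_sigma: float = 0.2
    intensity_scale_floor: float = 2000.0
    sample_scale_sigma: float = 0.10
    detection_failure_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.core_set_size > self.n_genes:
            raise ValueError("core set larger than gene count")
        if self.n_hypo_probes > self.n_open_sea_probes:
            raise ValueError("hypo block larger than open-sea probe count")
        for g in GROUPS:
            hi = self.programme_delta_bounds[g][1]
            if self.normal_island_beta_mean + hi >= BETA_CAP:
                raise ValueError("planted beta would exceed the intensity-safe cap")
        cap_ratio = self.intensity_scale_floor / (self.intensity_scale_floor + 100.0)
        if BETA_CAP >= cap_ratio:
            raise ValueError(
                "beta cap incompatible with intensity scale: "
                f"need beta < T/(T+100) = {cap_ratio:.4f}"
            )

    def group_sizes(self) -> dict[str, int]:
        h = round(self.n_pairs * self.group_proportions[0])
        l = round(self.n_pairs * self.group_proportions[1])
        return {CIMP_H: h, CIMP_L: l, CIMP_N: self.n_pairs - h - l}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """The recovery oracle: everything the generator planted."""

    core_genes: list[str]
    subtype: dict[str, str]  # tumour sample id -> CIMP-H/L/N
    background_events: dict[str, list[str]]  # tumour sample id -> genes
    normal_like_tumours: list[str]
    hypo_probes: list[str]
    batch: dict[str, str]  # sample id -> batch
    config: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# -- manifest -----------------------------------------------------------------

def generate_manifest(
    cfg: CohortConfig, seed: int | None = None
) -> ProbeManifest:
    """Tile synthetic CpG islands and surrounding probes onto chromosomes.

    Each gene owns one island (with its probes), shore probes within
    2 kb of the island edges, and shelf probes at 2-3 kb. Open-sea
    probes live on island-free chromosomes; a fixed subset of them forms
    the shared tumour hypomethylation block (flagged by the ``enhancer``
    feature context). Deterministic under the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tile = 100_000
    n_chrom = 10
    rows: list[dict] = []
    islands: list[IslandInterval] = []
    counter = 0

    def pid() -> str:
        nonlocal counter
        counter += 1
        return f"cg{counter:08d}"

    for gi in range(cfg.n_genes):
        gene = f"G{gi:04d}"
        chrom = f"chr{gi % n_chrom + 1}"
        start = (gi // n_chrom) * tile + 40_000
        end = start + 800
        islands.append(
            IslandInterval(f"CGI_{gene}", chrom, start, end, frozenset({gene}))
        )
        n_island = int(rng.integers(*cfg.island_probes_range, endpoint=True))
        n_shore = int(rng.integers(*cfg.shore_probes_range, endpoint=True))
        pos_island = np.sort(rng.choice(np.arange(start, end + 1), n_island, replace=False))
        for p in pos_island:
            rows.append(
                _row(pid(), chrom, int(p), f"CGI_{gene}", "island", {gene}, {"TSS_window"})
            )
        for _ in range(n_shore):
            off = int(rng.integers(1, 2001))
            side = -1 if rng.random() < 0.5 else 1
            p = start - off if side < 0 else end + off
            rows.append(
                _row(pid(), chrom, int(p), f"CGI_{gene}", "shore", {gene}, {"TSS_window"})
            )
        for _ in range(cfg.shelf_probes_per_gene):
            off = int(rng.integers(2001, 3001))
            side = -1 if rng.random() < 0.5 else 1
            p = start - off if side < 0 else end + off
            rows.append(
                _row(pid(), chrom, int(p), f"CGI_{gene}", "shelf", {gene}, {"body"})
            )

    hypo_ids: list[str] = []
    for i in range(cfg.n_open_sea_probes):
        chrom = f"chr{n_chrom + 1 + i % 2}"  # island-free chromosomes
        p = 10_000 + i * 500
        is_hypo = i < cfg.n_hypo_probes
        context = {"enhancer", "intergenic"} if is_hypo else {"intergenic"}
        probe = pid()
        if is_hypo:
            hypo_ids.append(probe)
        rows.append(_row(probe, chrom, p, "", "open_sea", set(), context))

    for i in range(cfg.n_sex_probes):
        chrom = "chrX" if i % 2 == 0 else "chrY"
        rows.append(
            _row(pid(), chrom, 10_000 + i * 700, "", "open_sea", set(), {"intergenic"},
                 sex=True)
        )
    for i in range(cfg.n_cross_reactive):
        rows.append(
            _row(pid(), f"chr{n_chrom + 1}", 5_000_000 + i * 900, "", "open_sea",
                 set(), {"intergenic"}, cross=True)
        )
    for i in range(cfg.n_negative_controls):
        rows.append(
            _row(f"negctl{i:05d}", "", 0, "", "open_sea", set(), set(), neg=True)
        )
    for i in range(cfg.n_internal_controls):
        rows.append(
            _row(f"intctl{i:05d}", "", 0, "", "open_sea", set(), set(), internal=True)
        )

    manifest = ProbeManifest(pd.DataFrame(rows), islands)
    manifest.hypo_probe_ids = hypo_ids  # geometry detail consumed by the generator
    return manifest


def _row(
    probe_id, chrom, pos, island_id, region, genes, context,
    sex=False, cross=False, neg=False, internal=False,
) -> dict:
    return {
        "probe_id": probe_id,
        "chromosome": chrom,
        "position": pos,
        "island_id": island_id,
        "region_class": region,
        "gene_symbols": frozenset(genes),
        "feature_context": frozenset(context),
        "cross_reactive": cross,
        "is_sex_chromosome": sex,
        "is_negative_control": neg,
        "is_internal_control": internal,
    }


def hypo_block_probes(manifest: ProbeManifest) -> list[str]:
    """The open-sea probes carrying the planted hypomethylation block."""
    if hasattr(manifest, "hypo_probe_ids"):
        return list(manifest.hypo_probe_ids)
    t = manifest.table
    mask = (t["region_class"] == "open_sea") & t["feature_context"].apply(
        lambda s: "enhancer" in s
    )
    return t.index[mask].tolist()


# -- cohort -------------------------------------------------------------------

def generate_cohort(
    cfg: CohortConfig, manifest: ProbeManifest, seed: int | None = None
) -> tuple[IntensityDataset, SyntheticTruth]:
    """Draw a full intensity dataset plus its ground truth."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    table = manifest.table
    probes = table.index.to_numpy()
    P = len(probes)
    n_pairs = cfg.n_pairs

    sizes = cfg.group_sizes()
    subtypes = np.array(
        [CIMP_H] * sizes[CIMP_H] + [CIMP_L] * sizes[CIMP_L] + [CIMP_N] * sizes[CIMP_N]
    )
    rng.shuffle(subtypes)
    subjects = [f"S{i + 1:03d}" for i in range(n_pairs)]
    tumour_ids = [f"{s}_T" for s in subjects]
    normal_ids = [f"{s}_N" for s in subjects]
    n_candidates = [i for i, st in enumerate(subtypes) if st == CIMP_N]
    k = min(cfg.n_normal_like, len(n_candidates))
    normal_like_idx = sorted(
        rng.choice(n_candidates, size=k, replace=False).tolist()
    ) if k else []
    normal_like = [tumour_ids[i] for i in normal_like_idx]

    # -- baseline methylation -------------------------------------------------
    base_mean = np.select(
        [
            table["region_class"].isin(("island", "shore")).values,
            (table["region_class"] == "shelf").values,
        ],
        [cfg.normal_island_beta_mean, cfg.normal_shelf_beta_mean],
        default=cfg.normal_open_sea_beta_mean,
    )
    base_logit = logit(base_mean) + rng.normal(0, cfg.baseline_logit_sd, P)
    subject_effect = rng.normal(0, cfg.subject_logit_sd, (P, n_pairs))
    normal_target = np.clip(
        expit(base_logit[:, None] + subject_effect), BETA_FLOOR, BETA_CAP
    )

    # -- planted tumour shifts ------------------------------------------------
    genomic = table[~(table["is_negative_control"] | table["is_internal_control"])]
    gene_rows: dict[str, np.ndarray] = {}
    pos_of = {p: i for i, p in enumerate(probes)}
    keep = genomic[genomic["region_class"].isin(("island", "shore"))]
    for probe_id, genes in zip(keep["probe_id"], keep["gene_symbols"]):
        for g in genes:
            gene_rows.setdefault(g, []).append(pos_of[probe_id])
    gene_rows = {g: np.asarray(v) for g, v in gene_rows.items()}
    all_genes = sorted(gene_rows)
    core_genes = all_genes[: cfg.core_set_size]
    non_core = np.array(all_genes[cfg.core_set_size :])

    shift = np.zeros((P, n_pairs))
    background_events: dict[str, list[str]] = {}
    for j in range(n_pairs):
        tumour = tumour_ids[j]
        group = subtypes[j]
        if tumour in normal_like:
            background_events[tumour] = []
            continue
        if cfg.programme_delta_mean[group] > 0:
            lo, hi = cfg.programme_delta_bounds[group]
            deltas = np.clip(
                rng.normal(
                    cfg.programme_delta_mean[group],
                    cfg.programme_delta_sd[group],
                    len(core_genes),
                ),
                lo,
                hi,
            )
            for g, d in zip(core_genes, deltas):
                shift[gene_rows[g], j] += d
        mean_rate = cfg.background_rate_mean[group]
        if mean_rate > 0 and len(non_core):
            sigma = cfg.background_rate_sigma
            mu = np.log(mean_rate) - sigma**2 / 2
            count = int(min(round(rng.lognormal(mu, sigma)), len(non_core)))
            picked = sorted(rng.choice(non_core, size=count, replace=False).tolist())
            eff_sigma = cfg.background_effect_sigma[group]
            effs = np.clip(
                rng.lognormal(
                    np.log(cfg.background_effect_median[group]), eff_sigma, count
                ),
                *cfg.background_effect_bounds,
            )
            for g, e in zip(picked, effs):
                shift[gene_rows[g], j] += e
            background_events[tumour] = picked
        else:
            background_events[tumour] = []

    hypo_ids = hypo_block_probes(manifest)
    hypo_rows = np.array([pos_of[p] for p in hypo_ids], dtype=int)
    if len(hypo_rows) and cfg.hypo_depth_mean > 0:
        for j in range(n_pairs):
            if tumour_ids[j] in normal_like:
                continue
            depth = max(rng.normal(cfg.hypo_depth_mean, cfg.hypo_depth_sd), 0.0)
            shift[hypo_rows, j] -= depth

    tumour_target = np.clip(normal_target + shift, BETA_FLOOR, BETA_CAP)

    # -- batches --------------------------------------------------------------
    # stratified chip layout: pairs are dealt to chips round-robin within
    # subtype so no chip is enriched for one CIMP group (a balanced design;
    # batch correction cannot distinguish subtype composition from a true
    # chip effect, so confounding the two is avoided at the design stage)
    n_batches = -(-n_pairs // cfg.pairs_per_batch)
    order = sorted(range(n_pairs), key=lambda j: (str(subtypes[j]), j))
    batch_of_pair = [""] * n_pairs
    for slot, j in enumerate(order):
        batch_of_pair[j] = f"chip{slot % n_batches + 1:02d}"
    batch_levels = sorted(set(batch_of_pair))
    gamma = {}
    for b in batch_levels:
        mu_b = rng.normal(0, cfg.batch_shift_sd)
        gamma[b] = mu_b + rng.normal(0, cfg.batch_probe_sd, P)
    for j, b in enumerate(batch_of_pair):
        tumour_target[:, j] = np.clip(tumour_target[:, j] + gamma[b], BETA_FLOOR, BETA_CAP)
        normal_target[:, j] = np.clip(normal_target[:, j] + gamma[b], BETA_FLOOR, BETA_CAP)

    # -- measurement noise ----------------------------------------------------
    def measure(target: np.ndarray) -> np.ndarray:
        if cfg.noise_sd_logit == 0:
            return target.copy()
        noisy = expit(logit(target) + rng.normal(0, cfg.noise_sd_logit, target.shape))
        return np.clip(noisy, 1e-4, BETA_CAP)

    beta_t = measure(tumour_target)
    beta_n = measure(normal_target)

    sample_ids = []
    columns = []
    for j in range(n_pairs):
        sample_ids += [tumour_ids[j], normal_ids[j]]
        columns += [beta_t[:, j], beta_n[:, j]]
    beta_all = np.column_stack(columns)

    # -- intensities ----------------------------------------------------------
    total = np.maximum(
        rng.lognormal(np.log(cfg.intensity_scale), cfg.intensity_scale_sigma, beta_all.shape),
        cfg.intensity_scale_floor,
    )
    if (beta_all >= total / (total + 100.0)).any():
        raise ValueError("planted beta exceeds T/(T+100); lower the beta cap or raise T")
    M = beta_all * (total + 100.0)
    U = total - M

    is_internal = table["is_internal_control"].values
    is_negative = table["is_negative_control"].values
    n_samples = 2 * n_pairs
    ctl = 0.5 * cfg.intensity_scale * (
        1.0 + rng.normal(0, 0.02, (int(is_internal.sum()), n_samples))
    )
    M[is_internal] = ctl
    U[is_internal] = ctl
    M[is_negative] = rng.exponential(30.0, (int(is_negative.sum()), n_samples))
    U[is_negative] = rng.exponential(30.0, (int(is_negative.sum()), n_samples))

    scale = rng.lognormal(0, cfg.sample_scale_sigma, n_samples)
    M *= scale
    U *= scale

    # -- detection p ----------------------------------------------------------
    det = rng.uniform(0, 0.01, (P, n_samples))
    det[is_negative] = rng.uniform(0.2, 1.0, (int(is_negative.sum()), n_samples))
    genomic_rows = np.flatnonzero(~(is_internal | is_negative))
    n_fail = int(round(cfg.detection_failure_rate * len(genomic_rows)))
    if n_fail:
        failed = rng.choice(genomic_rows, size=n_fail, replace=False)
        which = rng.integers(0, n_samples, size=n_fail)
        det[failed, which] = rng.uniform(0.06, 0.5, n_fail)

    sheet = _sample_sheet(
        subjects, tumour_ids, normal_ids, subtypes, batch_of_pair, normal_like, rng
    )
    ds = IntensityDataset(
        M=pd.DataFrame(M, index=probes, columns=sample_ids),
        U=pd.DataFrame(U, index=probes, columns=sample_ids),
        detection_p=pd.DataFrame(det, index=probes, columns=sample_ids),
        sample_sheet=sheet,
    )
    truth = SyntheticTruth(
        core_genes=list(core_genes),
        subtype={tumour_ids[j]: str(subtypes[j]) for j in range(n_pairs)},
        background_events=background_events,
        normal_like_tumours=list(normal_like),
        hypo_probes=list(hypo_ids),
        batch={s: batch_of_pair[j] for j in range(n_pairs) for s in (tumour_ids[j], normal_ids[j])},
        config=cfg.to_dict(),
    )
    return ds, truth


#: clinical covariate rates per subtype used for the generated sample sheet;
#: chosen to echo typical CIMP-subtype associations (BRAF and proximal
#: location enriched in CIMP-H, KRAS in CIMP-L).
CLINICAL_RATES = {
    CIMP_H: {"braf": 0.54, "kras": 0.19, "msi": 0.35, "proximal": 0.81,
             "panel": 0.90, "age": (73.6, 7.7)},
    CIMP_L: {"braf": 0.00, "kras": 0.50, "msi": 0.10, "proximal": 0.70,
             "panel": 0.40, "age": (69.2, 11.0)},
    CIMP_N: {"braf": 0.08, "kras": 0.16, "msi": 0.16, "proximal": 0.49,
             "panel": 0.05, "age": (69.0, 12.3)},
}


def _sample_sheet(
    subjects, tumour_ids, normal_ids, subtypes, batch_of_pair, normal_like, rng
) -> SampleSheet:
    rows = []
    for j, subject in enumerate(subjects):
        group = CIMP_N if tumour_ids[j] in normal_like else str(subtypes[j])
        rates = CLINICAL_RATES[group]
        flags = [bool(rng.random() < rates["panel"]) for _ in PANEL_GENES]
        clinical = {
            "age": float(np.round(rng.normal(*rates["age"]), 1)),
            "location": "proximal" if rng.random() < rates["proximal"] else "distal",
            "braf_mutant": bool(rng.random() < rates["braf"]),
            "kras_mutant": bool(rng.random() < rates["kras"]),
            "msi": bool(rng.random() < rates["msi"]),
            **{f"panel_{g}": f for g, f in zip(PANEL_GENES, flags)},
            "panel_cimp": panel_cimp_classify(flags),
        }
        rows.append(
            {"sample_id": tumour_ids[j], "subject_id": subject, "tissue": "tumour",
             "batch": batch_of_pair[j], **clinical}
        )
        rows.append(
            {"sample_id": normal_ids[j], "subject_id": subject, "tissue": "normal",
             "batch": batch_of_pair[j]}
        )
    return SampleSheet(pd.DataFrame(rows))


def generate_default_cohort(
    seed: int = 0, **overrides
) -> tuple[CohortConfig, ProbeManifest, IntensityDataset, SyntheticTruth]:
    """Standard cohort: 40 pairs, 2000 genes, planted core of 132."""
    cfg = CohortConfig(seed=seed, **overrides)
    manifest = generate_manifest(cfg)
    ds, truth = generate_cohort(cfg, manifest)
    return cfg, manifest, ds, truth


def write_cohort(out_dir, manifest: ProbeManifest, ds: IntensityDataset, truth: SyntheticTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_files(out / "manifest.tsv", out / "islands.tsv")
    ds.to_dir(out)
    truth.to_json(out / "truth.json")
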