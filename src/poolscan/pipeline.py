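"""End-to-end experiment orchestration from a single config + master seed.

Two experiments are supported: ``fig1_power`` (pool-seq case-control power
sweep over a coverage x effect grid) and ``xqtl_compare`` (synthetic
known-founder selection experiment scanned three ways).  Every stage draws
its randomness from a seed derived deterministically from the master seed
and a stage label, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as pdata
from .data import FounderPanel, GeneticMap, ValidationError
from .haplotypes import (
    define_windows,
    impute_snp_freqs,
    infer_haplotype_track,
)
from .neutral import simulate_neutral_haplotypes, subsample_panel
from .powersim import run_power_sweep, simulate_one_experiment, PoolDesign
from .scans import compare_scans, scan_direct_snp, scan_haplotype, scan_imputed_snp
from .xqtl import ExperimentDesign, QTLSpec, XQTLDataset, generate_xqtl_dataset

__all__ = [
    "Fig1Config",
    "XQTLConfig",
    "ExperimentConfig",
    "derive_stage_seed",
    "run_fig1",
    "build_xqtl_inputs",
    "run_xqtl_compare",
    "treatment_frequency_rmse",
    "load_config",
]

FLOAT_FMT = "%.10g"


def derive_stage_seed(master_seed: int, stage_label: str, replicate_index: int = 0) -> int:
    """Stable substream seed: pure function of (master seed, label, index)."""
    key = f"{int(master_seed)}:{stage_label}:{int(replicate_index)}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def _strict(cls, mapping: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValidationError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class Fig1Config:
    """Power-sweep experiment parameters (defaults mirror the simulated
    case-control design: 10,000-haplotype pools, 400/1,000/5,000x coverage,
    4%/8% focal shifts, a -log10 p = 5 call threshold)."""

    n_haplotypes: int = 500
    region_bp: float = 1_000_000
    N_e: float = 1e6
    mu: float = 5e-9
    rec: float = 2e-8
    maf_min: float = 0.05
    max_sites: int | None = None
    pool_size: int = 10_000
    coverages: tuple = (400.0, 1_000.0, 5_000.0)
    deltas: tuple = (0.04, 0.08)
    replicates: int = 20
    threshold: float = 5.0
    focal_maf_lo: float = 0.30
    focal_maf_hi: float = 0.70


@dataclass
class XQTLConfig:
    """Synthetic X-QTL experiment parameters.

    Defaults give a desk-scale analogue of a 12-replicate selection
    experiment: per-replicate pools of 400 control / 285 case diploids
    (totals ~4,800/3,420), treatment-aggregate coverage ~983x/739x split
    evenly across replicates, 8 founders, one planted QTL.
    """

    n_founders: int = 8
    region_bp: float = 400_000
    N_e: float = 1e6
    mu: float = 5e-9
    rec: float = 2e-8
    maf_min: float = 0.05
    max_sites: int | None = 20_000
    map_length_cM: float = 100.0
    generations: int = 33
    n_replicates: int = 12
    n_control: int = 400
    n_case: int = 285
    selection_fraction: float = 0.07
    coverage_control_total: float = 983.0
    coverage_case_total: float = 739.0
    double_control_replicates: tuple = (5, 6, 8, 11, 12)
    qtl_cM: float = 50.0
    favored_founder: int = 0
    qtl_effect: float = 0.25
    env_sd: float = 1.0
    width_cM: float = 1.5
    step_cM: float = 0.25
    min_coverage: int = 10
    efficiency_k: float = 1.0
    threshold: float = 5.0
    window_cM: float = 1.5
    cluster_radius_cM: float = 1.0
    cmh_variant: str = "classical"

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            n_replicates=self.n_replicates,
            n_control=self.n_control,
            n_case=self.n_case,
            selection_fraction=self.selection_fraction,
            coverage_control=self.coverage_control_total / self.n_replicates,
            coverage_case=self.coverage_case_total / self.n_replicates,
            efficiency_k=self.efficiency_k,
            double_control_replicates=tuple(self.double_control_replicates),
        )


@dataclass
class ExperimentConfig:
    experiment: str = "xqtl_compare"
    fig1: Fig1Config = field(default_factory=Fig1Config)
    xqtl: XQTLConfig = field(default_factory=XQTLConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        experiment = d.pop("experiment", "xqtl_compare")
        if experiment not in ("fig1_power", "xqtl_compare"):
            raise ValidationError(f"unknown experiment {experiment!r}")
        fig1 = _strict(Fig1Config, d.pop("fig1", {}), "fig1")
        xqtl = _strict(XQTLConfig, d.pop("xqtl", {}), "xqtl")
        if d:
            raise ValidationError(f"unknown top-level key(s): {sorted(d)}")
        return cls(experiment=experiment, fig1=fig1, xqtl=xqtl)

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(
            {
                "experiment": self.experiment,
                "fig1": dataclasses.asdict(self.fig1),
                "xqtl": dataclasses.asdict(self.xqtl),
            }
        )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    return ExperimentConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# fig1_power
# ---------------------------------------------------------------------------


def run_fig1(cfg: Fig1Config, master_seed: int, outdir) -> pd.DataFrame:
    """Run the power sweep; write per-cell example scans and a summary TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_neutral_haplotypes(
        n=cfg.n_haplotypes, L=cfg.region_bp, N_e=cfg.N_e, u=cfg.mu, r=cfg.rec,
        seed=derive_stage_seed(master_seed, "fig1_panel"),
    )
    panel = subsample_panel(
        panel, maf_min=cfg.maf_min, max_sites=cfg.max_sites,
        seed=derive_stage_seed(master_seed, "fig1_thin"),
    )
    maf_range = (cfg.focal_maf_lo, cfg.focal_maf_hi)
    for cov in cfg.coverages:
        for delta in cfg.deltas:
            design = PoolDesign(
                M=cfg.pool_size, expected_coverage=float(cov),
                delta_p=float(delta), focal_maf_range=maf_range,
            )
            scan, focal = simulate_one_experiment(
                panel, design,
                derive_stage_seed(master_seed, f"fig1_example_{cov}_{delta}"),
            )
            scan = scan.assign(is_focal=np.arange(len(scan)) == focal)
            scan.to_csv(
                outdir / f"scan_cov{cov:g}_delta{delta:g}.tsv",
                sep="\t", index=False, float_format=FLOAT_FMT,
            )
    power = run_power_sweep(
        panel,
        coverages=cfg.coverages,
        deltas=cfg.deltas,
        n_replicates=cfg.replicates,
        threshold=cfg.threshold,
        M=cfg.pool_size,
        focal_maf_range=maf_range,
        seed=derive_stage_seed(master_seed, "fig1_power"),
    )
    power.to_csv(outdir / "power_summary.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return power


# ---------------------------------------------------------------------------
# xqtl_compare
# ---------------------------------------------------------------------------


def build_xqtl_inputs(
    cfg: XQTLConfig, master_seed: int
) -> tuple[FounderPanel, GeneticMap, QTLSpec]:
    """Founder panel (from a neutral coalescent), linear genetic map, and the
    planted QTL derived from the config."""
    hap = simulate_neutral_haplotypes(
        n=cfg.n_founders, L=cfg.region_bp, N_e=cfg.N_e, u=cfg.mu, r=cfg.rec,
        seed=derive_stage_seed(master_seed, "founders"),
    )
    hap = subsample_panel(
        hap, maf_min=cfg.maf_min, max_sites=cfg.max_sites,
        seed=derive_stage_seed(master_seed, "founder_thin"),
    )
    panel = hap.to_founder_panel()
    gmap = GeneticMap(
        {str(panel.chrom[0]): (
            np.array([1, int(cfg.region_bp)]),
            np.array([0.0, cfg.map_length_cM]),
        )}
    )
    panel.attach_map(gmap)
    if not 0 <= cfg.favored_founder < cfg.n_founders:
        raise ValidationError("favored_founder out of range")
    effects = np.zeros(cfg.n_founders)
    effects[cfg.favored_founder] = cfg.qtl_effect
    qtl = QTLSpec(
        chrom=str(panel.chrom[0]),
        position_bp=int(round(gmap.inverse(str(panel.chrom[0]), cfg.qtl_cM))),
        founder_effects=effects,
        env_sd=cfg.env_sd,
    )
    return panel, gmap, qtl


def generate_xqtl(cfg: XQTLConfig, master_seed: int) -> XQTLDataset:
    panel, gmap, qtl = build_xqtl_inputs(cfg, master_seed)
    return generate_xqtl_dataset(
        design=cfg.design(), panel=panel, qtl=qtl,
        generations=cfg.generations, gmap=gmap,
        seed=derive_stage_seed(master_seed, "xqtl_dataset"),
    )


def write_xqtl_dataset(ds: XQTLDataset, outdir) -> None:
    """Materialize the dataset as plain-text TSV/SYNC files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = pd.DataFrame({"chrom": ds.panel.chrom, "pos": ds.panel.positions_bp})
    pdata.write_counts_table(
        sites, ds.pools, outdir / "counts.tsv", outdir / "samples.tsv"
    )
    pdata.write_founder_panel(ds.panel, outdir / "founders.tsv")
    pdata.write_genetic_map(ds.gmap, outdir / "map.tsv")
    truth = sites.copy()
    for sid, freqs in ds.truth_snp.items():
        truth[sid] = freqs
    truth.to_csv(outdir / "truth_snp.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    hap_rows = []
    for sid, hf in ds.truth_hap.items():
        for j, fid in enumerate(ds.panel.founder_ids):
            hap_rows.append([sid, fid] + list(hf[j]))
    pd.DataFrame(hap_rows).to_csv(
        outdir / "truth_hap.tsv", sep="\t", index=False, header=False,
        float_format=FLOAT_FMT,
    )
    ds.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False, float_format=FLOAT_FMT)


def treatment_frequency_rmse(ds: XQTLDataset, imputed: dict[str, np.ndarray]) -> pd.DataFrame:
    """Genome-wide RMSE against truth of direct vs imputed frequencies.

    Estimates and truth are aggregated to treatment level (read counts and
    truth frequencies summed / individual-weighted across all pools of a
    treatment), mirroring a per-treatment comparison at the aggregate
    coverage.
    """
    rows = []
    S = ds.panel.n_sites
    for treatment in ("case", "control"):
        pools = [p for p in ds.pools if p.treatment == treatment]
        ref = np.zeros(S)
        alt = np.zeros(S)
        truth_w = np.zeros(S)
        imp_w = np.zeros(S)
        total_n = 0
        for p in pools:
            ref += p.ref_count
            alt += p.alt_count
            truth_w += ds.truth_snp[p.sample_id] * p.n_individuals
            imp_w += imputed[p.sample_id] * p.n_individuals
            total_n += p.n_individuals
        truth = truth_w / total_n
        imp = imp_w / total_n
        cov = ref + alt
        ok = cov > 0
        direct = np.where(ok, alt / np.maximum(cov, 1), np.nan)
        rows.append(
            {
                "treatment": treatment,
                "n_sites": int(ok.sum()),
                "mean_coverage": float(cov.mean()),
                "rmse_direct": float(np.sqrt(np.nanmean((direct - truth) ** 2))),
                "rmse_imputed": float(np.sqrt(np.mean((imp[ok] - truth[ok]) ** 2))),
            }
        )
    return pd.DataFrame(rows)


def run_xqtl_compare(cfg: XQTLConfig, master_seed: int, outdir) -> dict:
    """Generate the dataset, infer haplotypes, run all three scans, and write
    scan + comparison + accuracy TSVs.  Returns the in-memory results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_xqtl(cfg, master_seed)
    write_xqtl_dataset(ds, outdir / "dataset")
    windows = define_windows(ds.gmap, ds.panel, cfg.width_cM, cfg.step_cM)
    track = infer_haplotype_track(ds.pools, ds.panel, windows, cfg.min_coverage)
    imputed = impute_snp_freqs(track, ds.panel)

    scans = {
        "direct_snp": scan_direct_snp(ds.pools, ds.panel, variant=cfg.cmh_variant),
        "haplotype": scan_haplotype(track, cfg.efficiency_k, variant=cfg.cmh_variant),
        "imputed_snp": scan_imputed_snp(
            imputed, track, ds.panel, cfg.efficiency_k, variant=cfg.cmh_variant
        ),
    }
    for name, scan in scans.items():
        scan.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    qtl_cM = ds.gmap.interpolate(ds.qtl.chrom, ds.qtl.position_bp)
    comparison = compare_scans(
        scans, ds.qtl.chrom, qtl_cM,
        window_cM=cfg.window_cM, threshold=cfg.threshold,
        cluster_radius_cM=cfg.cluster_radius_cM,
    )
    comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    rmse = treatment_frequency_rmse(ds, imputed)
    rmse.to_csv(outdir / "frequency_rmse.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    log = {
        "master_seed": int(master_seed),
        "qtl_chrom": ds.qtl.chrom,
        "qtl_bp": int(ds.qtl.position_bp),
        "qtl_cM": float(qtl_cM),
        "n_sites": int(ds.panel.n_sites),
        "n_windows": len(windows),
        "n_pools": len(ds.pools),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return {
        "dataset": ds,
        "track": track,
        "imputed": imputed,
        "scans": scans,
        "comparison": comparison,
        "rmse": rmse,
        "qtl_cM": float(qtl_cM),
    }
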