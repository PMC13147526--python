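"""Synthetic known-founder advanced-intercross (X-QTL) dataset generator.

An individual genome is a pair of founder mosaics produced by a one-shot
Poisson-breakpoint model: after G generations of random mating the haploid
breakpoint count is ~Poisson(G * map length in Morgans) with breakpoints
uniform on the cM scale.  A planted QTL assigns a liability-scale phenotype;
cases are truncation-selected, controls sampled at random, and both pools are
pool-sequenced in silico with overdispersed coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FounderPanel, GeneticMap, PoolCounts, ValidationError
from .powersim import simulate_poolseq_counts

__all__ = [
    "MosaicGenome",
    "QTLSpec",
    "ExperimentDesign",
    "simulate_mosaics",
    "assign_phenotypes",
    "truncation_select",
    "pool_truth",
    "generate_xqtl_dataset",
    "XQTLDataset",
]


@dataclass
class MosaicGenome:
    """One haploid genome as (start_bp, end_bp, founder_index) segments that
    tile a chromosome; stored as breakpoint ends + per-segment labels."""

    chrom: str
    seg_end_bp: np.ndarray  # sorted segment end positions; last = chrom end
    seg_founder: np.ndarray  # int founder index per segment

    def __post_init__(self) -> None:
        self.seg_end_bp = np.asarray(self.seg_end_bp, dtype=np.int64)
        self.seg_founder = np.asarray(self.seg_founder, dtype=np.int16)
        if self.seg_end_bp.size != self.seg_founder.size:
            raise ValidationError("segment arrays length mismatch")
        if np.any(np.diff(self.seg_end_bp) <= 0):
            raise ValidationError("segment ends must be strictly increasing")

    @property
    def n_breakpoints(self) -> int:
        return int(self.seg_end_bp.size - 1)

    def segments(self, start_bp: int = 1) -> list[tuple[int, int, int]]:
        out, s = [], start_bp
        for e, f in zip(self.seg_end_bp, self.seg_founder):
            out.append((s, int(e), int(f)))
            s = int(e) + 1
        return out

    def founder_at(self, positions_bp: np.ndarray) -> np.ndarray:
        """Founder index at each queried position."""
        idx = np.searchsorted(self.seg_end_bp, positions_bp, side="left")
        return self.seg_founder[idx]


@dataclass
class QTLSpec:
    """A single additive QTL: per-founder effects on a liability scale."""

    chrom: str
    position_bp: int
    founder_effects: np.ndarray
    env_sd: float = 1.0

    def __post_init__(self) -> None:
        self.founder_effects = np.asarray(self.founder_effects, dtype=float)
        if not np.any(self.founder_effects != 0):
            raise ValidationError("QTL needs at least one nonzero founder effect")
        if self.env_sd < 0:
            raise ValidationError("env_sd must be >= 0")


@dataclass
class ExperimentDesign:
    """Replicate/pool structure of the selection experiment."""

    n_replicates: int = 12
    n_control: int = 400  # diploid individuals per control pool set
    n_case: int = 285
    selection_fraction: float = 0.07
    coverage_control: float = 983.0 / 12  # expected coverage per control pool set
    coverage_case: float = 739.0 / 12
    efficiency_k: float = 1.0
    double_control_replicates: tuple[int, ...] = ()  # replicate ids with 2 control pools

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")
        if min(self.n_control, self.n_case) < 1:
            raise ValidationError("pool sizes must be >= 1")
        if not 0 < self.selection_fraction < 1:
            raise ValidationError("selection_fraction must be in (0, 1)")
        if not 0 < self.efficiency_k <= 1:
            raise ValidationError("efficiency_k must be in (0, 1]")
        if min(self.coverage_control, self.coverage_case) <= 0:
            raise ValidationError("coverages must be positive")
        bad = [r for r in self.double_control_replicates if not 1 <= r <= self.n_replicates]
        if bad:
            raise ValidationError(f"double-control replicate ids out of range: {bad}")


def _simulate_haploid_mosaics(
    n: int, chrom: str, gmap: GeneticMap, G: int, n_founders: int, rng: np.random.Generator
) -> list[MosaicGenome]:
    abp, acm = gmap.anchors[chrom]
    cm_lo, cm_hi = float(acm[0]), float(acm[-1])
    morgans = (cm_hi - cm_lo) / 100.0
    end_bp = int(abp[-1])
    lam = G * morgans
    n_breaks = rng.poisson(lam, size=n)
    out = []
    for nb in n_breaks:
        if nb:
            bp_cm = np.sort(rng.uniform(cm_lo, cm_hi, size=nb))
            bps = np.unique(np.asarray(gmap.inverse(chrom, bp_cm), dtype=np.int64))
            bps = bps[(bps >= 1) & (bps < end_bp)]
        else:
            bps = np.zeros(0, dtype=np.int64)
        ends = np.concatenate([bps, [end_bp]])
        labels = rng.integers(0, n_founders, size=ends.size)
        out.append(MosaicGenome(chrom=chrom, seg_end_bp=ends, seg_founder=labels))
    return out


def simulate_mosaics(
    panel: FounderPanel,
    n_individuals: int,
    generations: int,
    gmap: GeneticMap,
    seed: int,
) -> list[tuple[MosaicGenome, MosaicGenome]]:
    """Diploid mosaic genomes for ``n_individuals`` (two independent haploids
    each).  Multi-chromosome panels are not supported here; the synthetic
    dataset uses one chromosome."""
    if generations < 1:
        raise ValidationError("generations must be >= 1")
    chroms = np.unique(panel.chrom.astype(str))
    if chroms.size != 1:
        raise ValidationError("simulate_mosaics expects a single-chromosome panel")
    chrom = str(chroms[0])
    if chrom not in gmap.anchors:
        raise ValidationError(f"map lacks chromosome {chrom!r}")
    abp = gmap.anchors[chrom][0]
    if panel.positions_bp[0] < abp[0] or panel.positions_bp[-1] > abp[-1]:
        raise ValidationError("genetic map does not span the panel")
    rng = np.random.default_rng(seed)
    haploids = _simulate_haploid_mosaics(
        2 * n_individuals, chrom, gmap, generations, panel.n_founders, rng
    )
    return [(haploids[2 * i], haploids[2 * i + 1]) for i in range(n_individuals)]


def assign_phenotypes(
    individuals: list[tuple[MosaicGenome, MosaicGenome]],
    qtl: QTLSpec,
    seed: int,
) -> np.ndarray:
    """Liability phenotype: sum of the two haploid founder effects at the QTL
    plus Gaussian(0, env_sd) noise."""
    pos = np.array([qtl.position_bp], dtype=np.int64)
    geno = np.empty(len(individuals))
    for i, (h1, h2) in enumerate(individuals):
        geno[i] = (
            qtl.founder_effects[int(h1.founder_at(pos)[0])]
            + qtl.founder_effects[int(h2.founder_at(pos)[0])]
        )
    rng = np.random.default_rng(seed)
    return geno + rng.normal(0.0, qtl.env_sd, size=len(individuals))


def truncation_select(phenotypes: np.ndarray, q: float, seed: int) -> np.ndarray:
    """Indices of the ceil(q*n) largest phenotypes; ties broken by a seeded
    random permutation."""
    if not 0 < q < 1:
        raise ValidationError("selection fraction must be in (0, 1)")
    phen = np.asarray(phenotypes, dtype=float)
    n_sel = int(np.ceil(q * phen.size - 1e-9))  # guard fp noise in q*n
    n_sel = max(n_sel, 1)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(phen.size)
    order = np.lexsort((tiebreak, -phen))
    return np.sort(order[:n_sel])


def pool_truth(
    individuals: list[tuple[MosaicGenome, MosaicGenome]],
    panel: FounderPanel,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-site (snp_freqs, hap_freqs) bookkeeping for a pool.

    hap_freqs is F x S founder-label proportions among the 2N haploids;
    snp_freqs[s] = sum_j hap_freqs[j, s] * h[s, j] (missing founder states
    propagate NaN at their sites).
    """
    if not individuals:
        raise ValidationError("empty pool")
    S, F = panel.n_sites, panel.n_founders
    counts = np.zeros((F, S), dtype=np.int32)
    cols = np.arange(S)
    for h1, h2 in individuals:
        counts[h1.founder_at(panel.positions_bp), cols] += 1
        counts[h2.founder_at(panel.positions_bp), cols] += 1
    hap_freqs = counts / (2.0 * len(individuals))
    snp_freqs = np.einsum("js,sj->s", hap_freqs, panel.matrix)
    return snp_freqs, hap_freqs


def allele_count_bookkeeping(
    control_total: int,
    case_total: int,
    coverage_control: float,
    coverage_case: float,
) -> dict:
    """Sample-size bookkeeping for a two-treatment pooled design.

    The per-treatment autosomal allele count is twice the mean of the two
    treatment pool totals (mean rounded to the nearest ten); the fold-ratio
    divides that allele count by the mean treatment-level sequence coverage
    and rounds to the nearest integer.
    """
    if min(control_total, case_total) < 1:
        raise ValidationError("pool totals must be positive")
    if min(coverage_control, coverage_case) <= 0:
        raise ValidationError("coverages must be positive")
    mean_pool = (control_total + case_total) / 2.0
    mean_pool_rounded = int(round(mean_pool / 10.0) * 10)
    alleles = 2 * mean_pool_rounded
    mean_coverage = (coverage_control + coverage_case) / 2.0
    return {
        "mean_pool_size": mean_pool,
        "mean_pool_size_rounded": mean_pool_rounded,
        "alleles_per_treatment": alleles,
        "mean_coverage": mean_coverage,
        "fold_ratio": int(round(alleles / mean_coverage)),
    }


@dataclass
class XQTLDataset:
    """Everything generate_xqtl_dataset produces."""

    panel: FounderPanel
    gmap: GeneticMap
    qtl: QTLSpec
    design: ExperimentDesign
    pools: list[PoolCounts]
    truth_snp: dict[str, np.ndarray]  # sample_id -> per-site true ALT freq
    truth_hap: dict[str, np.ndarray]  # sample_id -> F x S true founder freq
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_xqtl_dataset(
    design: ExperimentDesign,
    panel: FounderPanel,
    qtl: QTLSpec,
    generations: int,
    gmap: GeneticMap,
    seed: int,
) -> XQTLDataset:
    """Simulate the full replicated selection experiment.

    Per replicate an independent cohort of ``ceil(n_case / q)`` individuals is
    simulated; cases are the top ``q`` fraction by phenotype (trimmed to
    ``n_case``), controls an unselected random draw of ``n_control``
    individuals.  Replicates listed in ``design.double_control_replicates``
    split their control individuals into two equally sized pools whose
    expected coverage halves.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pools: list[PoolCounts] = []
    truth_snp: dict[str, np.ndarray] = {}
    truth_hap: dict[str, np.ndarray] = {}
    meta_rows = []
    cohort_n = int(np.ceil(design.n_case / design.selection_fraction))
    cohort_n = max(cohort_n, design.n_control)
    for rep in range(1, design.n_replicates + 1):
        s = rng.integers(0, 2**63, size=8)
        cohort = simulate_mosaics(panel, cohort_n, generations, gmap, int(s[0]))
        phen = assign_phenotypes(cohort, qtl, int(s[1]))
        sel = truncation_select(phen, design.selection_fraction, int(s[2]))
        rng_rep = np.random.default_rng(int(s[3]))
        case_idx = rng_rep.permutation(sel)[: design.n_case]
        control_idx = rng_rep.choice(cohort_n, size=design.n_control, replace=False)

        case_pool = [cohort[i] for i in case_idx]
        sid = f"rep{rep:02d}_case"
        snp_f, hap_f = pool_truth(case_pool, panel)
        truth_snp[sid], truth_hap[sid] = snp_f, hap_f
        pools.append(
            simulate_poolseq_counts(
                snp_f, design.coverage_case, int(s[4]), sample_id=sid,
                treatment="case", replicate=rep, n_individuals=len(case_pool),
            )
        )
        meta_rows.append((sid, "case", rep, len(case_pool), design.coverage_case))

        if rep in design.double_control_replicates:
            half = design.n_control // 2
            splits = [control_idx[:half], control_idx[half:]]
        else:
            splits = [control_idx]
        for ci, idx in enumerate(splits, start=1):
            suffix = f"_{ci}" if len(splits) > 1 else ""
            sid = f"rep{rep:02d}_control{suffix}"
            sub = [cohort[i] for i in idx]
            snp_f, hap_f = pool_truth(sub, panel)
            truth_snp[sid], truth_hap[sid] = snp_f, hap_f
            cov = design.coverage_control / len(splits)
            pools.append(
                simulate_poolseq_counts(
                    snp_f, cov, int(s[4 + ci]), sample_id=sid,
                    treatment="control", replicate=rep, n_individuals=len(sub),
                )
            )
            meta_rows.append((sid, "control", rep, len(sub), cov))
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "treatment", "replicate", "n_individuals", "expected_coverage"],
    )
    return XQTLDataset(
        panel=panel, gmap=gmap, qtl=qtl, design=design, pools=pools,
        truth_snp=truth_snp, truth_hap=truth_hap, metadata=metadata,
    )
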