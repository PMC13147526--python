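"""Pool-seq case-control power simulation.

Builds large case/control haplotype pools that differ only at one focal SNP,
pool-sequences them in silico with overdispersed coverage, and scans each
site with a 2x2 Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import PoolCounts, ValidationError, make_scan_frame
from .neutral import HaplotypePanel

__all__ = [
    "PoolDesign",
    "expand_to_control_pool",
    "pool_frequencies",
    "select_focal_snp",
    "sample_case_pool_conditional",
    "simulate_poolseq_counts",
    "chisq_scan",
    "run_power_sweep",
]


@dataclass
class PoolDesign:
    """One cell of the power-simulation grid."""

    M: int = 10_000  # haplotypes per pool (2N of pooled individuals)
    expected_coverage: float = 1_000.0
    delta_p: float = 0.08
    focal_maf_range: tuple[float, float] = (0.30, 0.70)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValidationError("pool must hold at least 2 haplotypes")
        if self.expected_coverage <= 0:
            raise ValidationError("expected_coverage must be positive")
        if not 0 <= self.delta_p < 1:
            raise ValidationError("delta_p must be in [0, 1)")
        lo, hi = self.focal_maf_range
        if not 0 < lo < hi < 1:
            raise ValidationError("focal_maf_range must satisfy 0 < lo < hi < 1")


def expand_to_control_pool(panel: HaplotypePanel, M: int, seed: int) -> np.ndarray:
    """Draw ``M`` haplotype indices uniformly with replacement from the panel."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, panel.n_haplotypes, size=M)


def pool_frequencies(pool: np.ndarray, panel: HaplotypePanel) -> np.ndarray:
    """Exact ALT frequency at every site in a pool of haplotype indices."""
    weights = np.bincount(pool, minlength=panel.n_haplotypes).astype(float)
    return weights @ panel.haplotypes / pool.size


def select_focal_snp(
    panel: HaplotypePanel, focal_maf_range: tuple[float, float], seed: int
) -> int:
    """Uniformly random site whose panel MAF lies in the closed range."""
    lo, hi = focal_maf_range
    ok = np.where((panel.maf >= lo) & (panel.maf <= hi))[0]
    if ok.size == 0:
        raise ValidationError(f"no site with MAF in [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    return int(rng.choice(ok))


def sample_case_pool_conditional(
    control_pool: np.ndarray,
    panel: HaplotypePanel,
    focal_site: int,
    delta_p: float,
    seed: int,
    direction: int = +1,
) -> np.ndarray:
    """Resample a case pool from the control pool conditional on the focal SNP.

    The case pool has the same size M and a focal ALT count of exactly
    ``round((p_control + direction*delta_p) * M)``; within each focal-allele
    class haplotypes are drawn uniformly with replacement from that class of
    the control pool, so non-focal sites shift only through hitchhiking.
    """
    M = control_pool.size
    focal_alleles = panel.haplotypes[control_pool, focal_site]
    alt_idx = control_pool[focal_alleles == 1]
    ref_idx = control_pool[focal_alleles == 0]
    p_control = alt_idx.size / M
    target = p_control + direction * delta_p
    if not 0.0 <= target <= 1.0:
        raise ValidationError(
            f"target focal frequency {target:.4f} outside [0, 1]"
        )
    n_alt = int(round(target * M))
    if n_alt > 0 and alt_idx.size == 0:
        raise ValidationError("control pool carries no ALT haplotype at the focal site")
    if n_alt < M and ref_idx.size == 0:
        raise ValidationError("control pool carries no REF haplotype at the focal site")
    rng = np.random.default_rng(seed)
    picks = []
    if n_alt:
        picks.append(rng.choice(alt_idx, size=n_alt, replace=True))
    if M - n_alt:
        picks.append(rng.choice(ref_idx, size=M - n_alt, replace=True))
    case = np.concatenate(picks)
    rng.shuffle(case)
    return case


def simulate_poolseq_counts(
    true_freqs: np.ndarray,
    expected_coverage: float,
    seed: int,
    sample_id: str = "pool",
    treatment: str = "control",
    replicate: int = 1,
    n_individuals: int = 1,
) -> PoolCounts:
    """Draw pool-seq REF/ALT counts conditional on known frequencies.

    Per-site total coverage is negative binomial with size = mean =
    ``expected_coverage`` (variance twice the mean); the ALT count is
    binomial(coverage, true frequency).
    """
    if expected_coverage <= 0:
        raise ValidationError("expected_coverage must be positive")
    freqs = np.asarray(true_freqs, dtype=float)
    if np.any((freqs < -1e-9) | (freqs > 1 + 1e-9)):
        raise ValidationError("true frequencies must lie in [0, 1]")
    freqs = np.clip(freqs, 0.0, 1.0)  # absorb fp round-off from exact bookkeeping
    rng = np.random.default_rng(seed)
    size = expected_coverage
    # NB(n=size, p=size/(size+mu)) has mean mu and variance mu + mu^2/size
    coverage = rng.negative_binomial(size, 0.5, size=freqs.size)
    alt = rng.binomial(coverage, freqs)
    return PoolCounts(
        sample_id=sample_id,
        treatment=treatment,
        replicate=replicate,
        n_individuals=n_individuals,
        ref_count=(coverage - alt).astype(np.int64),
        alt_count=alt.astype(np.int64),
    )


def pearson_chi2_2x2(a, b, c, d):
    """Vectorized 2x2 Pearson chi-square without continuity correction.

    Cells are [[a, b], [c, d]] (rows: case/control; cols: REF/ALT).  Tables
    with a zero row or column margin get statistic 0, p 1.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    total = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(denom > 0, total * (a * d - b * c) ** 2 / denom, 0.0)
    p = np.where(denom > 0, stats.chi2.sf(stat, 1), 1.0)
    return stat, p


def chisq_scan(case: PoolCounts, control: PoolCounts, panel=None) -> pd.DataFrame:
    """Per-site 2x2 chi-square (REF/ALT x case/control) over matched sites."""
    if case.n_sites != control.n_sites:
        raise ValidationError("case/control site vectors differ in length")
    stat, p = pearson_chi2_2x2(
        case.ref_count, case.alt_count, control.ref_count, control.alt_count
    )
    pos = panel.positions_bp if panel is not None else np.arange(case.n_sites)
    chrom = (
        np.full(case.n_sites, panel.chrom, dtype=object)
        if panel is not None
        else np.full(case.n_sites, "sim1", dtype=object)
    )
    return make_scan_frame(
        chrom=chrom,
        locus_id=np.arange(case.n_sites),
        pos_bp=pos,
        cM=np.full(case.n_sites, np.nan),
        statistic=stat,
        df=np.ones(case.n_sites, dtype=int),
        p_value=p,
        scan_type="direct_snp",
    )


def simulate_one_experiment(
    panel: HaplotypePanel, design: PoolDesign, seed: int
) -> tuple[pd.DataFrame, int]:
    """One case-control realization; returns (scan table, focal site index)."""
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2**63, size=5)
    control = expand_to_control_pool(panel, design.M, int(s[0]))
    focal = select_focal_snp(panel, design.focal_maf_range, int(s[1]))
    case = sample_case_pool_conditional(
        control, panel, focal, design.delta_p, int(s[2])
    )
    f_control = pool_frequencies(control, panel)
    f_case = pool_frequencies(case, panel)
    counts_control = simulate_poolseq_counts(
        f_control, design.expected_coverage, int(s[3]), "control", "control"
    )
    counts_case = simulate_poolseq_counts(
        f_case, design.expected_coverage, int(s[4]), "case", "case"
    )
    return chisq_scan(counts_case, counts_control, panel), focal


def run_power_sweep(
    panel: HaplotypePanel,
    coverages,
    deltas,
    n_replicates: int,
    threshold: float = 5.0,
    M: int = 10_000,
    focal_maf_range: tuple[float, float] = (0.30, 0.70),
    seed: int = 0,
) -> pd.DataFrame:
    """Power table over the coverage x delta grid.

    Per cell: fraction of replicates where the focal SNP's -log10 p exceeds
    ``threshold`` (power) and fraction where any non-focal SNP does
    (false-signal rate).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cov in coverages:
        for delta in deltas:
            design = PoolDesign(
                M=M, expected_coverage=float(cov), delta_p=float(delta),
                focal_maf_range=focal_maf_range,
            )
            hits = 0
            false_signal = 0
            for _ in range(n_replicates):
                rep_seed = int(rng.integers(0, 2**63))
                scan, focal = simulate_one_experiment(panel, design, rep_seed)
                nlp = scan["neg_log10_p"].to_numpy()
                if nlp[focal] >= threshold:
                    hits += 1
                others = np.delete(nlp, focal)
                if others.size and np.nanmax(others) >= threshold:
                    false_signal += 1
            rows.append(
                {
                    "coverage": float(cov),
                    "delta_p": float(delta),
                    "n_replicates": n_replicates,
                    "power": hits / n_replicates,
                    "false_signal_rate": false_signal / n_replicates,
                }
            )
    return pd.DataFrame(rows)
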