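"""Neutral coalescent haplotype panels (msprime-backed).

These panels serve two roles: the base haplotypes of the pool-seq
case-control power simulation, and the founder haplotypes of the synthetic
multiparent population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import msprime
import numpy as np

from .data import FounderPanel, ValidationError

__all__ = ["HaplotypePanel", "simulate_neutral_haplotypes", "subsample_panel"]

# refuse simulations whose expected segregating-site count would exceed this
DEFAULT_SITE_CAP = 5_000_000


@dataclass
class HaplotypePanel:
    """n x S binary haplotype matrix over segregating sites of one region."""

    haplotypes: np.ndarray  # n x S, uint8
    positions_bp: np.ndarray  # 1-based ints, strictly increasing
    region_length_bp: int
    n_e: float
    mu: float
    rec: float
    seed: int | None = None
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValidationError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] < 2:
            raise ValidationError("need at least 2 haplotypes")
        if self.haplotypes.shape[1] != self.positions_bp.size:
            raise ValidationError("positions/haplotype column mismatch")
        if self.positions_bp.size and np.any(np.diff(self.positions_bp) <= 0):
            raise ValidationError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.haplotypes.shape[1])

    @property
    def alt_freq(self) -> np.ndarray:
        """Derived-allele frequency per site across the panel."""
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        f = self.alt_freq
        return np.minimum(f, 1.0 - f)

    def to_founder_panel(self, founder_ids: list[str] | None = None) -> FounderPanel:
        """View the panel rows as known founders (sites become panel sites)."""
        ids = founder_ids or [f"F{i + 1}" for i in range(self.n_haplotypes)]
        # simulated sites are abstract 0/1; label them A->T for SYNC export
        return FounderPanel(
            founder_ids=ids,
            chrom=np.full(self.n_sites, self.chrom, dtype=object),
            positions_bp=self.positions_bp,
            matrix=self.haplotypes.T.astype(float),
            ref=np.full(self.n_sites, "A", dtype=object),
            alt=np.full(self.n_sites, "T", dtype=object),
        )


def simulate_neutral_haplotypes(
    n: int,
    L: float,
    N_e: float,
    u: float,
    r: float,
    seed: int,
    site_cap: int = DEFAULT_SITE_CAP,
) -> HaplotypePanel:
    """Simulate ``n`` haplotypes of a neutrally evolving region of ``L`` bp.

    ``N_e`` is the diploid effective population size, ``u``/``r`` per-bp
    per-generation mutation/recombination rates, so the scaled diversity is
    theta = 4*N_e*u per bp.  Monomorphic and non-segregating sites are
    dropped; sites where recurrent mutation produced a non-biallelic pattern
    are excluded.  Deterministic given ``seed``.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if L < 1:
        raise ValidationError("L must be >= 1")
    if min(N_e, u, r) < 0 or N_e == 0:
        raise ValidationError("rates must be non-negative and N_e positive")
    harmonic = np.sum(1.0 / np.arange(1, n))
    expected_sites = 4.0 * N_e * u * L * harmonic
    if expected_sites > site_cap:
        raise ValidationError(
            f"expected ~{expected_sites:.0f} segregating sites exceeds cap "
            f"{site_cap}; scale down N_e, u, or L"
        )
    # ploidy=1 with population_size=2*N_e reproduces the diploid coalescent
    # timescale (pairwise rate 1/(2N_e)), i.e. theta = 4*N_e*u.
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=2.0 * N_e,
        sequence_length=L,
        recombination_rate=r,
        random_seed=_msprime_seed(seed),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=u,
        random_seed=_msprime_seed(seed + 1),
        model=msprime.BinaryMutationModel(),
    )
    if mts.num_sites == 0:
        geno = np.zeros((n, 0), dtype=np.uint8)
        pos = np.zeros(0, dtype=np.int64)
    else:
        geno = mts.genotype_matrix().T  # n x S
        pos = np.array([s.position for s in mts.sites()], dtype=np.int64) + 1
        biallelic = (geno <= 1).all(axis=0)
        freq = geno.mean(axis=0, where=(geno <= 1))
        segregating = biallelic & (geno.max(axis=0) == 1) & (geno.min(axis=0) == 0)
        keep = segregating & (freq > 0) & (freq < 1)
        # discrete-genome mutation can stack two sites at one bp; keep first
        geno = geno[:, keep].astype(np.uint8)
        pos = pos[keep]
        if pos.size:
            first = np.concatenate(([True], np.diff(pos) > 0))
            geno, pos = geno[:, first], pos[first]
    return HaplotypePanel(
        haplotypes=geno,
        positions_bp=pos,
        region_length_bp=int(L),
        n_e=float(N_e),
        mu=float(u),
        rec=float(r),
        seed=int(seed),
    )


def _msprime_seed(seed: int) -> int:
    # msprime requires seeds in [1, 2^32); fold arbitrary ints into range
    return int(np.uint32(np.int64(seed) % (2**32 - 1))) + 1


def subsample_panel(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    max_sites: int | None = None,
    seed: int | None = None,
) -> HaplotypePanel:
    """Retain common sites (MAF >= ``maf_min``), optionally thinning uniformly
    at random to ``max_sites``."""
    if not 0 <= maf_min < 0.5:
        raise ValidationError("maf_min must be in [0, 0.5)")
    keep = np.where(panel.maf >= maf_min)[0]
    if keep.size == 0:
        raise ValidationError("no sites survive the MAF filter")
    if max_sites is not None and keep.size > max_sites:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=max_sites, replace=False))
    return replace(
        panel,
        haplotypes=panel.haplotypes[:, keep],
        positions_bp=panel.positions_bp[keep],
    )
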