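"""Founder-haplotype frequency inference from pooled SNP frequencies.

In each sliding genetic-map window the founder frequencies f solve

    min || H f - y ||_2   subject to   f >= 0,  sum(f) = 1

where H is the window's site-by-founder 0/1 matrix and y the observed pooled
ALT frequencies.  The solver collapses founders that are indistinguishable
in-window (identical columns), solves the reduced problem by non-negative
least squares with the equality constraint imposed as a heavily weighted
augmented row, and splits each collapsed group's total equally among its
members (window flagged non-identifiable).

Imputed SNP frequencies are the inner product of the nearest window's founder
frequencies with the known founder states; pseudo-counts multiply by 2*N*k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .data import FounderPanel, GeneticMap, PoolCounts, ValidationError

__all__ = [
    "Window",
    "HaplotypeFreqTrack",
    "define_windows",
    "estimate_founder_freqs",
    "infer_haplotype_track",
    "impute_snp_freqs",
    "to_pseudo_counts",
]

_EQ_WEIGHT = 1e4  # weight of the sum-to-one row in the augmented NNLS system


@dataclass
class Window:
    """A genetic-map window: closed cM interval and its member panel sites."""

    chrom: str
    center_cM: float
    half_width_cM: float
    site_idx: np.ndarray  # panel site indices inside the window
    usable_idx: np.ndarray  # subset with complete founder states
    flag: str = ""

    @property
    def n_sites(self) -> int:
        return int(self.site_idx.size)


@dataclass
class HaplotypeFreqTrack:
    """Per-(sample, window) founder-frequency simplex estimates."""

    windows: list[Window]
    sample_ids: list[str]
    treatments: list[str]
    replicates: list[int]
    n_individuals: list[int]
    freqs: np.ndarray  # n_samples x n_windows x F
    residual: np.ndarray  # n_samples x n_windows
    flags: np.ndarray  # n_samples x n_windows, object

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_founders(self) -> int:
        return int(self.freqs.shape[2])


def define_windows(
    gmap: GeneticMap,
    panel: FounderPanel,
    width_cM: float = 1.5,
    step_cM: float = 0.25,
) -> list[Window]:
    """Overlapping windows on a regular cM grid; every site lands in >= 1."""
    if width_cM <= 0 or not 0 < step_cM <= width_cM:
        raise ValidationError("need width > 0 and 0 < step <= width")
    if panel.map_cM is None:
        panel.attach_map(gmap)
    half = width_cM / 2.0
    complete = panel.complete_sites()
    windows: list[Window] = []
    for chrom in dict.fromkeys(panel.chrom.astype(str)):  # preserve order
        mask = panel.chrom.astype(str) == chrom
        idx = np.where(mask)[0]
        cm = panel.map_cM[idx]
        lo, hi = float(cm.min()), float(cm.max())
        if hi - lo <= width_cM:
            centers = np.array([(lo + hi) / 2.0])
        else:
            n_steps = int(np.ceil((hi - lo) / step_cM))
            centers = lo + step_cM * np.arange(n_steps + 1)
        for c in centers:
            inside = idx[(cm >= c - half) & (cm <= c + half)]
            usable = inside[complete[inside]]
            flag = ""
            if usable.size < panel.n_founders:
                flag = "too_few_sites"
            windows.append(
                Window(
                    chrom=chrom,
                    center_cM=float(c),
                    half_width_cM=half,
                    site_idx=inside,
                    usable_idx=usable,
                    flag=flag,
                )
            )
    return windows


def estimate_founder_freqs(
    H: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Simplex-constrained least-squares founder frequencies for one window.

    Rows with a missing founder state or missing observation are dropped.
    Returns (f_hat, diagnostics) with diagnostics keys ``residual_norm``,
    ``n_sites_used``, ``identifiable``, ``flag``.
    """
    H = np.asarray(H, dtype=float)
    y = np.asarray(y, dtype=float)
    if H.ndim != 2 or H.shape[0] != y.size:
        raise ValidationError("H/y shape mismatch")
    F = H.shape[1]
    ok = np.isfinite(H).all(axis=1) & np.isfinite(y)
    H, y = H[ok], y[ok]
    if H.shape[0] == 0:
        raise ValidationError("window has no usable sites")
    if F == 1:
        f = np.ones(1)
        resid = float(np.linalg.norm(H[:, 0] - y))
        return f, {
            "residual_norm": resid, "n_sites_used": int(H.shape[0]),
            "identifiable": True, "flag": "",
        }
    # collapse founders with identical in-window columns
    _, first, inverse = np.unique(
        H.T, axis=0, return_index=True, return_inverse=True
    )
    Hu = H[:, np.sort(first)]
    # map group of np.unique (sorted rows) onto column-order groups
    order = np.argsort(first)
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(order.size)
    groups = rank_of[inverse]  # founder j belongs to unique column groups[j]
    U = Hu.shape[1]
    A = np.vstack([Hu, np.full((1, U), _EQ_WEIGHT)])
    b = np.concatenate([y, [_EQ_WEIGHT]])
    g, _ = nnls(A, b)
    total = g.sum()
    g = g / total if total > 0 else np.full(U, 1.0 / U)
    sizes = np.bincount(groups, minlength=U).astype(float)
    f = g[groups] / sizes[groups]
    duplicated = U < F
    ones = np.ones((1, U))
    identifiable = (not duplicated) and (
        np.linalg.matrix_rank(np.vstack([Hu, ones])) == U
    )
    resid = float(np.linalg.norm(H @ f - y))
    return f, {
        "residual_norm": resid,
        "n_sites_used": int(H.shape[0]),
        "identifiable": bool(identifiable),
        "flag": "" if identifiable else "non_identifiable",
    }


def infer_haplotype_track(
    pools: list[PoolCounts],
    panel: FounderPanel,
    windows: list[Window],
    min_coverage: int = 10,
) -> HaplotypeFreqTrack:
    """Fit founder frequencies independently per (sample, window).

    Sites with read coverage below ``min_coverage`` are excluded from that
    sample's fits; a window left without usable sites keeps the uniform
    simplex point and is flagged ``empty``.
    """
    F = panel.n_founders
    n_s, n_w = len(pools), len(windows)
    freqs = np.full((n_s, n_w, F), 1.0 / F)
    residual = np.full((n_s, n_w), np.nan)
    flags = np.full((n_s, n_w), "", dtype=object)
    for si, pool in enumerate(pools):
        if pool.n_sites != panel.n_sites:
            raise ValidationError(f"{pool.sample_id}: counts not aligned to panel")
        y_all = pool.alt_freq
        covered = pool.coverage >= min_coverage
        for wi, win in enumerate(windows):
            use = win.usable_idx[covered[win.usable_idx]]
            if use.size == 0:
                flags[si, wi] = "empty"
                continue
            f, diag = estimate_founder_freqs(panel.matrix[use], y_all[use])
            freqs[si, wi] = f
            residual[si, wi] = diag["residual_norm"]
            parts = [p for p in (win.flag, diag["flag"]) if p]
            flags[si, wi] = ";".join(parts)
    return HaplotypeFreqTrack(
        windows=windows,
        sample_ids=[p.sample_id for p in pools],
        treatments=[p.treatment for p in pools],
        replicates=[p.replicate for p in pools],
        n_individuals=[p.n_individuals for p in pools],
        freqs=freqs,
        residual=residual,
        flags=flags,
    )


def nearest_window_index(windows: list[Window], panel: FounderPanel) -> np.ndarray:
    """Index of the window whose center is nearest each panel site on the cM
    scale (ties broken toward the lower center); -1 where no window exists on
    the site's chromosome."""
    if panel.map_cM is None:
        raise ValidationError("panel has no genetic-map coordinates attached")
    assign = np.full(panel.n_sites, -1, dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for wi, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(wi)
    for chrom, wis in by_chrom.items():
        centers = np.array([windows[wi].center_cM for wi in wis])
        order = np.argsort(centers, kind="stable")
        centers = centers[order]
        wis_sorted = np.array(wis)[order]
        mask = panel.chrom.astype(str) == chrom
        cm = panel.map_cM[mask]
        pos = np.searchsorted(centers, cm)
        left = np.clip(pos - 1, 0, centers.size - 1)
        right = np.clip(pos, 0, centers.size - 1)
        d_left = np.abs(cm - centers[left])
        d_right = np.abs(cm - centers[right])
        choose_left = d_left <= d_right  # tie -> lower center
        chosen = np.where(choose_left, left, right)
        assign[mask] = wis_sorted[chosen]
    return assign


def impute_snp_freqs(
    track: HaplotypeFreqTrack, panel: FounderPanel
) -> dict[str, np.ndarray]:
    """Imputed per-site ALT frequencies for every sample.

    Each site uses the nearest window's founder frequencies:
    freq = sum_j f_hat_j * h_ij.  Sites with a missing founder state impute
    to NaN; a site on a chromosome without windows raises.
    """
    assign = nearest_window_index(track.windows, panel)
    if np.any(assign < 0):
        raise ValidationError("some sites are covered by no window")
    out: dict[str, np.ndarray] = {}
    for si, sid in enumerate(track.sample_ids):
        imputed = np.empty(panel.n_sites)
        for wi in np.unique(assign):
            mask = assign == wi
            imputed[mask] = panel.matrix[mask] @ track.freqs[si, wi]
        out[sid] = imputed
    return out


def to_pseudo_counts(
    freqs: np.ndarray, n_individuals: int, k: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """(REF, ALT) pseudo-counts: frequency x 2N x k, kept real-valued."""
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    if not 0 < k <= 1:
        raise ValidationError("efficiency factor k must be in (0, 1]")
    freqs = np.asarray(freqs, dtype=float)
    scale = 2.0 * n_individuals * k
    alt = freqs * scale
    ref = (1.0 - freqs) * scale
    return ref, alt
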