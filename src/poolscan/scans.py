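"""Replicated genome scans: Cochran-Mantel-Haenszel statistics on direct
read counts, imputed founder-haplotype pseudo-counts, and imputed-SNP
pseudo-counts, plus thresholds and scan comparison.

Strata are experimental replicates.  Tables may be real-valued
(pseudo-counts); the CMH formulas are evaluated on reals.  Two variance
variants exist: the classical one with the (T-1) term (default) and the
``no_tminus1`` variant under which the statistic scales exactly linearly
when every cell is multiplied by a constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import FounderPanel, PoolCounts, ValidationError, make_scan_frame
from .haplotypes import HaplotypeFreqTrack, nearest_window_index, to_pseudo_counts

__all__ = [
    "cmh_2x2xK",
    "cmh_general",
    "scan_direct_snp",
    "scan_haplotype",
    "scan_imputed_snp",
    "bonferroni",
    "compare_scans",
    "group_pools_by_replicate",
]


def cmh_2x2xK(a, b, c, d, variant: str = "classical"):
    """Classical CMH statistic for K 2x2 strata, vectorized over loci.

    Cell layout per stratum: [[a, b], [c, d]] with rows treatment (case,
    control) and columns (REF, ALT).  Arrays have shape (K,) or (K, S).
    Strata with a zero row or column margin contribute nothing; if every
    stratum is degenerate the statistic is 0 with p 1.

    Returns (statistic, p_value, degenerate_mask).
    """
    if variant not in ("classical", "no_tminus1"):
        raise ValidationError(f"unknown CMH variant {variant!r}")
    a, b, c, d = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (a, b, c, d))
    squeeze = a.ndim == 1
    if squeeze:
        a, b, c, d = (x[:, None] for x in (a, b, c, d))
    n1, n2 = a + b, c + d
    m1, m2 = a + c, b + d
    T = n1 + n2
    ok = (n1 > 0) & (n2 > 0) & (m1 > 0) & (m2 > 0)
    if variant == "classical":
        ok &= T > 1
        denom_T = T * T * np.maximum(T - 1.0, 1.0)
    else:
        denom_T = T * T * np.maximum(T, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = n1 * m1 / np.maximum(T, 1.0)
        V = n1 * n2 * m1 * m2 / denom_T
    num = np.where(ok, a - E, 0.0).sum(axis=0)
    var = np.where(ok, V, 0.0).sum(axis=0)
    degenerate = var <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(degenerate, 0.0, num**2 / np.where(degenerate, 1.0, var))
    p = np.where(degenerate, 1.0, stats.chi2.sf(stat, 1))
    if squeeze:
        return float(stat[0]), float(p[0]), bool(degenerate[0])
    return stat, p, degenerate


def cmh_general(tables: np.ndarray, variant: str = "classical"):
    """Generalized CMH general-association statistic for K 2xJ strata.

    ``tables`` has shape (K, 2, J): rows treatment (case, control), J
    category columns.  The statistic is the quadratic form of the summed
    (observed - expected) case-row category counts against the summed
    null covariance, evaluated on the first J-1 categories; df = J - 1
    (reduced via pseudo-inverse when the summed covariance is singular,
    with the effective df reported).  Reduces to :func:`cmh_2x2xK` at J=2.

    Returns (statistic, df, p_value, flag).
    """
    if variant not in ("classical", "no_tminus1"):
        raise ValidationError(f"unknown CMH variant {variant!r}")
    tab = np.asarray(tables, dtype=float)
    if tab.ndim != 3 or tab.shape[1] != 2:
        raise ValidationError("tables must have shape (K, 2, J)")
    if np.any(tab < 0):
        raise ValidationError("negative cell")
    K, _, J = tab.shape
    d = np.zeros(J - 1)
    V = np.zeros((J - 1, J - 1))
    used = 0
    for k in range(K):
        n1 = tab[k, 0].sum()
        n2 = tab[k, 1].sum()
        T = n1 + n2
        if n1 <= 0 or n2 <= 0:
            continue
        if variant == "classical" and T <= 1:
            continue
        m = tab[k].sum(axis=0)
        E = n1 * m / T
        d += tab[k, 0, : J - 1] - E[: J - 1]
        mm = m[: J - 1]
        cov = T * np.diag(mm) - np.outer(mm, mm)
        tdenom = T - 1.0 if variant == "classical" else T
        V += (n1 * n2) / (T * T * tdenom) * cov
        used += 1
    if used == 0 or not np.any(V):
        return 0.0, J - 1, 1.0, "degenerate"
    rank = np.linalg.matrix_rank(V)
    flag = ""
    if rank < J - 1:
        Vinv = np.linalg.pinv(V)
        df = int(rank)
        flag = "singular_covariance"
    else:
        Vinv = np.linalg.inv(V)
        df = J - 1
    stat = float(d @ Vinv @ d)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p, flag


def group_pools_by_replicate(
    pools: list[PoolCounts],
) -> dict[int, dict[str, list[PoolCounts]]]:
    """{replicate: {"case": [...], "control": [...]}}; validates that every
    replicate has at least one pool of each treatment."""
    grouped: dict[int, dict[str, list[PoolCounts]]] = {}
    for p in pools:
        grouped.setdefault(p.replicate, {"case": [], "control": []})[p.treatment].append(p)
    for rep, d in grouped.items():
        if not d["case"] or not d["control"]:
            raise ValidationError(f"replicate {rep} lacks a case or control pool")
    return grouped


def _stacked_counts(pools: list[PoolCounts], n_sites: int):
    """Sum REF/ALT across pools (multiple control pools collapse by summing)."""
    ref = np.zeros(n_sites)
    alt = np.zeros(n_sites)
    for p in pools:
        if p.n_sites != n_sites:
            raise ValidationError(f"{p.sample_id}: site vector length mismatch")
        ref += p.ref_count
        alt += p.alt_count
    return ref, alt


def scan_direct_snp(
    pools: list[PoolCounts], panel: FounderPanel, variant: str = "classical"
) -> pd.DataFrame:
    """CMH scan on directly ascertained read counts, stratified by replicate."""
    grouped = group_pools_by_replicate(pools)
    reps = sorted(grouped)
    S = panel.n_sites
    a = np.empty((len(reps), S))
    b = np.empty((len(reps), S))
    c = np.empty((len(reps), S))
    d = np.empty((len(reps), S))
    for i, rep in enumerate(reps):
        a[i], b[i] = _stacked_counts(grouped[rep]["case"], S)
        c[i], d[i] = _stacked_counts(grouped[rep]["control"], S)
    stat, p, degenerate = cmh_2x2xK(a, b, c, d, variant=variant)
    return make_scan_frame(
        chrom=panel.chrom,
        locus_id=np.arange(S),
        pos_bp=panel.positions_bp,
        cM=panel.map_cM if panel.map_cM is not None else np.full(S, np.nan),
        statistic=stat,
        df=np.ones(S, dtype=int),
        p_value=p,
        scan_type="direct_snp",
        flag=np.where(degenerate, "degenerate", ""),
    )


def scan_haplotype(
    track: HaplotypeFreqTrack,
    efficiency_k: float = 1.0,
    variant: str = "classical",
) -> pd.DataFrame:
    """Generalized CMH scan on founder pseudo-counts, one test per window.

    Per sample the window's founder frequencies become pseudo-counts
    f_hat * 2N * k; replicates form strata (2 x F tables, control pools
    within a replicate summed).
    """
    sample_ids = track.sample_ids
    reps = sorted(set(track.replicates))
    F = track.n_founders
    rows = []
    for wi, win in enumerate(track.windows):
        tables = np.zeros((len(reps), 2, F))
        for si in range(len(sample_ids)):
            row = 0 if track.treatments[si] == "case" else 1
            k_idx = reps.index(track.replicates[si])
            scale = 2.0 * track.n_individuals[si] * efficiency_k
            tables[k_idx, row] += track.freqs[si, wi] * scale
        stat, df, p, flag = cmh_general(tables, variant=variant)
        win_flags = set(track.flags[:, wi]) - {""}
        all_flags = ";".join(sorted(win_flags | ({flag} - {""})))
        rows.append((win.chrom, wi, win.center_cM, stat, df, p, all_flags))
    frame = pd.DataFrame(
        rows, columns=["chrom", "locus_id", "cM", "statistic", "df", "p_value", "flag"]
    )
    return make_scan_frame(
        chrom=frame["chrom"],
        locus_id=frame["locus_id"],
        pos_bp=np.full(len(frame), -1),
        cM=frame["cM"],
        statistic=frame["statistic"],
        df=frame["df"],
        p_value=frame["p_value"],
        scan_type="haplotype",
        flag=frame["flag"],
    )


def scan_imputed_snp(
    imputed: dict[str, np.ndarray],
    track: HaplotypeFreqTrack,
    panel: FounderPanel,
    efficiency_k: float = 1.0,
    variant: str = "classical",
) -> pd.DataFrame:
    """CMH scan on imputed-SNP REF/ALT pseudo-counts, as scan_direct_snp but
    with frequency x 2N x k in place of read counts."""
    reps = sorted(set(track.replicates))
    S = panel.n_sites
    a = np.zeros((len(reps), S))
    b = np.zeros((len(reps), S))
    c = np.zeros((len(reps), S))
    d = np.zeros((len(reps), S))
    for si, sid in enumerate(track.sample_ids):
        if sid not in imputed:
            raise ValidationError(f"no imputed frequencies for sample {sid!r}")
        freqs = np.nan_to_num(imputed[sid], nan=0.0)
        ref, alt = to_pseudo_counts(freqs, track.n_individuals[si], efficiency_k)
        k_idx = reps.index(track.replicates[si])
        if track.treatments[si] == "case":
            a[k_idx] += ref
            b[k_idx] += alt
        else:
            c[k_idx] += ref
            d[k_idx] += alt
    stat, p, degenerate = cmh_2x2xK(a, b, c, d, variant=variant)
    missing = ~panel.complete_sites()
    flags = np.where(degenerate, "degenerate", "")
    flags = np.where(missing, "missing_founder_state", flags).astype(object)
    return make_scan_frame(
        chrom=panel.chrom,
        locus_id=np.arange(S),
        pos_bp=panel.positions_bp,
        cM=panel.map_cM if panel.map_cM is not None else np.full(S, np.nan),
        statistic=stat,
        df=np.ones(S, dtype=int),
        p_value=p,
        scan_type="imputed_snp",
        flag=flags,
    )


def bonferroni(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise -log10 p threshold: -log10(alpha / n_tests)."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return float(np.log10(n_tests) - np.log10(alpha))


def cluster_score(cm: np.ndarray, nlp: np.ndarray, threshold: float, radius_cM: float = 1.0) -> float:
    """Median, over loci above threshold, of the number of *other*
    above-threshold loci within +-radius_cM; 0 when no locus qualifies."""
    hits = np.sort(cm[np.asarray(nlp) >= threshold])
    if hits.size == 0:
        return 0.0
    left = np.searchsorted(hits, hits - radius_cM, side="left")
    right = np.searchsorted(hits, hits + radius_cM, side="right")
    return float(np.median(right - left - 1))


def compare_scans(
    scans: dict[str, pd.DataFrame],
    qtl_chrom: str,
    qtl_cM: float,
    window_cM: float = 1.5,
    threshold: float = 5.0,
    cluster_radius_cM: float = 1.0,
) -> pd.DataFrame:
    """Per-scan localization summary around a known QTL position.

    Columns: global max -log10 p and its locus, peak inside +-window_cM of
    the QTL, max outside it, peak-minus-background gap, whether the global
    argmax falls inside the window, and the cluster score of hits above
    ``threshold``.
    """
    rows = []
    for scan_type, scan in scans.items():
        nlp = scan["neg_log10_p"].to_numpy()
        cm = scan["cM"].to_numpy(float)
        on_chrom = scan["chrom"].to_numpy(object).astype(str) == str(qtl_chrom)
        in_win = on_chrom & (np.abs(cm - qtl_cM) <= window_cM)
        gmax_i = int(np.nanargmax(nlp))
        peak = float(np.nanmax(nlp[in_win])) if in_win.any() else 0.0
        background = float(np.nanmax(nlp[~in_win])) if (~in_win).any() else 0.0
        rows.append(
            {
                "scan_type": scan_type,
                "global_max": float(nlp[gmax_i]),
                "argmax_locus": scan["locus_id"].iloc[gmax_i],
                "argmax_cM": float(cm[gmax_i]),
                "argmax_in_window": bool(in_win[gmax_i]),
                "qtl_window_peak": peak,
                "background_max": background,
                "gap": peak - background,
                "cluster_score": cluster_score(cm, nlp, threshold, cluster_radius_cM),
                "n_hits": int((nlp >= threshold).sum()),
            }
        )
    return pd.DataFrame(rows)
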