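"""Core data model, file readers/writers, and genetic-map arithmetic.

Coordinates are 1-based inclusive base pairs (VCF convention).  Genetic-map
windows operate on the centiMorgan scale as closed intervals.  Founder allele
states are 0/1 with NaN for missing; sites carrying a missing founder state
are excluded from haplotype-inference windows downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GeneticMap",
    "FounderPanel",
    "PoolCounts",
    "SCAN_COLUMNS",
    "make_scan_frame",
    "validate_scan_frame",
    "interpolate_cM",
    "read_genetic_map",
    "write_genetic_map",
    "read_founder_panel",
    "write_founder_panel",
    "read_counts_table",
    "write_counts_table",
    "write_sync",
]


class ParseError(ValueError):
    """A malformed input file (carries the offending line number when known)."""


class ValidationError(ValueError):
    """Input violated a data-model invariant."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map, anchored per chromosome.

    ``anchors`` maps a chromosome label to a pair of equal-length arrays
    ``(bp, cM)`` with bp strictly increasing and cM non-decreasing.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if bp.size != cm.size:
                raise ValidationError(f"{chrom}: bp/cM anchor length mismatch")
            if bp.size < 2:
                raise ValidationError(f"{chrom}: need at least 2 map anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValidationError(f"{chrom}: anchor bp must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValidationError(f"{chrom}: anchor cM must be non-decreasing")
            clean[chrom] = (bp, cm)
        if not clean:
            raise ValidationError("empty genetic map")
        self.anchors = clean

    @property
    def chroms(self) -> list[str]:
        return list(self.anchors)

    def interpolate(self, chrom: str, bp) -> np.ndarray:
        """cM position(s) of ``bp`` on ``chrom``; no extrapolation."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in map")
        abp, acm = self.anchors[chrom]
        bp_arr = np.atleast_1d(np.asarray(bp, dtype=np.int64))
        if np.any(bp_arr < abp[0]) or np.any(bp_arr > abp[-1]):
            raise ValidationError(
                f"{chrom}: bp outside map anchor range [{abp[0]}, {abp[-1]}]"
            )
        out = np.interp(bp_arr, abp, acm)
        return out if np.ndim(bp) else float(out[0])

    def inverse(self, chrom: str, cm) -> np.ndarray:
        """bp position(s) of ``cm`` (pseudo-inverse on flat segments)."""
        abp, acm = self.anchors[chrom]
        cm_arr = np.atleast_1d(np.asarray(cm, dtype=float))
        if np.any(cm_arr < acm[0]) or np.any(cm_arr > acm[-1]):
            raise ValidationError(f"{chrom}: cM outside map range")
        out = np.interp(cm_arr, acm, abp)
        return out if np.ndim(cm) else float(out[0])

    def length_cM(self, chrom: str) -> float:
        acm = self.anchors[chrom][1]
        return float(acm[-1] - acm[0])

    def total_morgans(self) -> float:
        return sum(self.length_cM(c) for c in self.anchors) / 100.0


def interpolate_cM(gmap: GeneticMap, chrom: str, bp):
    """Piecewise-linear interpolation of ``bp`` onto the cM scale."""
    return gmap.interpolate(chrom, bp)


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------


@dataclass
class FounderPanel:
    """Site-by-founder 0/1 haplotype matrix with physical and genetic coords.

    ``matrix`` is S x F float with entries in {0, 1, NaN}; NaN marks a missing
    founder state.  ``ref``/``alt`` hold nucleotide labels when known (needed
    for SYNC export), else None.
    """

    founder_ids: list[str]
    chrom: np.ndarray
    positions_bp: np.ndarray
    matrix: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    map_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=float)
        S = self.positions_bp.size
        if self.matrix.shape != (S, len(self.founder_ids)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} != ({S}, {len(self.founder_ids)})"
            )
        finite = self.matrix[np.isfinite(self.matrix)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValidationError("founder matrix entries must be 0, 1, or missing")
        for c in np.unique(self.chrom.astype(str)):
            pos = self.positions_bp[self.chrom.astype(str) == c]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"{c}: positions must be strictly increasing within chromosome"
                )
        if self.map_cM is not None:
            self.map_cM = np.asarray(self.map_cM, dtype=float)
            if self.map_cM.size != S:
                raise ValidationError("map_cM length mismatch")

    @property
    def n_sites(self) -> int:
        return int(self.positions_bp.size)

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def attach_map(self, gmap: GeneticMap) -> None:
        """Fill ``map_cM`` by interpolating every site on ``gmap``."""
        cm = np.empty(self.n_sites, dtype=float)
        for c in np.unique(self.chrom.astype(str)):
            mask = self.chrom.astype(str) == c
            cm[mask] = gmap.interpolate(c, self.positions_bp[mask])
        self.map_cM = cm

    def complete_sites(self) -> np.ndarray:
        """Boolean mask of sites with no missing founder state."""
        return np.isfinite(self.matrix).all(axis=1)


# ---------------------------------------------------------------------------
# Pool counts
# ---------------------------------------------------------------------------


@dataclass
class PoolCounts:
    """REF/ALT read counts for one pooled sample, aligned to a site index."""

    sample_id: str
    treatment: str
    replicate: int
    n_individuals: int
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count)
        self.alt_count = np.asarray(self.alt_count)
        if self.ref_count.shape != self.alt_count.shape:
            raise ValidationError("ref/alt count length mismatch")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValidationError(f"{self.sample_id}: negative count")
        if self.treatment not in ("case", "control"):
            raise ValidationError(f"treatment must be case/control, got {self.treatment!r}")
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")

    @property
    def n_sites(self) -> int:
        return int(self.ref_count.size)

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def alt_freq(self) -> np.ndarray:
        """ALT/(REF+ALT); NaN at zero-coverage sites."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.alt_count / cov, np.nan)


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

SCAN_COLUMNS = [
    "chrom",
    "locus_id",
    "pos_bp",
    "cM",
    "statistic",
    "df",
    "p_value",
    "neg_log10_p",
    "scan_type",
    "flag",
]

_SCAN_TYPES = {"direct_snp", "haplotype", "imputed_snp"}

P_FLOOR = 1e-300  # keeps -log10 p finite


def make_scan_frame(
    chrom,
    locus_id,
    pos_bp,
    cM,
    statistic,
    df,
    p_value,
    scan_type: str,
    flag=None,
) -> pd.DataFrame:
    """Assemble a per-locus scan table with the floored -log10 p column."""
    if scan_type not in _SCAN_TYPES:
        raise ValidationError(f"unknown scan_type {scan_type!r}")
    p = np.clip(np.asarray(p_value, dtype=float), P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "locus_id": np.asarray(locus_id),
            "pos_bp": np.asarray(pos_bp),
            "cM": np.asarray(cM, dtype=float),
            "statistic": np.asarray(statistic, dtype=float),
            "df": np.asarray(df, dtype=int),
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "scan_type": scan_type,
            "flag": np.asarray(flag, dtype=object)
            if flag is not None
            else np.full(len(p), "", dtype=object),
        }
    )
    return out


def validate_scan_frame(scan: pd.DataFrame) -> None:
    if list(scan.columns) != SCAN_COLUMNS:
        raise ValidationError(f"scan columns must be {SCAN_COLUMNS}")
    if np.any(scan["statistic"] < 0):
        raise ValidationError("negative statistic")
    if np.any((scan["p_value"] <= 0) | (scan["p_value"] > 1)):
        raise ValidationError("p_value outside (0,1]")
    if not np.allclose(scan["neg_log10_p"], -np.log10(scan["p_value"]), atol=1e-9):
        raise ValidationError("neg_log10_p inconsistent with p_value")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genetic_map(path) -> GeneticMap:
    """Read a TSV of (chrom, pos, cM) anchors."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "cM"):
        if col not in df.columns:
            raise ParseError(f"genetic map missing column {col!r}")
    anchors = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        anchors[str(chrom)] = (
            sub["pos"].to_numpy(np.int64),
            sub["cM"].to_numpy(float),
        )
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = []
    for chrom, (bp, cm) in gmap.anchors.items():
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), float(c)))
    pd.DataFrame(rows, columns=["chrom", "pos", "cM"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_founder_panel(path) -> FounderPanel:
    """Read a founder panel TSV: chrom, pos, ref, alt, then one 0/1/NA column
    per founder."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    fixed = ["chrom", "pos", "ref", "alt"]
    for col in fixed[:2]:
        if col not in df.columns:
            raise ParseError(f"founder panel missing column {col!r}")
    founder_cols = [c for c in df.columns if c not in fixed]
    if not founder_cols:
        raise ParseError("founder panel has no founder columns")
    if len(df) == 0:
        raise ParseError("no sites in founder panel")
    matrix = df[founder_cols].to_numpy(float)
    return FounderPanel(
        founder_ids=founder_cols,
        chrom=df["chrom"].to_numpy(object),
        positions_bp=df["pos"].to_numpy(np.int64),
        matrix=matrix,
        ref=df["ref"].to_numpy(object) if "ref" in df.columns else None,
        alt=df["alt"].to_numpy(object) if "alt" in df.columns else None,
    )


def write_founder_panel(panel: FounderPanel, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.positions_bp,
            "ref": panel.ref if panel.ref is not None else ["."] * panel.n_sites,
            "alt": panel.alt if panel.alt is not None else ["."] * panel.n_sites,
        }
    )
    for j, fid in enumerate(panel.founder_ids):
        col = panel.matrix[:, j]
        df[fid] = pd.array(col, dtype="Int64") if np.isfinite(col).all() else [
            "NA" if not np.isfinite(v) else int(v) for v in col
        ]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_counts_table(counts_path, meta_path) -> tuple[pd.DataFrame, list[PoolCounts]]:
    """Read a counts TSV plus its sample-metadata sidecar.

    The counts TSV has columns chrom, pos[, ref, alt] then ``<sample>_ref`` /
    ``<sample>_alt`` pairs; the metadata TSV has sample_id, treatment,
    replicate, n_individuals.  Returns (site table, pools) with one
    :class:`PoolCounts` per metadata row, in metadata order.
    """
    df = pd.read_csv(counts_path, sep="\t", dtype={"chrom": str})
    if len(df) == 0:
        raise ParseError("no sites in counts table")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"counts table missing column {col!r}")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "treatment", "replicate", "n_individuals"):
        if col not in meta.columns:
            raise ParseError(f"metadata missing column {col!r}")

    site_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
    sites = df[site_cols].copy()
    pools = []
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        rc, ac = f"{sid}_ref", f"{sid}_alt"
        for col in (rc, ac):
            if col not in df.columns:
                raise ParseError(f"counts table missing column {col!r}")
            vals = df[col]
            if vals.isna().any():
                line = int(vals.index[vals.isna()][0]) + 2  # +header +1-based
                raise ParseError(f"missing count in column {col!r} at line {line}")
        ref = df[rc].to_numpy()
        alt = df[ac].to_numpy()
        if np.any(ref < 0) or np.any(alt < 0):
            bad = np.where((ref < 0) | (alt < 0))[0][0]
            raise ValidationError(
                f"negative count for sample {sid!r} at line {int(bad) + 2}"
            )
        pools.append(
            PoolCounts(
                sample_id=sid,
                treatment=str(row["treatment"]),
                replicate=int(row["replicate"]),
                n_individuals=int(row["n_individuals"]),
                ref_count=ref.astype(np.int64),
                alt_count=alt.astype(np.int64),
            )
        )
    return sites, pools


def write_counts_table(sites: pd.DataFrame, pools: list[PoolCounts], counts_path, meta_path) -> None:
    """Write counts + metadata TSVs in the layout read_counts_table expects."""
    df = sites.copy()
    meta_rows = []
    for p in pools:
        if p.n_sites != len(df):
            raise ValidationError(f"{p.sample_id}: site count mismatch with site table")
        df[f"{p.sample_id}_ref"] = p.ref_count
        df[f"{p.sample_id}_alt"] = p.alt_count
        meta_rows.append((p.sample_id, p.treatment, p.replicate, p.n_individuals))
    df.to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(
        meta_rows, columns=["sample_id", "treatment", "replicate", "n_individuals"]
    ).to_csv(meta_path, sep="\t", index=False)


_SYNC_SLOTS = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}


def write_sync(pools: list[PoolCounts], panel: FounderPanel, path) -> None:
    """Write popoolation2-style SYNC: chrom, pos, ref base, then per-pool
    A:T:C:G:N:del counts (tab-separated, pool order = input order)."""
    if panel.ref is None or panel.alt is None:
        raise ValidationError("SYNC export needs REF/ALT nucleotide labels")
    refs = np.asarray(panel.ref, dtype=object)
    alts = np.asarray(panel.alt, dtype=object)
    for arr, name in ((refs, "ref"), (alts, "alt")):
        bad = ~np.isin(arr.astype(str), list("ATCGN"))
        if bad.any():
            raise ValidationError(f"non-nucleotide {name} label at site {np.where(bad)[0][0]}")
    with open(path, "w") as fh:
        for i in range(panel.n_sites):
            fields = [str(panel.chrom[i]), str(int(panel.positions_bp[i])), str(refs[i])]
            ri, ai = _SYNC_SLOTS[str(refs[i])], _SYNC_SLOTS[str(alts[i])]
            for p in pools:
                slots = [0, 0, 0, 0, 0, 0]
                slots[ri] += int(p.ref_count[i])
                slots[ai] += int(p.alt_count[i])
                fields.append(":".join(str(s) for s in slots))
            fh.write("\t".join(fields) + "\n")


def read_sync(path) -> tuple[pd.DataFrame, list[tuple[np.ndarray, np.ndarray]]]:
    """Read SYNC back as (site table, per-pool (ref, alt) count arrays).

    ALT base per site is taken as the non-REF base with the largest total
    count across pools (SYNC does not record ALT explicitly).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"malformed SYNC line {lineno}")
            rows.append(parts)
    n_pools = len(rows[0]) - 3
    chroms, poss, refs, alts = [], [], [], []
    ref_counts = [[] for _ in range(n_pools)]
    alt_counts = [[] for _ in range(n_pools)]
    for lineno, parts in enumerate(rows, start=1):
        if len(parts) - 3 != n_pools:
            raise ParseError(f"inconsistent pool count at SYNC line {lineno}")
        chrom, pos, ref = parts[0], int(parts[1]), parts[2]
        mats = []
        for f in parts[3:]:
            vals = f.split(":")
            if len(vals) != 6:
                raise ParseError(f"malformed count field at SYNC line {lineno}")
            mats.append([int(v) for v in vals])
        mats = np.array(mats)  # pools x 6
        ri = _SYNC_SLOTS.get(ref, 4)
        totals = mats.sum(axis=0)
        totals[ri] = -1
        totals[5] = -1  # ignore deletions
        ai = int(np.argmax(totals))
        chroms.append(chrom)
        poss.append(pos)
        refs.append(ref)
        alts.append("ATCGN"[ai])
        for k in range(n_pools):
            ref_counts[k].append(mats[k, ri])
            alt_counts[k].append(mats[k, ai])
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    pools = [
        (np.array(ref_counts[k], dtype=np.int64), np.array(alt_counts[k], dtype=np.int64))
        for k in range(n_pools)
    ]
    return sites, pools
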