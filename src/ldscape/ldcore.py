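"""Pairwise linkage disequilibrium from phased gametes.

Signed r and r² between syntenic SNP pairs, computed from haplotype
frequencies counted directly at the gametic level (Hill–Robertson):

    D  = p_A1B1 · p_A2B2 − p_A1B2 · p_A2B1
    r  = D / sqrt(p_A1 · p_A2 · p_B1 · p_B2),   r² = r²

which equals the squared Pearson correlation of the 0/1 allele indicators
across gametes.  The module also provides adjacent-pair summaries, distance
binning of the decay curve, r² threshold proportions, and the panel-thinning
experiment (retaining every k-th marker per chromosome).

All pair tables are pandas DataFrames with columns
``chrom, pos_i, pos_j, distance_bp, r_signed, r2`` (one row per syntenic
pair, ``pos_i < pos_j``), the atom of every downstream stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .popdata import HaplotypeSet

PAIR_COLUMNS = ["chrom", "pos_i", "pos_j", "distance_bp", "r_signed", "r2"]


def pair_ld(hapA: np.ndarray, hapB: np.ndarray) -> tuple[float, float]:
    """Signed r and r² for one SNP pair from phased 0/1 allele columns.

    Haplotype frequencies are counted directly from the gametes; allele 1 is
    the map's allele1.  Raises on a monomorphic column (LD undefined) — the
    caller must pre-filter.
    """
    a = np.asarray(hapA, dtype=np.float64)
    b = np.asarray(hapB, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("allele columns must be 1-D and equal length")
    n = len(a)
    p_A1 = a.mean()
    p_B1 = b.mean()
    if p_A1 in (0.0, 1.0) or p_B1 in (0.0, 1.0):
        raise ValueError("undefined LD: monomorphic column")
    p_A1B1 = np.mean(a * b)
    p_A1B2 = p_A1 - p_A1B1
    p_A2B1 = p_B1 - p_A1B1
    p_A2B2 = 1.0 - p_A1B1 - p_A1B2 - p_A2B1
    D = p_A1B1 * p_A2B2 - p_A1B2 * p_A2B1
    r = D / np.sqrt(p_A1 * (1 - p_A1) * p_B1 * (1 - p_B1))
    return float(r), float(r * r)


def _signed_r_matrix(H: np.ndarray) -> np.ndarray:
    """Signed r for all column pairs of a 0/1 gamete matrix.

    Vectorised Hill–Robertson: D = P_11 − p pᵀ with P_11 the haplotype
    co-occurrence frequency of the 1-alleles.  Columns must be polymorphic.
    Dense m×m output; adequate at array scale per chromosome (a few thousand
    markers).
    """
    X = H.astype(np.float64)
    n, m = X.shape
    p = X.mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("undefined LD: monomorphic column present; filter first")
    P11 = (X.T @ X) / n
    D = P11 - np.outer(p, p)
    het = p * (1.0 - p)
    denom = np.sqrt(np.outer(het, het))
    return D / denom


def drop_monomorphic(h: HaplotypeSet) -> HaplotypeSet:
    """Remove markers monomorphic in this population (their r is undefined)."""
    return h.select_markers(h.maf() > 0)


def syntenic_pairs(
    h: HaplotypeSet, max_distance_bp: int | None = 10_000_000
) -> pd.DataFrame:
    """All within-chromosome SNP pairs with distance <= ``max_distance_bp``.

    Ordered by (chrom, pos_i, pos_j).  ``h`` must be polymorphic-filtered
    (see :func:`drop_monomorphic`) and position-sorted.
    """
    h = h.sorted_by_position()
    chrom = h.map.chrom
    pos = h.map.pos_bp
    frames = []
    for c in dict.fromkeys(chrom):
        cols = np.flatnonzero(chrom == c)
        if len(cols) < 2:
            continue
        R = _signed_r_matrix(h.haplotypes[:, cols])
        ii, jj = np.triu_indices(len(cols), k=1)
        d = pos[cols][jj] - pos[cols][ii]
        if max_distance_bp is not None:
            keep = d <= max_distance_bp
            ii, jj, d = ii[keep], jj[keep], d[keep]
        r = R[ii, jj]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos_i": pos[cols][ii],
                    "pos_j": pos[cols][jj],
                    "distance_bp": d,
                    "r_signed": r,
                    "r2": r * r,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos_i", "pos_j"], kind="stable").reset_index(
        drop=True
    )


def adjacent_pairs(h: HaplotypeSet) -> pd.DataFrame:
    """Consecutive-marker pairs per chromosome: Σ_chrom (n_chrom − 1) rows."""
    h = h.sorted_by_position()
    chrom = h.map.chrom
    pos = h.map.pos_bp
    H = h.haplotypes.astype(np.float64)
    n = H.shape[0]
    p = H.mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("undefined LD: monomorphic column present; filter first")
    frames = []
    for c in dict.fromkeys(chrom):
        cols = np.flatnonzero(chrom == c)
        if len(cols) < 2:
            continue
        A = H[:, cols[:-1]]
        B = H[:, cols[1:]]
        pa = p[cols[:-1]]
        pb = p[cols[1:]]
        p11 = (A * B).mean(axis=0)
        D = p11 - pa * pb
        r = D / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos_i": pos[cols[:-1]],
                    "pos_j": pos[cols[1:]],
                    "distance_bp": pos[cols[1:]] - pos[cols[:-1]],
                    "r_signed": r,
                    "r2": r * r,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def bin_by_distance(
    pairs: pd.DataFrame,
    bin_width_bp: int = 100_000,
    max_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Mean and SD of r² in half-open distance bins [k·w, (k+1)·w).

    Bins cover 0 up to ``max_bp``; empty bins are reported with n = 0.  A
    pair at exactly a bin edge falls in the upper bin (half-open convention).
    """
    n_bins = int(np.ceil(max_bp / bin_width_bp))
    lo = np.arange(n_bins, dtype=np.int64) * bin_width_bp
    hi = lo + bin_width_bp
    d = pairs["distance_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    inrange = d < n_bins * bin_width_bp
    idx = (d[inrange] // bin_width_bp).astype(np.int64)
    r2v = r2[inrange]
    n = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=r2v, minlength=n_bins)
    ss = np.bincount(idx, weights=r2v * r2v, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s / n
        var = (ss - n * mean**2) / (n - 1)
    mean = np.where(n > 0, mean, np.nan)
    sd = np.where(n > 1, np.sqrt(np.maximum(var, 0.0)), np.nan)
    return pd.DataFrame(
        {
            "bin_lo_bp": lo,
            "bin_hi_bp": hi,
            "n_pairs": n,
            "mean_r2": mean,
            "sd_r2": sd,
        }
    )


def proportion_above(pairs: pd.DataFrame, threshold: float) -> float:
    """Fraction of pairs with r² strictly greater than ``threshold``."""
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    return float((pairs["r2"].to_numpy() > threshold).mean())


def thin_panel(h: HaplotypeSet, keep_every: int, offset: int = 0) -> HaplotypeSet:
    """Retain markers at indices offset, offset+k, ... within each chromosome.

    Thinning restarts at each chromosome (the per-chromosome retained count
    is ceil((n_i − offset)/k)).  ``keep_every=1`` is the identity.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    h = h.sorted_by_position()
    chrom = h.map.chrom
    counts = pd.Series(chrom).value_counts()
    if keep_every > counts.max():
        raise ValueError(
            f"keep_every={keep_every} exceeds every chromosome's marker count"
        )
    keep = []
    for c in dict.fromkeys(chrom):
        cols = np.flatnonzero(chrom == c)
        keep.append(cols[offset::keep_every])
    return h.select_markers(np.concatenate(keep))


def thinning_experiment(
    h: HaplotypeSet,
    keep_every_list: Sequence[int] = (1, 2, 4, 5, 6, 7, 14),
    thresholds: Sequence[float] = (0.2, 0.3),
    offset: int = 0,
) -> pd.DataFrame:
    """Adjacent-pair LD summaries at decreasing panel densities.

    One row per thinning factor: retained-marker percentage and count, mean
    ± SD adjacent r², mean adjacent distance (Kb), and the fraction of pairs
    with r² above each threshold.  The default factors {1,2,4,5,6,7,14}
    correspond to 100/50/25/20/17/14/7 % panel densities.
    """
    rows = []
    for k in keep_every_list:
        hk = thin_panel(h, k, offset=offset)
        ap = adjacent_pairs(hk)
        row = {
            "keep_every": k,
            "pct_snp_kept": 100.0 * hk.n_markers / h.n_markers,
            "n_markers": hk.n_markers,
            "n_pairs": len(ap),
            "mean_r2": float(ap["r2"].mean()) if len(ap) else np.nan,
            "sd_r2": float(ap["r2"].std(ddof=1)) if len(ap) > 1 else np.nan,
            "mean_distance_kb": float(ap["distance_bp"].mean() / 1e3)
            if len(ap)
            else np.nan,
        }
        for t in thresholds:
            key = f"pct_r2_gt_{t:g}".replace(".", "p")
            row[key] = 100.0 * proportion_above(ap, t) if len(ap) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
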