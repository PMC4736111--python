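"""Across-population persistence of linkage phase.

For marker pairs common to two populations, the persistence of phase in a
distance bin is the Pearson correlation of the signed LD correlations:

    R = Σ (r_ij(B) − r̄(B)) (r_ij(H) − r̄(H)) / (S(B) · S(H))

over matched pairs (i, j) in the bin.  A value near 1 means a marker–QTL
phase learned in one population transfers to the other; a large fraction of
reversed r signs predicts antagonistic responses to across-population
selection on those markers.

Pairs are matched by exact (chrom, pos_i, pos_j) after intersecting the
marker sets, which presumes both pair tables were computed under the shared
allele coding enforced by :mod:`ldscape.popdata` — R flips sign under a
one-population allele-label swap, so a shared coding is a precondition, not
a convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: bins with fewer matched pairs than this are reported as undefined
MIN_PAIRS_PER_BIN = 3


def match_pairs(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two pair tables on (chrom, pos_i, pos_j).

    Returns columns ``chrom, pos_i, pos_j, distance_bp, r_a, r_b``.
    Raises if no pairs match ("no common markers").
    """
    key = ["chrom", "pos_i", "pos_j"]
    a = pairs_a[key + ["distance_bp", "r_signed"]].rename(columns={"r_signed": "r_a"})
    b = pairs_b[key + ["r_signed"]].rename(columns={"r_signed": "r_b"})
    m = a.merge(b, on=key, how="inner")
    if len(m) == 0:
        raise ValueError("no common markers between the two pair tables")
    return m


def reversed_sign_fraction(r_a: np.ndarray, r_b: np.ndarray) -> float:
    """Fraction of matched pairs whose r signs disagree (r_a · r_b < 0).

    Pairs where either r is exactly zero count as non-reversed.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if len(r_a) == 0:
        raise ValueError("empty bin: reversed-sign fraction undefined")
    return float((r_a * r_b < 0).mean())


def phase_correlation(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    bin_width_bp: int = 100_000,
    max_bp: int = 10_000_000,
    min_pairs: int = MIN_PAIRS_PER_BIN,
) -> pd.DataFrame:
    """Binned phase correlation between two populations.

    Half-open distance bins [k·w, (k+1)·w) from 0 to ``max_bp``; per bin the
    Pearson correlation of matched signed r, the per-population means and
    SDs, and the reversed-sign fraction.  Bins with fewer than ``min_pairs``
    matched pairs (or zero variance in either population) carry
    ``defined=False`` and NaN statistics, with ``n_pairs`` still reported.
    """
    m = match_pairs(pairs_a, pairs_b)
    n_bins = int(np.ceil(max_bp / bin_width_bp))
    d = m["distance_bp"].to_numpy()
    inrange = d < n_bins * bin_width_bp
    m = m.loc[inrange]
    idx = (m["distance_bp"].to_numpy() // bin_width_bp).astype(np.int64)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        ra = m["r_a"].to_numpy()[sel]
        rb = m["r_b"].to_numpy()[sel]
        n = int(sel.sum())
        row = {
            "bin_lo_bp": k * bin_width_bp,
            "bin_hi_bp": (k + 1) * bin_width_bp,
            "n_pairs": n,
            "R": np.nan,
            "mean_r_a": np.nan,
            "mean_r_b": np.nan,
            "sd_r_a": np.nan,
            "sd_r_b": np.nan,
            "reversed_fraction": np.nan,
            "defined": False,
        }
        if n > 0:
            row["mean_r_a"] = float(ra.mean())
            row["mean_r_b"] = float(rb.mean())
            row["reversed_fraction"] = reversed_sign_fraction(ra, rb)
        if n >= min_pairs:
            sa = float(ra.std(ddof=1))
            sb = float(rb.std(ddof=1))
            row["sd_r_a"] = sa
            row["sd_r_b"] = sb
            if sa > 0 and sb > 0:
                ca = ra - ra.mean()
                cb = rb - rb.mean()
                row["R"] = float(
                    np.dot(ca, cb) / np.sqrt(np.dot(ca, ca) * np.dot(cb, cb))
                )
                row["defined"] = True
        rows.append(row)
    return pd.DataFrame(rows)
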