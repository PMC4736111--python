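"""Historical effective population size from distance-stratified LD.

At drift–recombination equilibrium the expected LD between loci at genetic
distance c Morgans is E(r²) = 1/(4·c·Ne + 1), and the LD at distance c
reflects the effective size roughly t = 1/(2c) generations ago.  Inverting:

    Ne(t) = (1 − r̄²) / (4 · c̄ · r̄²)

with r̄² and c̄ the mean r² and mean genetic distance of the SNP pairs whose
c falls in the bin corresponding to generation t.  Physical distance is
converted at 1 Mb = 1 cM, and pairs are taken within 100 Mb (= 1 Morgan) of
the same chromosome so the most recent generation (t = 1, c up to 1 M) is
observable.

Generation bins widen into the past: one generation wide for t = 1..10
(range t ± 0.5), five for t = 15, 20, …, 100 (t ± 2.5), fifty for
t = 150, 200, …, 1000 (t ± 25).  Gaps between regimes (t = 11–14, 105–145)
are intentionally unestimated.  The bin mid-point is reported as c at the
target generation, 1/(2t).

No sample-size correction is applied by default: the estimator is used
exactly as stated above.  ``sample_size_correction=True`` subtracts
1/n_haplotypes from each bin's mean r², removing the finite-sample
inflation of r² — at recent generations (large c, tiny true r²) that
inflation can exceed the signal, so parameter-recovery work on modest
samples should enable it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: genetic map conversion: 1 Mb = 1 cM => Morgans per bp
MORGANS_PER_BP = 1e-8


def morgans_from_bp(distance_bp, cm_per_mb: float = 1.0):
    """Physical → genetic distance: c = bp · rate · 1e-8 Morgans."""
    return np.asarray(distance_bp, dtype=float) * cm_per_mb * 1e-8


def generation_bins() -> pd.DataFrame:
    """The generation-binning table mapping past generations to c ranges.

    Columns: ``t`` (target generation), ``t_lo, t_hi`` (generation range),
    ``c_lo, c_hi`` (Morgans; c = 1/(2t), so c_lo = 1/(2·t_hi) and
    c_hi = 1/(2·t_lo)), ``c_mid`` = 1/(2t).
    """
    targets: list[tuple[float, float, float]] = []
    for t in range(1, 11):
        targets.append((t, t - 0.5, t + 0.5))
    for t in range(15, 101, 5):
        targets.append((t, t - 2.5, t + 2.5))
    for t in range(150, 1001, 50):
        targets.append((t, t - 25.0, t + 25.0))
    rows = []
    for t, t_lo, t_hi in targets:
        rows.append(
            {
                "t": t,
                "t_lo": t_lo,
                "t_hi": t_hi,
                "c_lo": 1.0 / (2.0 * t_hi),
                "c_hi": 1.0 / (2.0 * t_lo),
                "c_mid": 1.0 / (2.0 * t),
            }
        )
    return pd.DataFrame(rows)


def expected_r2(c, ne):
    """Equilibrium expectation E(r²) = 1/(4·c·Ne + 1)."""
    c = np.asarray(c, dtype=float)
    ne = np.asarray(ne, dtype=float)
    return 1.0 / (4.0 * c * ne + 1.0)


def ne_from_r2(r2, c):
    """Inverse of :func:`expected_r2`: Ne = (1 − r²)/(4·c·r²)."""
    r2 = np.asarray(r2, dtype=float)
    c = np.asarray(c, dtype=float)
    return (1.0 - r2) / (4.0 * c * r2)


def ne_trajectory(
    pairs: pd.DataFrame,
    cm_per_mb: float = 1.0,
    sample_size_correction: bool = False,
    n_haplotypes: int | None = None,
) -> pd.DataFrame:
    """Ne estimate per generation bin from a syntenic pair table.

    ``pairs`` should be enumerated with a 100 Mb distance cap (1 Morgan at
    the default map rate) so the t = 1 bin is populated.  Pairs with r² = 0
    or r² = 1 are excluded (the estimator is defined for 0 < r² < 1).  The
    c-selection interval is half-open [c_lo, c_hi).

    Returns one row per generation bin, ordered by t, with ``n_pairs``,
    ``mean_r2``, ``mean_c`` and ``ne``; unusable (empty) bins carry
    ``available=False`` and NaN estimates.
    """
    if sample_size_correction and not n_haplotypes:
        raise ValueError("sample_size_correction requires n_haplotypes")
    bins = generation_bins()
    if len(pairs):
        r2 = pairs["r2"].to_numpy(dtype=float)
        c = morgans_from_bp(pairs["distance_bp"].to_numpy(), cm_per_mb)
        usable = (r2 > 0.0) & (r2 < 1.0)
        r2, c = r2[usable], c[usable]
    else:
        r2 = np.empty(0)
        c = np.empty(0)
    rows = []
    for _, b in bins.iterrows():
        sel = (c >= b["c_lo"]) & (c < b["c_hi"])
        n = int(sel.sum())
        row = {
            "t": b["t"],
            "c_lo": b["c_lo"],
            "c_hi": b["c_hi"],
            "c_mid": b["c_mid"],
            "n_pairs": n,
            "mean_r2": np.nan,
            "mean_c": np.nan,
            "ne": np.nan,
            "available": False,
        }
        if n > 0:
            mean_r2 = float(r2[sel].mean())
            if sample_size_correction:
                mean_r2 -= 1.0 / n_haplotypes
            mean_c = float(c[sel].mean())
            row["mean_r2"] = mean_r2
            row["mean_c"] = mean_c
            if 0.0 < mean_r2 < 1.0:
                row["ne"] = float(ne_from_r2(mean_r2, mean_c))
                row["available"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def ne_at_generation(
    pairs: pd.DataFrame,
    t: int,
    cm_per_mb: float = 1.0,
    sample_size_correction: bool = False,
    n_haplotypes: int | None = None,
) -> pd.Series:
    """Single-generation convenience wrapper around :func:`ne_trajectory`."""
    traj = ne_trajectory(
        pairs,
        cm_per_mb=cm_per_mb,
        sample_size_correction=sample_size_correction,
        n_haplotypes=n_haplotypes,
    )
    sel = traj[traj["t"] == t]
    if len(sel) == 0:
        raise ValueError(f"t={t} is not a target generation of the binning scheme")
    return sel.iloc[0]
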