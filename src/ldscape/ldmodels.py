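"""ANCOVA models of LD heterogeneity across chromosomes and breeds.

Two ordinary-least-squares models of pairwise r² on log-distance are
provided through a single Model/Results pair:

* order 1 (adjacent pairs): r² = μ + cᵢ + bⱼ + β₁·d* + cbᵢⱼ + e — effects of
  chromosome, breed, their interaction, and a linear regression on the
  adjusted log distance d* = log₁₀(d) − log₁₀(d̄), with d̄ the mean physical
  distance over the model's input pairs (shared across breeds).
* order 3 (all syntenic pairs): adds quadratic and cubic powers of d* and
  the full set of chromosome/breed interactions with every power.

Chromosome and breed enter with sum-to-zero contrasts so μ is the overall
mean of r² and least-squares means are literal.  Marginal (type-III-style)
F-tests are reported per term.  Fitting is delegated to
``statsmodels.OLS``; the design matrices, term grouping, LS-mean contrasts
and prediction rows are constructed here.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


def panel_distance_kb(n_markers: int, genome_mb: float = 3000.0) -> int:
    """Expected inter-marker distance (Kb) of an evenly spaced panel.

    genome length (Mb → Kb) divided by marker count, rounded half-up:
    150K markers on a 3,000 Mb genome → 20 Kb; 80K → 38 Kb; 3K → 1000 Kb.
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be > 0")
    return int(math.floor(genome_mb * 1000.0 / n_markers + 0.5))


#: commercial-panel marker counts and the implied inter-marker distances
COMMERCIAL_PANELS = (150_000, 80_000, 50_000, 20_000, 8_000, 3_000)


def make_model_records(pairs_by_breed: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-breed pair tables into model records.

    Input: ``{breed_label: pair table}`` (from :mod:`ldscape.ldcore`).
    Output columns: ``r2, chrom, breed, distance_bp``.
    """
    frames = []
    for breed, pairs in pairs_by_breed.items():
        frames.append(
            pd.DataFrame(
                {
                    "r2": pairs["r2"].to_numpy(),
                    "chrom": pairs["chrom"].astype(str).to_numpy(),
                    "breed": str(breed),
                    "distance_bp": pairs["distance_bp"].to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if (out["distance_bp"] <= 0).any():
        raise ValueError("all pair distances must be > 0")
    return out


def _sum_code(idx: np.ndarray, k: int) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor with k levels (k−1 cols)."""
    Z = np.zeros((len(idx), k - 1))
    for c in range(k - 1):
        Z[idx == c, c] = 1.0
    Z[idx == k - 1, :] = -1.0
    return Z


class LDHeterogeneityModel:
    """OLS ANCOVA of pairwise r² on distance, chromosome and breed.

    Parameters
    ----------
    records : DataFrame
        Columns ``r2, chrom, breed, distance_bp`` (see
        :func:`make_model_records`).
    order : {1, 3}
        1 — linear distance term, no slope interactions (adjacent-pair
        model); 3 — cubic in d* with full chromosome/breed interactions at
        each power (all-syntenic-pairs model).
    powers, slope_interactions :
        Explicit term control overriding ``order``; an order-3 model
        restricted to ``powers=(1,)`` and ``slope_interactions=False`` has
        the identical design to the order-1 model.

    Both breeds and at least two chromosomes must be present, with every
    chromosome observed in every breed (the design is rank-deficient
    otherwise).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        order: int = 1,
        powers: Sequence[int] | None = None,
        slope_interactions: bool | None = None,
    ):
        if order not in (1, 3):
            raise ValueError("order must be 1 or 3")
        self.order = order
        self.powers = tuple(powers) if powers is not None else (
            (1,) if order == 1 else (1, 2, 3)
        )
        self.slope_interactions = (
            slope_interactions if slope_interactions is not None else (order == 3)
        )
        rec = records.reset_index(drop=True)
        if (rec["distance_bp"] <= 0).any():
            raise ValueError("all pair distances must be > 0")
        self.records = rec
        self.chrom_levels = sorted(rec["chrom"].astype(str).unique(), key=_level_key)
        self.breed_levels = sorted(rec["breed"].astype(str).unique())
        if len(self.breed_levels) < 2:
            raise ValueError("both breeds must be present")
        if len(self.chrom_levels) < 2:
            raise ValueError("at least two chromosomes required")
        cells = rec.groupby(["chrom", "breed"]).size()
        for c in self.chrom_levels:
            for b in self.breed_levels:
                if (c, b) not in cells.index:
                    raise ValueError(
                        f"rank deficiency: no records for chromosome {c} in breed {b}"
                    )
        # d* uses a single d̄ over the pooled input
        self.d_bar = float(rec["distance_bp"].mean())
        self.distance_range_bp = (
            float(rec["distance_bp"].min()),
            float(rec["distance_bp"].max()),
        )

    # -- design ------------------------------------------------------------

    def _d_star(self, distance_bp: np.ndarray) -> np.ndarray:
        return np.log10(np.asarray(distance_bp, dtype=float)) - np.log10(self.d_bar)

    def _design(
        self, chrom: np.ndarray, breed: np.ndarray, d_star: np.ndarray
    ) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
        kc = len(self.chrom_levels)
        kb = len(self.breed_levels)
        ci = np.array([self.chrom_levels.index(str(c)) for c in chrom])
        bi = np.array([self.breed_levels.index(str(b)) for b in breed])
        Zc = _sum_code(ci, kc)
        Zb = _sum_code(bi, kb)
        cols: list[np.ndarray] = [np.ones((len(ci), 1))]
        names: list[str] = ["mu"]
        groups: dict[str, list[int]] = {}

        def add(name_prefix, block, col_names):
            start = sum(c.shape[1] for c in cols)
            cols.append(block)
            names.extend(col_names)
            groups[name_prefix] = list(range(start, start + block.shape[1]))

        add("chrom", Zc, [f"chrom[{l}]" for l in self.chrom_levels[:-1]])
        add("breed", Zb, [f"breed[{l}]" for l in self.breed_levels[:-1]])
        inter = np.einsum("ij,ik->ijk", Zc, Zb).reshape(len(ci), -1)
        add(
            "chrom:breed",
            inter,
            [
                f"chrom[{c}]:breed[{b}]"
                for c in self.chrom_levels[:-1]
                for b in self.breed_levels[:-1]
            ],
        )
        for p in self.powers:
            dp = (d_star**p)[:, None]
            add(f"d{p}", dp, [f"d{p}"])
            if self.slope_interactions:
                add(
                    f"chrom:d{p}",
                    Zc * dp,
                    [f"chrom[{l}]:d{p}" for l in self.chrom_levels[:-1]],
                )
                add(
                    f"breed:d{p}",
                    Zb * dp,
                    [f"breed[{l}]:d{p}" for l in self.breed_levels[:-1]],
                )
                add(
                    f"chrom:breed:d{p}",
                    inter * dp,
                    [
                        f"chrom[{c}]:breed[{b}]:d{p}"
                        for c in self.chrom_levels[:-1]
                        for b in self.breed_levels[:-1]
                    ],
                )
        X = np.hstack(cols)
        return X, names, groups

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        rec = self.records
        X, names, _ = self._design(
            rec["chrom"].to_numpy(),
            rec["breed"].to_numpy(),
            self._d_star(rec["distance_bp"].to_numpy()),
        )
        return X, names

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "LDHeterogeneityResults":
        rec = self.records
        X, names, groups = self._design(
            rec["chrom"].to_numpy(),
            rec["breed"].to_numpy(),
            self._d_star(rec["distance_bp"].to_numpy()),
        )
        res = sm.OLS(rec["r2"].to_numpy(), X).fit()
        return LDHeterogeneityResults(self, res, names, groups)


def _level_key(label: str):
    try:
        return (0, int(label), label)
    except ValueError:
        return (1, 0, label)


class LDHeterogeneityResults:
    """Fitted LD-heterogeneity ANCOVA: coefficients, marginal F-tests,
    least-squares means and panel-distance predictions."""

    def __init__(self, model: LDHeterogeneityModel, sm_results, names, groups):
        self.model = model
        self._res = sm_results
        self.param_names = names
        self.term_columns = groups
        self.params = pd.Series(sm_results.params, index=names)
        self.bse = pd.Series(sm_results.bse, index=names)
        self.resid = np.asarray(sm_results.resid)
        self.fittedvalues = np.asarray(sm_results.fittedvalues)
        self.scale = float(sm_results.scale)
        self.df_resid = float(sm_results.df_resid)

    # -- effects -----------------------------------------------------------

    def _factor_effects(self, prefix: str, levels: list[str]) -> pd.Series:
        vals = np.array([self.params[f"{prefix}[{l}]"] for l in levels[:-1]])
        return pd.Series(np.append(vals, -vals.sum()), index=levels)

    @property
    def chromosome_effects(self) -> pd.Series:
        """Sum-to-zero chromosome effects c_i (all levels)."""
        return self._factor_effects("chrom", self.model.chrom_levels)

    @property
    def breed_effects(self) -> pd.Series:
        """Sum-to-zero breed effects b_j (all levels)."""
        return self._factor_effects("breed", self.model.breed_levels)

    # -- inference ---------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Marginal (type-III-style) F-test per model term."""
        k = len(self.params)
        rows = []
        for term, cols in self.term_columns.items():
            R = np.zeros((len(cols), k))
            for r, c in enumerate(cols):
                R[r, c] = 1.0
            ft = self._res.f_test(R)
            rows.append(
                {
                    "term": term,
                    "df": len(cols),
                    "F": float(ft.fvalue),
                    "p_value": float(ft.pvalue),
                }
            )
        return pd.DataFrame(rows)

    # -- least-squares means ----------------------------------------------

    def ls_means_by_chromosome(self) -> pd.DataFrame:
        """Predicted marginal mean r² ± SE per chromosome, averaged across
        breed levels, at d* = 0 (the mean inter-marker distance)."""
        m = self.model
        V = self._res.cov_params()
        rows = []
        for c in m.chrom_levels:
            Ls = []
            for b in m.breed_levels:
                X, _, _ = m._design(
                    np.array([c]), np.array([b]), np.zeros(1)
                )
                Ls.append(X[0])
            L = np.mean(Ls, axis=0)
            est = float(L @ self.params.to_numpy())
            se = float(np.sqrt(L @ V @ L))
            rows.append({"chrom": c, "ls_mean_r2": est, "se": se})
        return pd.DataFrame(rows)

    # -- prediction --------------------------------------------------------

    def predict(
        self,
        chrom,
        breed,
        distance_bp,
    ) -> pd.DataFrame:
        """Predicted r² for (chromosome, breed, distance) combinations.

        Inputs broadcast like numpy arrays.  A prediction at a distance
        outside the fitted range carries ``extrapolated=True``.
        """
        chrom = np.atleast_1d(np.asarray(chrom, dtype=object))
        breed = np.atleast_1d(np.asarray(breed, dtype=object))
        distance_bp = np.atleast_1d(np.asarray(distance_bp, dtype=float))
        chrom, breed, distance_bp = np.broadcast_arrays(chrom, breed, distance_bp)
        m = self.model
        X, _, _ = m._design(chrom, breed, m._d_star(distance_bp))
        pred = X @ self.params.to_numpy()
        lo, hi = m.distance_range_bp
        return pd.DataFrame(
            {
                "chrom": chrom.astype(str),
                "breed": breed.astype(str),
                "distance_bp": distance_bp,
                "r2_pred": pred,
                "extrapolated": (distance_bp < lo) | (distance_bp > hi),
            }
        )

    def predict_panel_grid(
        self,
        panels: Sequence[int] = COMMERCIAL_PANELS,
        genome_mb: float = 3000.0,
    ) -> pd.DataFrame:
        """Predicted r² at each commercial panel's inter-marker distance, for
        every chromosome × breed combination."""
        m = self.model
        frames = []
        for n_markers in panels:
            d_kb = panel_distance_kb(n_markers, genome_mb)
            grid_c = np.repeat(m.chrom_levels, len(m.breed_levels))
            grid_b = np.tile(m.breed_levels, len(m.chrom_levels))
            df = self.predict(grid_c, grid_b, d_kb * 1000.0)
            df.insert(0, "panel_n_markers", n_markers)
            df.insert(1, "panel_distance_kb", d_kb)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "LD heterogeneity ANCOVA "
            f"(order {m.order}; powers {m.powers}; "
            f"slope interactions {'on' if m.slope_interactions else 'off'})",
            f"records: {len(m.records)}   chromosomes: {len(m.chrom_levels)}   "
            f"breeds: {m.breed_levels}",
            f"mean distance d-bar: {m.d_bar:.1f} bp",
            f"R-squared: {self._res.rsquared:.4f}   "
            f"residual df: {self.df_resid:.0f}   scale: {self.scale:.3e}",
            "",
            "Marginal F-tests:",
        ]
        an = self.anova()
        for _, r in an.iterrows():
            lines.append(
                f"  {r['term']:<16s} df={int(r['df']):<3d} "
                f"F={r['F']:#10.4g}  p={r['p_value']:.3g}"
            )
        lines.append("")
        lines.append(f"mu (overall mean r2): {self.params['mu']:.5f}")
        return "\n".join(lines)
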