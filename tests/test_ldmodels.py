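import numpy as np
import pandas as pd
import pytest

from ldscape.ldmodels import (
    COMMERCIAL_PANELS,
    LDHeterogeneityModel,
    make_model_records,
    panel_distance_kb,
)


def synth_records(
    chroms=("1", "2", "3"),
    breeds=("B", "H"),
    n_per_cell=8,
    mu=0.2,
    chrom_eff=None,
    breed_eff=None,
    beta=(-0.05, 0.0, 0.0),
    interaction=None,
    noise_sd=0.0,
    seed=0,
):
    """Records generated from the ANCOVA model itself with sum-to-zero
    effects; the generating coefficients are returned for recovery checks."""
    rng = np.random.default_rng(seed)
    kc, kb = len(chroms), len(breeds)
    if chrom_eff is None:
        chrom_eff = np.linspace(-0.02, 0.02, kc)
        chrom_eff -= chrom_eff.mean()
    if breed_eff is None:
        breed_eff = np.array([0.03, -0.03]) if kb == 2 else np.zeros(kb)
    if interaction is None:
        interaction = np.zeros((kc, kb))
    rows = []
    for ic, c in enumerate(chroms):
        for ib, b in enumerate(breeds):
            d = rng.uniform(20_000, 2_000_000, n_per_cell)
            rows.append(
                pd.DataFrame({"chrom": c, "breed": b, "distance_bp": d, "r2": 0.0})
            )
            rows[-1]["_ic"] = ic
            rows[-1]["_ib"] = ib
    rec = pd.concat(rows, ignore_index=True)
    d_bar = rec["distance_bp"].mean()
    ds = np.log10(rec["distance_bp"]) - np.log10(d_bar)
    ic = rec["_ic"].to_numpy()
    ib = rec["_ib"].to_numpy()
    y = mu + np.asarray(chrom_eff)[ic] + np.asarray(breed_eff)[ib]
    y = y + np.asarray(interaction)[ic, ib]
    for p, bp in enumerate(beta, start=1):
        y = y + bp * ds**p
    y = y + rng.normal(0, noise_sd, len(y))
    rec["r2"] = y
    return rec.drop(columns=["_ic", "_ib"]), {
        "mu": mu,
        "chrom_eff": np.asarray(chrom_eff, dtype=float),
        "breed_eff": np.asarray(breed_eff, dtype=float),
        "beta": beta,
    }


class TestPanelDistance:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (150_000, 20),
            (80_000, 38),
            (50_000, 60),
            (20_000, 150),
            (8_000, 375),
            (3_000, 1000),
        ],
    )
    def test_commercial_panels(self, n, expected):
        assert panel_distance_kb(n) == expected

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            panel_distance_kb(0)


class TestAdjacentModel:
    def test_noise_free_exact_recovery(self):
        rec, truth = synth_records(beta=(-0.1,))
        fit = LDHeterogeneityModel(rec, order=1).fit()
        assert fit.params["mu"] == pytest.approx(truth["mu"], abs=1e-8)
        assert np.allclose(
            fit.chromosome_effects.to_numpy(), truth["chrom_eff"], atol=1e-8
        )
        assert np.allclose(fit.breed_effects.to_numpy(), truth["breed_eff"], atol=1e-8)
        assert fit.params["d1"] == pytest.approx(-0.1, abs=1e-8)

    def test_constant_response_all_effects_zero(self):
        rec, _ = synth_records(mu=0.42, chrom_eff=[0, 0, 0], breed_eff=[0, 0], beta=(0.0,))
        fit = LDHeterogeneityModel(rec, order=1).fit()
        assert fit.params["mu"] == pytest.approx(0.42, abs=1e-10)
        other = fit.params.drop("mu")
        assert np.allclose(other.to_numpy(), 0.0, atol=1e-10)

    def test_residual_orthogonality(self):
        rec, _ = synth_records(noise_sd=0.05, seed=3)
        model = LDHeterogeneityModel(rec, order=1)
        fit = model.fit()
        X, _ = model.design_matrix()
        assert np.max(np.abs(X.T @ fit.resid)) < 1e-8

    def test_record_order_permutation_invariance(self):
        rec, _ = synth_records(noise_sd=0.03, seed=4)
        perm = np.random.default_rng(0).permutation(len(rec))
        f1 = LDHeterogeneityModel(rec, order=1).fit()
        f2 = LDHeterogeneityModel(rec.iloc[perm], order=1).fit()
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-10)

    def test_rank_deficiency_names_cell(self):
        rec, _ = synth_records()
        rec = rec[~((rec["chrom"] == "2") & (rec["breed"] == "H"))]
        with pytest.raises(ValueError, match="chromosome 2 in breed H"):
            LDHeterogeneityModel(rec, order=1)

    def test_distance_slope_detected_significant(self):
        rec, _ = synth_records(n_per_cell=60, beta=(-0.05,), noise_sd=0.01, seed=5)
        fit = LDHeterogeneityModel(rec, order=1).fit()
        an = fit.anova().set_index("term")
        assert an.loc["d1", "p_value"] < 1e-6


class TestSyntenicModel:
    def test_noise_free_cubic_recovery(self):
        inter = np.array([[0.01, -0.01], [0.0, 0.0], [-0.01, 0.01]])
        rec, truth = synth_records(
            n_per_cell=40, beta=(-0.08, 0.015, -0.002), interaction=inter
        )
        fit = LDHeterogeneityModel(rec, order=3).fit()
        assert fit.params["mu"] == pytest.approx(truth["mu"], abs=1e-6)
        assert fit.params["d1"] == pytest.approx(-0.08, abs=1e-6)
        assert fit.params["d2"] == pytest.approx(0.015, abs=1e-6)
        assert fit.params["d3"] == pytest.approx(-0.002, abs=1e-6)
        assert fit.params["chrom[1]:breed[B]"] == pytest.approx(0.01, abs=1e-6)

    def test_nested_limit_higher_orders_vanish(self):
        rec, _ = synth_records(n_per_cell=30, beta=(-0.06,))
        fit3 = LDHeterogeneityModel(rec, order=3).fit()
        fit1 = LDHeterogeneityModel(rec, order=1).fit()
        assert abs(fit3.params["d2"]) < 1e-8
        assert abs(fit3.params["d3"]) < 1e-8
        grid = fit1.predict(["1", "2"], ["B", "B"], [100_000, 700_000])
        grid3 = fit3.predict(["1", "2"], ["B", "B"], [100_000, 700_000])
        assert np.allclose(grid["r2_pred"], grid3["r2_pred"], atol=1e-8)

    def test_restricted_design_identical_to_first_order(self):
        rec, _ = synth_records(noise_sd=0.02, seed=6)
        m1 = LDHeterogeneityModel(rec, order=1)
        m3r = LDHeterogeneityModel(rec, order=3, powers=(1,), slope_interactions=False)
        X1, n1 = m1.design_matrix()
        X3, n3 = m3r.design_matrix()
        assert n1 == n3
        assert np.array_equal(X1, X3)
        assert np.allclose(
            m1.fit().params.to_numpy(), m3r.fit().params.to_numpy(), atol=1e-12
        )

    def test_centering_invariance(self):
        # scaling all distances rescales d-bar but leaves d* and fits unchanged
        rec, _ = synth_records(noise_sd=0.02, seed=7)
        rec2 = rec.copy()
        rec2["distance_bp"] = rec2["distance_bp"] * 10
        f1 = LDHeterogeneityModel(rec, order=3).fit()
        f2 = LDHeterogeneityModel(rec2, order=3).fit()
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-9)


class TestLsMeansAndPrediction:
    def test_balanced_ls_mean_equals_mu_plus_chrom(self):
        rec, truth = synth_records(beta=(0.0,))
        fit = LDHeterogeneityModel(rec, order=1).fit()
        lsm = fit.ls_means_by_chromosome()
        expect = truth["mu"] + truth["chrom_eff"]
        assert np.allclose(lsm["ls_mean_r2"].to_numpy(), expect, atol=1e-8)

    def test_breed_effects_cancel_in_ls_mean(self):
        rec, truth = synth_records(breed_eff=[0.07, -0.07], beta=(0.0,))
        fit = LDHeterogeneityModel(rec, order=1).fit()
        lsm = fit.ls_means_by_chromosome()
        assert np.allclose(
            lsm["ls_mean_r2"].to_numpy(), truth["mu"] + truth["chrom_eff"], atol=1e-8
        )

    def test_ls_mean_equals_brute_force_grid_average(self):
        rec, _ = synth_records(noise_sd=0.04, seed=8)
        fit = LDHeterogeneityModel(rec, order=1).fit()
        lsm = fit.ls_means_by_chromosome().set_index("chrom")
        model = fit.model
        d_at_zero = model.d_bar  # d* = 0
        for c in model.chrom_levels:
            preds = fit.predict(
                [c] * len(model.breed_levels), model.breed_levels, d_at_zero
            )
            assert lsm.loc[c, "ls_mean_r2"] == pytest.approx(
                preds["r2_pred"].mean(), abs=1e-10
            )

    def test_prediction_at_dbar_is_cell_mean_parameterisation(self):
        inter = np.array([[0.02, -0.02], [0.0, 0.0], [-0.02, 0.02]])
        rec, truth = synth_records(beta=(0.0, 0.0, 0.0), interaction=inter)
        fit = LDHeterogeneityModel(rec, order=3).fit()
        pred = fit.predict("1", "B", fit.model.d_bar)
        expect = truth["mu"] + truth["chrom_eff"][0] + truth["breed_eff"][0] + 0.02
        assert pred["r2_pred"].iloc[0] == pytest.approx(expect, abs=1e-6)

    def test_extrapolation_flagged(self):
        rec, _ = synth_records()
        fit = LDHeterogeneityModel(rec, order=1).fit()
        out = fit.predict("1", "B", [50_000, 9_000_000])
        assert not out["extrapolated"].iloc[0]
        assert out["extrapolated"].iloc[1]

    def test_monotone_decay_prediction_over_panel_grid(self):
        # monotone generating curve -> non-increasing panel predictions
        rec, _ = synth_records(n_per_cell=50, beta=(-0.07,), seed=9)
        fit = LDHeterogeneityModel(rec, order=3).fit()
        grid = fit.predict_panel_grid(COMMERCIAL_PANELS)
        one = grid[(grid["chrom"] == "1") & (grid["breed"] == "B")]
        one = one.sort_values("panel_distance_kb")
        assert (np.diff(one["r2_pred"]) <= 1e-10).all()


class TestRecords:
    def test_make_records_stacks_breeds(self):
        pa = pd.DataFrame(
            {"chrom": ["1"], "pos_i": [1], "pos_j": [2], "distance_bp": [100],
             "r_signed": [0.5], "r2": [0.25]}
        )
        rec = make_model_records({"B": pa, "H": pa})
        assert len(rec) == 2
        assert set(rec["breed"]) == {"B", "H"}

    def test_nonpositive_distance_rejected(self):
        pa = pd.DataFrame(
            {"chrom": ["1"], "pos_i": [1], "pos_j": [1], "distance_bp": [0],
             "r_signed": [0.5], "r2": [0.25]}
        )
        with pytest.raises(ValueError):
            make_model_records({"B": pa, "H": pa})
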