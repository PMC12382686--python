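"""Synthetic-data generators: determinism, noise models, assay calibration,
and full generate-then-refit closure."""

import numpy as np
import pytest

from soilcolumn.hydraulics import SoilHydraulicModel
from soilcolumn.inverse import InfiltrationCurveFitter
from soilcolumn.richards import ColumnSpec, TimeGrid
from soilcolumn.synthetic import (
    CALIBRATION_INTERCEPT,
    NoiseModel,
    absorbance_from_concentration,
    concentration_from_absorbance,
    gen_conc_profiles,
    gen_grain_size,
    gen_infiltration,
)


class TestInfiltrationGenerator:
    def test_noise_free_equals_solver_output(self, fast_column, fast_model, fast_grid, fast_flow):
        ds = gen_infiltration(fast_model, fast_column, fast_grid, flow=fast_flow)
        expected = np.interp(ds.payload["t_h"], fast_flow.t, fast_flow.cumulative_infiltration)
        np.testing.assert_array_equal(ds.payload["I_cm"].to_numpy(), expected)
        np.testing.assert_array_equal(ds.payload["I_cm"], ds.clean["I_cm"])

    def test_seed_determinism(self, fast_column, fast_model, fast_grid, fast_flow):
        nm = NoiseModel("multiplicative", 0.05)
        kw = dict(noise_model=nm, flow=fast_flow)
        a = gen_infiltration(fast_model, fast_column, fast_grid, seed=7, **kw)
        b = gen_infiltration(fast_model, fast_column, fast_grid, seed=7, **kw)
        c = gen_infiltration(fast_model, fast_column, fast_grid, seed=8, **kw)
        np.testing.assert_array_equal(a.payload["I_cm"], b.payload["I_cm"])
        assert not np.array_equal(a.payload["I_cm"], c.payload["I_cm"])
        np.testing.assert_array_equal(a.clean["I_cm"], c.clean["I_cm"])  # same truth

    def test_multiplicative_noise_level(self, fast_column, fast_model, fast_grid, fast_flow):
        """Empirical residual sd over many replicates matches sigma = 5%."""
        nm = NoiseModel("multiplicative", 0.05)
        rels = []
        for seed in range(20):
            ds = gen_infiltration(fast_model, fast_column, fast_grid, noise_model=nm,
                                  seed=seed, flow=fast_flow)
            clean = ds.clean["I_cm"].to_numpy()
            rels.append((ds.payload["I_cm"].to_numpy() - clean) / clean)
        sd = np.std(np.concatenate(rels))
        assert 0.035 < sd < 0.065

    def test_truth_sidecar_round_trips(self, fast_column, fast_model, fast_grid, fast_flow):
        import json

        ds = gen_infiltration(fast_model, fast_column, fast_grid, flow=fast_flow)
        sidecar = json.loads(json.dumps(ds.truth_sidecar()))
        assert sidecar["truth"]["Ks"] == fast_model.Ks
        assert sidecar["noise"]["kind"] == "none"


class TestProfileGenerator:
    def test_matches_sample_profile_and_zero_truth(self, c1, c1_flow):
        grid = TimeGrid(dt=2e-3, t_end=0.3, dt_init=1e-6, save_interval=2e-3)
        ds = gen_conc_profiles(c1.model, c1.transport, c1.column, grid, flow=c1_flow)
        assert list(ds.payload.columns) == ["depth_cm", "concentration_mg_L"]
        np.testing.assert_array_equal(
            ds.payload["concentration_mg_L"], ds.clean["concentration_mg_L"]
        )
        # zero inlet concentration produces an all-zero profile
        zero_tp = type(c1.transport)(dispersion_coefficient=9.55e-3, C0=0.0)
        ds0 = gen_conc_profiles(c1.model, zero_tp, c1.column, grid, flow=c1_flow)
        np.testing.assert_array_equal(ds0.payload["concentration_mg_L"].to_numpy(), 0.0)

    def test_sulfate_truth_penetrates_deeper_at_equal_time(self, c1, c2):
        """Once both columns run at their steady rates, the c2 truth (higher
        Ks and D) has pushed solute deeper than c1 at equal elapsed time.
        (At very early time c1 is ahead: its stronger capillary pull wins
        before conductivity takes over.)"""
        grid = TimeGrid(dt=2e-3, t_end=0.6, dt_init=1e-6, save_interval=2e-3)
        t_min = 0.6 * 60.0
        p1 = gen_conc_profiles(c1.model, c1.transport, c1.column, grid, time_min=t_min)
        p2 = gen_conc_profiles(c2.model, c2.transport, c2.column, grid, time_min=t_min)
        c1_deep = p1.payload["concentration_mg_L"].to_numpy()[-2:] / c1.transport.C0
        c2_deep = p2.payload["concentration_mg_L"].to_numpy()[-2:] / c2.transport.C0
        assert np.all(c2_deep >= c1_deep)
        assert c2_deep.sum() > c1_deep.sum()


class TestGrainSizeGenerator:
    TRUTH = dict(Dd=1136.6942, m=0.18609, n=3.1784, s=0.6923)

    def test_characteristic_diameter_value(self):
        ds = gen_grain_size(diameters_um=[self.TRUTH["Dd"]], **self.TRUTH)
        assert ds.payload["cumulative_fraction"][0] == pytest.approx(2.0 ** (-0.18609), rel=1e-12)
        assert ds.payload["cumulative_fraction"][0] == pytest.approx(0.879, abs=5e-4)

    def test_limits_and_rising_limb_monotonicity_with_small_noise(self):
        """Clipped noisy curves stay in [0, 1]; on the rising limb (where
        adjacent increments dwarf sigma = 0.01) monotonicity survives the
        noise.  In the flat tails inversions are unavoidable and the fitter
        input is made isotonic instead."""
        d = np.geomspace(1.0, 1e6, 25)
        clean = gen_grain_size(diameters_um=d, **self.TRUTH).payload[
            "cumulative_fraction"].to_numpy()
        limb = (clean > 0.05) & (clean < 0.95)
        violations = 0
        for seed in range(20):
            ds = gen_grain_size(diameters_um=d, noise_model=NoiseModel("additive", 0.01),
                                seed=seed, **self.TRUTH)
            f = ds.payload["cumulative_fraction"].to_numpy()
            assert f.min() >= 0.0 and f.max() <= 1.0
            violations += int(np.any(np.diff(f[limb]) < 0))
        assert violations <= 2

    def test_saturates_to_one(self):
        ds = gen_grain_size(diameters_um=[1e12], **self.TRUTH)
        assert ds.payload["cumulative_fraction"][0] == pytest.approx(1.0, abs=1e-6)


class TestAssayCalibration:
    def test_intercept_is_zero_concentration(self):
        assert concentration_from_absorbance(CALIBRATION_INTERCEPT) == 0.0

    def test_forward_value(self):
        assert absorbance_from_concentration(100.0) == pytest.approx(0.1892, rel=1e-12)

    def test_round_trip_identity(self):
        c = np.array([0.0, 10.0, 150.0, 300.0])
        np.testing.assert_allclose(
            concentration_from_absorbance(absorbance_from_concentration(c)), c, atol=1e-10
        )

    def test_below_intercept_flagged(self):
        with pytest.raises(ValueError):
            concentration_from_absorbance(0.05)
        assert concentration_from_absorbance(0.05, clip_negative=True) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            absorbance_from_concentration(-1.0)


class TestPipelineClosure:
    def test_generate_then_fit_recovers_random_truths(self, fast_model):
        """Noise-free closure: for random (Ks, psi_d) inside the search box the
        generate -> refit loop returns the generating values."""
        column = ColumnSpec(length=4.0, ponded_head=3.5, theta_initial=0.20, dz=0.1)
        t_obs = np.arange(1, 16) / 60.0
        grid = TimeGrid(dt=2e-3, t_end=0.25, dt_init=1e-6, output_times=t_obs)
        rng = np.random.default_rng(99)
        for _ in range(5):
            Ks = 10.0 ** rng.uniform(np.log10(0.3), np.log10(4.0))
            psi_d = 10.0 ** rng.uniform(np.log10(20.0), np.log10(200.0))
            truth = fast_model.with_(Ks=Ks, psi_d=psi_d)
            ds = gen_infiltration(truth, column, grid)
            template = fast_model.with_(Ks=1.0, psi_d=60.0)
            est = InfiltrationCurveFitter(column, template, grid=grid, n_starts=1)
            est.fit(ds.payload["t_h"].to_numpy(), ds.payload["I_cm"].to_numpy())
            assert est.Ks_ == pytest.approx(Ks, rel=0.02), (Ks, psi_d)
            assert est.psi_d_ == pytest.approx(psi_d, rel=0.02), (Ks, psi_d)
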