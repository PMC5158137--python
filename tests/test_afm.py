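"""Sneddon contact model, force-indentation conversion, modulus fitting, rank test."""

import itertools

import numpy as np
import pytest

from mtnet import afm, synth
from mtnet.afm import (
    BaselineError,
    FitConfig,
    ForceCurve,
    ModelRangeError,
    batch_fit,
    compare_groups,
    fit_hertz,
    hertz_force,
    sneddon_delta_of_a,
    sneddon_force,
    to_force_indentation,
)


class TestSneddonModel:
    def test_zero_indentation_zero_force(self):
        assert sneddon_force(0.0, 1000.0, 0.5, 2250.0) == 0.0

    def test_delta_at_tenth_radius(self):
        # delta(a = Rs/10) slightly exceeds the Hertz limit a^2/Rs
        Rs, a = 2250.0, 225.0
        delta = sneddon_delta_of_a(a, Rs)
        assert delta == pytest.approx(22.575, abs=1e-3)
        assert delta > a * a / Rs  # 22.5

    def test_hertz_limit_within_one_percent(self):
        Rs = 2250.0
        for delta in (1.0, 5.0, 10.0, Rs * 0.005):
            F_s = sneddon_force(delta, 1000.0, 0.5, Rs)
            F_h = hertz_force(delta, 1000.0, 0.5, Rs)
            assert F_s == pytest.approx(F_h, rel=0.01)

    def test_monotone_delta_and_force(self):
        Rs = 2250.0
        a = np.linspace(1.0, Rs * 0.99, 400)
        delta = sneddon_delta_of_a(a, Rs)
        assert np.all(np.diff(delta) > 0)
        F = sneddon_force(np.linspace(0.1, 500.0, 200), 800.0, 0.5, Rs)
        assert np.all(np.diff(F) > 0)

    def test_out_of_range_indentation(self):
        with pytest.raises(ModelRangeError):
            sneddon_force(1e6, 1000.0, 0.5, 100.0)
        with pytest.raises(ModelRangeError):
            sneddon_force(-1.0, 1000.0, 0.5, 100.0)

    def test_inversion_consistency(self):
        Rs = 2250.0
        for delta in (0.5, 50.0, 400.0):
            a = afm.sneddon_contact_radius(delta, Rs)
            assert sneddon_delta_of_a(a, Rs) == pytest.approx(delta, rel=1e-9)


class TestForceIndentation:
    def _flat_curve(self, k=0.08):
        z = np.arange(0.0, 500.0, 2.0)
        return ForceCurve(z=z, d=np.zeros_like(z), k=k, Rs=2250.0)

    def test_arithmetic(self):
        # k = 0.08 N/m, corrected deflection 20 nm at z - z0 = 100 nm
        z = np.arange(0.0, 301.0, 10.0)
        d = np.zeros_like(z)
        d[z > 200.0] = 20.0
        curve = ForceCurve(z=z, d=d, k=0.08, Rs=2250.0)
        ic = to_force_indentation(curve, z0=200.0)
        i = np.nonzero(z == 300.0)[0][0]
        assert ic.F[i] == pytest.approx(1.6)
        assert ic.delta[i] == pytest.approx(80.0)

    def test_zero_deflection(self):
        curve = self._flat_curve()
        ic = to_force_indentation(curve, z0=250.0)
        assert np.allclose(ic.F, 0.0)
        assert np.allclose(ic.delta, curve.z - 250.0)

    def test_roundtrip_against_generator(self, noiseless_curve):
        curve, spec = noiseless_curve
        ic = to_force_indentation(curve, spec.contact_point)
        sel = ic.delta > 1.0
        F_model = sneddon_force(
            ic.delta[sel], spec.youngs_modulus, spec.poisson_ratio, spec.bead_radius
        )
        assert np.allclose(F_model, ic.F[sel], rtol=1e-6)

    def test_baseline_underdetermined(self):
        curve = self._flat_curve()
        with pytest.raises(BaselineError):
            to_force_indentation(curve, z0=2.0, min_pre_contact=5)

    def test_z0_outside_range(self):
        with pytest.raises(ValueError):
            to_force_indentation(self._flat_curve(), z0=1e5)


class TestFitHertz:
    def test_noiseless_recovery(self, noiseless_curve):
        curve, spec = noiseless_curve
        r = fit_hertz(curve, 400.0)
        assert r.E == pytest.approx(spec.youngs_modulus, rel=1e-3)
        assert r.z0 == pytest.approx(spec.contact_point, abs=1.0)
        assert r.n_points >= 10

    def test_modulus_scales_with_force(self, noiseless_curve):
        # scaling every force by c (here: stiffer spring, same deflections)
        curve, spec = noiseless_curve
        scaled = ForceCurve(
            z=curve.z, d=curve.d, k=2 * curve.k, Rs=curve.Rs, nu=curve.nu
        )
        r1 = fit_hertz(curve, 400.0)
        r2 = fit_hertz(scaled, 400.0)
        assert r2.E == pytest.approx(2 * r1.E, rel=1e-3)

    def test_fixed_z0_mode(self, noiseless_curve):
        curve, spec = noiseless_curve
        r = fit_hertz(curve, 400.0, FitConfig(z0_init=spec.contact_point, fit_z0=False))
        assert r.z0 == spec.contact_point
        assert r.E == pytest.approx(spec.youngs_modulus, rel=1e-3)

    def test_too_few_points(self):
        z = np.arange(0.0, 12.0, 2.0)
        curve = ForceCurve(z=z, d=np.zeros_like(z), k=0.08, Rs=2250.0)
        with pytest.raises(ValueError):
            fit_hertz(curve, 400.0)


class TestBatchFit:
    def test_identical_curves_identical_fits(self):
        spec = synth.CurveSpec(youngs_modulus=800.0, deflection_noise_sd=0.0, seed=0)
        curves = [synth.generate_force_curve(spec) for _ in range(3)]
        table = batch_fit(curves, depths=(200.0, 400.0))
        assert (table["status"] == "ok").all()
        for depth in (200.0, 400.0):
            vals = table.loc[table["depth_nm"] == depth, "E_Pa"].to_numpy()
            assert np.allclose(vals, vals[0])

    def test_depths_agree_on_model_data(self, noiseless_curve):
        curve, spec = noiseless_curve
        table = batch_fit([curve])
        vals = table["E_Pa"].to_numpy()
        assert np.all(np.abs(vals - vals.mean()) / vals.mean() < 0.01)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            batch_fit([])

    def test_failures_recorded_not_fatal(self, noiseless_curve):
        curve, _ = noiseless_curve
        z = np.arange(0.0, 12.0, 2.0)
        bad = ForceCurve(z=z, d=np.zeros_like(z), k=0.08, Rs=2250.0, identifier="bad")
        table = batch_fit([curve, bad], depths=(400.0,))
        assert (table.loc[table["curve_id"] != "bad", "status"] == "ok").all()
        assert table.loc[table["curve_id"] == "bad", "status"].str.startswith("error").all()

    def test_cell_summary_median(self, noiseless_curve):
        curve, spec = noiseless_curve
        table = batch_fit([curve], depths=(400.0,))
        agg = afm.summarize_cells(table)
        assert agg["E_Pa_median"].iloc[0] == pytest.approx(spec.youngs_modulus, rel=1e-3)


class TestCompareGroups:
    @staticmethod
    def _exact_p_enumeration(a, b):
        """Oracle: exact two-sided p by enumerating all rank splits."""
        pooled = np.concatenate([a, b])
        n1 = len(a)
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        obs = ranks[:n1].sum()
        mean = n1 * (len(pooled) + 1) / 2.0
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean) >= abs(obs - mean) - 1e-12:
                count += 1
        return count / total

    def test_exact_small_sample(self):
        u, p = compare_groups([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert p == pytest.approx(self._exact_p_enumeration([1, 2], [3, 4]), abs=1e-12)

    def test_enumeration_oracle_random(self, rng):
        a = rng.normal(0, 1, size=5)
        b = rng.normal(1, 1, size=6)
        _, p = compare_groups(a, b)
        assert p == pytest.approx(self._exact_p_enumeration(a, b), abs=1e-9)

    def test_identical_groups(self):
        _, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_all_values_identical(self):
        u, p = compare_groups([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0
        assert u == 3.0  # null mean n1*n2/2

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, size=8)
        b = rng.normal(0.5, 1, size=7)
        _, p1 = compare_groups(a, b)
        _, p2 = compare_groups(b, a)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestForceCurveValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"z": [0, 1, 1], "d": [0, 0, 0]},  # not strictly increasing
            {"z": [0, 1], "d": [0, 0, 0]},  # length mismatch
            {"z": [0, 1], "d": [0, 0], "k": 0.0},
            {"z": [0, 1], "d": [0, 0], "nu": 0.7},
        ],
    )
    def test_invalid(self, kwargs):
        defaults = dict(k=0.08, Rs=2250.0)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            ForceCurve(
                z=np.asarray(defaults.pop("z"), float),
                d=np.asarray(defaults.pop("d"), float),
                **defaults,
            )
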