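import numpy as np
import pytest

import clusterpdf as cp
from clusterpdf.exceptions import ValidationError
from clusterpdf.refinement import RefinementOptions, SolvationWave


@pytest.fixture(scope="module")
def fitted_grid():
    return cp.default_rgrid(16.0, 0.01)


class TestSolvationWave:
    def test_zero_amplitude_zero_curve(self, fitted_grid):
        wave = SolvationWave(0.0, 5.0)
        assert np.allclose(cp.wave_curve(wave, fitted_grid).g, 0.0)

    def test_sine_maximum(self):
        # phase 0, nearly undamped: g(lambda/4) -> A
        wave = SolvationWave(2.0, 8.0, phase=0.0, decay=1e6)
        assert wave.evaluate(np.array([2.0]))[0] == pytest.approx(2.0, rel=1e-5)

    def test_envelope_decay(self):
        # at r equal to the decay length the envelope has fallen to A/e
        wave = SolvationWave(1.0, 8.0, phase=np.pi / 2, decay=2.0)
        value = wave.evaluate(np.array([2.0]))[0]
        expected = np.sin(2 * np.pi * 2.0 / 8.0 + np.pi / 2) * np.exp(-1.0)
        assert value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [dict(wavelength=0.0), dict(decay=-1.0)])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValidationError):
            SolvationWave(1.0, bad.get("wavelength", 5.0), decay=bad.get("decay", 5.0))

    def test_normalized_form(self):
        wave = SolvationWave(-2.0, 5.0, phase=0.3)
        norm = wave.normalized()
        assert norm.amplitude == 2.0
        r = np.linspace(0.5, 10, 50)
        assert np.allclose(norm.evaluate(r), wave.evaluate(r), atol=1e-12)


class TestRefinePositions:
    def test_fixed_point(self, toy, fitted_grid):
        model, _ = toy
        data = cp.calc_pdf(model, fitted_grid)
        res = cp.refine_positions(model, data, RefinementOptions(max_iter=60))
        assert res.rw_value < 1e-6
        assert np.max(np.abs(res.model.positions - model.positions)) < 1e-3
        assert res.scale == pytest.approx(1.0, abs=1e-4)

    def test_scale_only_with_zero_bound(self, toy, fitted_grid):
        model, _ = toy
        data = cp.PDFCurve(fitted_grid, 2.0 * cp.calc_pdf(model, fitted_grid).g)
        res = cp.refine_positions(model, data, RefinementOptions(max_shift=0.0))
        assert np.array_equal(res.model.positions, model.positions)
        assert res.scale == pytest.approx(2.0, rel=1e-9)
        assert res.rw_value < 1e-12

    def test_small_displacement_recovery(self, toy, fitted_grid):
        # noiseless data from a slightly displaced thermally broadened copy
        # is recovered essentially exactly; the comparison removes the rigid
        # (rotation + translation) motion, which the PDF cannot constrain
        model, _ = toy
        model = model.with_biso(0.5)
        rng = np.random.default_rng(5)
        truth = model.with_positions(
            model.positions + rng.uniform(-0.05, 0.05, (len(model), 3))
        )
        data = cp.calc_pdf(truth, fitted_grid)
        res = cp.refine_positions(model, data, RefinementOptions(max_iter=300))
        A = res.model.positions - res.model.positions.mean(0)
        B = truth.positions - truth.positions.mean(0)
        U, _, Vt = np.linalg.svd(A.T @ B)
        R = Vt.T @ np.diag([1, 1, np.sign(np.linalg.det(Vt.T @ U.T))]) @ U.T
        rms = np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1)))
        assert rms < 0.02
        assert res.rw_value < 1e-6

    def test_determinism(self, toy, fitted_grid):
        model, _ = toy
        truth = model.with_positions(model.positions + 0.03)
        data = cp.calc_pdf(truth, fitted_grid)
        opts = RefinementOptions(max_iter=40)
        a = cp.refine_positions(model, data, opts)
        b = cp.refine_positions(model, data, opts)
        assert np.array_equal(a.model.positions, b.model.positions)
        assert a.rw_value == b.rw_value

    def test_translation_gauge_invariance(self, toy, fitted_grid):
        # PDF depends only on internal distances: translating start and
        # truth together leaves the misfit trajectory unchanged
        model, _ = toy
        rng = np.random.default_rng(2)
        shift = rng.uniform(-0.04, 0.04, (len(model), 3))
        data = cp.calc_pdf(model.with_positions(model.positions + shift), fitted_grid)
        res_a = cp.refine_positions(model, data, RefinementOptions(max_iter=60))
        translated = model.with_positions(model.positions + np.array([5.0, -3.0, 2.0]))
        res_b = cp.refine_positions(translated, data, RefinementOptions(max_iter=60))
        assert res_a.rw_value == pytest.approx(res_b.rw_value, abs=1e-9)

    def test_initial_outside_bounds_raises(self, toy, fitted_grid):
        model, _ = toy
        data = cp.calc_pdf(model, fitted_grid)
        far = model.with_positions(model.positions + 2.0)
        with pytest.raises(ValidationError):
            cp.refine_positions(model, data, RefinementOptions(), initial=far)


class TestRefineWave:
    def make_wave_data(self, model, rgrid, amplitude_frac=0.08,
                       wavelength=7.0, phase=0.9, decay=6.0):
        clean = cp.calc_pdf(model, rgrid)
        wave = SolvationWave(
            amplitude_frac * float(np.max(np.abs(clean.g))), wavelength, phase, decay
        )
        return cp.PDFCurve(rgrid, clean.g + wave.evaluate(rgrid)), wave

    def test_pure_model_data_gives_null_wave(self, toy, fitted_grid):
        model, _ = toy
        data = cp.calc_pdf(model, fitted_grid)
        res1 = cp.refine_positions(model, data, RefinementOptions(max_shift=0.0))
        res2 = cp.refine_wave(res1, data, RefinementOptions(max_shift=0.0))
        assert abs(res2.wave.amplitude) < 1e-3 * np.max(np.abs(data.g))

    def test_known_wave_recovered(self, toy, fitted_grid):
        model, _ = toy
        data, wave = self.make_wave_data(model, fitted_grid)
        opts = RefinementOptions(max_shift=0.0)
        res = cp.refine_wave(cp.refine_positions(model, data, opts), data, opts)
        fitted = res.wave.normalized()
        assert fitted.amplitude == pytest.approx(wave.amplitude, rel=0.05)
        assert fitted.wavelength == pytest.approx(wave.wavelength, rel=0.05)
        assert fitted.decay == pytest.approx(wave.decay, rel=0.05)

    def test_rw_non_increasing_across_stages(self, toy, fitted_grid):
        model, _ = toy
        data, _ = self.make_wave_data(model, fitted_grid, amplitude_frac=0.15)
        scale_only = cp.refine_positions(model, data, RefinementOptions(max_shift=0.0))
        stage1 = cp.refine_positions(model, data, RefinementOptions(max_iter=80))
        stage2 = cp.refine_wave(stage1, data, RefinementOptions(max_iter=80))
        assert stage2.rw_value <= stage1.rw_value <= scale_only.rw_value

    def test_stage1_residual_stored(self, toy, fitted_grid):
        model, _ = toy
        data, _ = self.make_wave_data(model, fitted_grid)
        opts = RefinementOptions(max_shift=0.0)
        res = cp.refine_wave(cp.refine_positions(model, data, opts), data, opts)
        assert res.stage1_residual is not None
        # residual carries the injected wave: it should correlate strongly
        fit = res.stage1_residual.restricted(1.7, 15.0)
        assert np.max(np.abs(fit.g)) > 0


class TestCollisionGuard:
    def test_penalty_active_below_cutoff(self):
        from clusterpdf.refinement import _Profile

        sites = [
            cp.AtomSite("Ag", np.array([0.0, 0.0, 0.0]), label="Ag1"),
            cp.AtomSite("Ag", np.array([0.3, 0.0, 0.0]), label="Ag2"),
        ]
        model = cp.ClusterModel(sites)
        r = np.linspace(1.0, 5.0, 100)
        profile = _Profile(model, r, RefinementOptions())
        pen, grad = profile.collision_penalty(model.positions, kappa=10.0)
        assert pen[0] == pytest.approx(10.0 * (0.5 - 0.3))
        # gradient pushes the two atoms apart along x
        assert grad[0, 0] > 0 or grad[0, 3] > 0
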