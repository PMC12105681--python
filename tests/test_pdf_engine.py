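import numpy as np
import pytest

import clusterpdf as cp
from clusterpdf.exceptions import (
    DegenerateGeometryError,
    UndefinedCoherenceError,
    ValidationError,
)
from clusterpdf.pdf_engine import RESOLUTION_FLOOR
from conftest import brute_force_pdf



class TestPairTable:
    def test_single_element_weight_is_one(self, two_atom_model):
        pt = cp.pair_table(two_atom_model)
        assert len(pt) == 1
        assert pt.r[0] == pytest.approx(2.8)
        assert pt.w[0] == pytest.approx(1.0)

    def test_pair_count(self, toy):
        model, _ = toy
        assert len(cp.pair_table(model)) == 18 * 17 // 2

    def test_mixed_weights_ordering(self, toy):
        model, _ = toy
        pt = cp.pair_table(model)
        els = model.elements
        w_agag = [w for i, j, w in zip(pt.i, pt.j, pt.w) if els[i] == els[j] == "Ag"]
        w_agcl = [w for i, j, w in zip(pt.i, pt.j, pt.w) if {els[i], els[j]} == {"Ag", "Cl"}]
        assert min(w_agag) > max(w_agcl)

    def test_coincident_atoms_raise(self):
        sites = [
            cp.AtomSite("Ag", np.zeros(3), label="Ag1"),
            cp.AtomSite("Ag", np.zeros(3) + 1e-9, label="Ag2"),
        ]
        with pytest.raises(DegenerateGeometryError):
            cp.pair_table(cp.ClusterModel(sites))


class TestCalcPDF:
    def test_single_pair_peak_position(self, two_atom_model, rgrid):
        curve = cp.calc_pdf(two_atom_model, rgrid)
        peaks = cp.find_peaks(curve, 0.1)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(2.80, abs=1e-3)

    def test_biso_widens_peak(self, two_atom_model, rgrid):
        sharp = cp.calc_pdf(two_atom_model, rgrid)
        broad = cp.calc_pdf(two_atom_model.with_biso(0.5), rgrid)
        # unit-area peaks: width and height trade off
        sigma_expected = np.sqrt(1.0 / (8 * np.pi**2) + RESOLUTION_FLOOR**2)
        ratio = np.max(sharp.g) / np.max(broad.g)
        assert ratio == pytest.approx(sigma_expected / RESOLUTION_FLOOR, rel=0.02)

    def test_similarity_transform_doubles_peaks(self, toy, rgrid):
        model, _ = toy
        doubled = model.with_positions(model.positions * 2.0)
        wide = cp.default_rgrid(30.0, 0.01)
        p1 = cp.find_peaks(cp.calc_pdf(model, wide), 0.2)
        p2 = cp.find_peaks(cp.calc_pdf(doubled, wide), 0.2)
        assert p2[0] == pytest.approx(2 * p1[0], abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence(self, seed, rgrid):
        model = cp.make_random_model(12 + 5 * seed, seed=seed)
        calc = cp.calc_pdf(model, rgrid)
        oracle = brute_force_pdf(model, rgrid)
        assert np.max(np.abs(calc.g - oracle)) < 1e-8

    def test_permutation_invariance(self, toy, rgrid):
        model, _ = toy
        rng = np.random.default_rng(3)
        order = rng.permutation(len(model))
        permuted = cp.ClusterModel([model.sites[int(k)] for k in order], "perm")
        assert np.allclose(
            cp.calc_pdf(model, rgrid).g, cp.calc_pdf(permuted, rgrid).g, atol=1e-10
        )

    def test_area_conservation_single_pair(self, two_atom_model):
        # integral of r*G(r) over an isolated peak equals 2*s*w, independent of sigma
        rgrid = cp.default_rgrid(10.0, 0.002)
        for biso in (0.0, 1.0):
            curve = cp.calc_pdf(two_atom_model.with_biso(biso), rgrid, scale=1.5)
            area = np.trapezoid(curve.r * curve.g, curve.r)
            assert area == pytest.approx(2 * 1.5 * 1.0, rel=1e-3)


class TestRw:
    def test_identity_is_zero(self, two_atom_model, rgrid):
        curve = cp.calc_pdf(two_atom_model, rgrid)
        assert cp.rw(curve, curve) == 0.0

    def test_null_model_is_one(self, two_atom_model, rgrid):
        obs = cp.calc_pdf(two_atom_model, rgrid)
        zero = cp.PDFCurve(rgrid, np.zeros_like(rgrid))
        assert cp.rw(obs, zero) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "obs,calc,expected",
        [([1.0, 0.0], [0.0, 0.0], 1.0), ([1.0, 0.0], [1.0, 1.0], 1.0)],
    )
    def test_hand_computed_values(self, obs, calc, expected):
        r = np.array([1.0, 2.0])
        value = cp.rw(cp.PDFCurve(r, np.array(obs)), cp.PDFCurve(r, np.array(calc)))
        assert value == pytest.approx(expected)

    def test_joint_rescaling_invariance(self, toy, rgrid):
        model, _ = toy
        obs = cp.calc_pdf(model, rgrid)
        calc = cp.PDFCurve(rgrid, obs.g * 0.7 + 0.01)
        a = cp.rw(obs, calc)
        scaled = cp.rw(
            cp.PDFCurve(rgrid, obs.g * 3.0), cp.PDFCurve(rgrid, calc.g * 3.0)
        )
        assert scaled == pytest.approx(a, rel=1e-12)

    def test_zero_observation_raises(self, rgrid):
        zero = cp.PDFCurve(rgrid, np.zeros_like(rgrid))
        with pytest.raises(ValidationError):
            cp.rw(zero, zero)


class TestLinearCombination:
    def test_single_curve_identity(self, rgrid):
        curve = cp.PDFCurve(rgrid, np.sin(rgrid))
        out = cp.linear_combination([curve], [1.0])
        assert np.allclose(out.g, curve.g)

    def test_equal_halves_identity(self, rgrid):
        curve = cp.PDFCurve(rgrid, np.sin(rgrid))
        out = cp.linear_combination([curve, curve.copy()], [0.5, 0.5])
        assert np.allclose(out.g, curve.g)

    def test_grid_mismatch_raises(self, rgrid):
        a = cp.PDFCurve(rgrid, np.zeros_like(rgrid))
        b = cp.PDFCurve(rgrid[:-1], np.zeros(len(rgrid) - 1))
        with pytest.raises(ValidationError):
            cp.linear_combination([a, b], [1, 1])


class TestFeatureExtraction:
    def test_two_gaussians_found(self, rgrid):
        g = np.exp(-0.5 * ((rgrid - 2.8) / 0.1) ** 2) + 0.8 * np.exp(
            -0.5 * ((rgrid - 5.0) / 0.15) ** 2
        )
        peaks = cp.find_peaks(cp.PDFCurve(rgrid, g), 0.1)
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(2.8, abs=0.01)
        assert peaks[1] == pytest.approx(5.0, abs=0.01)

    def test_flat_curve_has_no_peaks(self, rgrid):
        assert cp.find_peaks(cp.PDFCurve(rgrid, np.zeros_like(rgrid)), 0.1) == []

    def test_coherence_single_pair(self, two_atom_model, rgrid):
        curve = cp.calc_pdf(two_atom_model, rgrid)
        lo, hi = cp.coherence_length(curve, noise_floor=0.05 * np.max(curve.g))
        assert lo <= 2.8 <= hi + 0.5

    def test_coherence_bounded_by_max_distance(self):
        spec = cp.ToyClusterSpec(atoms_per_channel=3, channel_z_stagger=0.5,
                                 cap_distance=2.0)
        model, _ = cp.make_toy_cluster(spec)
        pos = model.positions
        iu, ju = np.triu_indices(len(pos), 1)
        dmax = np.linalg.norm(pos[iu] - pos[ju], axis=1).max()
        grid = cp.default_rgrid(dmax + 6.0, 0.01)
        curve = cp.calc_pdf(model, grid)
        # floor low enough that the weak halide cap-cap pair at dmax counts
        _, hi = cp.coherence_length(curve, noise_floor=0.002 * np.max(np.abs(curve.g)))
        assert dmax - 1.5 <= hi <= dmax + 1.0

    def test_pure_noise_raises(self, rgrid):
        rng = np.random.default_rng(0)
        curve = cp.PDFCurve(rgrid, rng.normal(0, 0.01, rgrid.size))
        with pytest.raises(UndefinedCoherenceError):
            cp.coherence_length(curve, noise_floor=1.0)
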