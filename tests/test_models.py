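"""Reference intensities, LLM/RBT models, fitting, ADP utilities."""

import gemmi
import numpy as np
import pytest

import diffusekit as dk
from diffusekit.metrics import pearson_cc
from diffusekit.models import (
    AtomicModel,
    BoxAveragedKernel,
    U_TO_B,
    anisotropy_ratio,
    beq_from_u,
    convolve_periodic,
    fit_model,
    grid_qvectors,
    llm_intensity,
    llm_kernel,
    process_model_map,
    rbt_intensity,
    reference_intensity,
    rescale_adps,
    traceless,
)
from diffusekit.volume import DiffuseVolume

CELL = gemmi.UnitCell(20.0, 24.0, 26.0, 90.0, 95.0, 90.0)


def one_atom_model(element="C", frac=(0.0, 0.0, 0.0), b=0.0, u=None,
                   spacegroup="P 1"):
    u_arr = np.full((1, 3, 3), np.nan) if u is None else np.array([u])
    return AtomicModel([element], np.array([frac]), [1.0], [""], [b], u_arr,
                       CELL, spacegroup)


def it92_f(element, qmag):
    it = gemmi.Element(element).it92
    s2 = np.asarray(qmag) ** 2
    return sum(a * np.exp(-b * s2 / 4) for a, b in zip(it.a, it.b)) + it.c


class TestReferenceIntensity:
    def test_single_atom_at_origin_phase_free(self):
        m = one_atom_model()
        I = reference_intensity(m, 4, "zero")
        _, qmag = grid_qvectors(CELL, 4)
        assert np.allclose(I, it92_f("C", qmag) ** 2, rtol=1e-10)

    def test_centrosymmetric_pair_cosine_squared(self):
        x = np.array([0.13, 0.21, 0.07])
        m = AtomicModel(["O", "O"], np.array([x, -x]), [1.0, 1.0], ["", ""],
                        [0.0, 0.0], np.full((2, 3, 3), np.nan), CELL, "P 1")
        I = reference_intensity(m, 3, "zero")
        _, qmag = grid_qvectors(CELL, 3)
        ax = np.arange(-3, 4)
        h, k, l = np.meshgrid(ax, ax, ax, indexing="ij")
        phase = 2 * np.pi * (h * x[0] + k * x[1] + l * x[2])
        expected = 4 * it92_f("O", qmag) ** 2 * np.cos(phase) ** 2
        assert np.allclose(I, expected, rtol=1e-9, atol=1e-9)

    def test_isotropic_equals_spherical_anisotropic(self):
        b = 12.0
        u_iso = np.eye(3) * b / U_TO_B
        m_iso = one_atom_model(frac=(0.1, 0.2, 0.3), b=b, u=u_iso)
        I_iso = reference_intensity(m_iso, 4, "isotropic")
        I_ani = reference_intensity(m_iso, 4, "anisotropic")
        assert np.allclose(I_iso, I_ani, rtol=1e-10)

    def test_matches_gemmi_structure_factors(self, tiny_model):
        """Cross-check against gemmi's calculator on the symmetry-expanded
        P1 atom list (zero ADPs)."""
        from diffusekit.models import _symmetry_expand

        frac, _, src = _symmetry_expand(tiny_model)
        st = gemmi.Structure()
        st.cell = tiny_model.cell
        st.spacegroup_hm = "P 1"
        mdl = gemmi.Model("1")
        ch = gemmi.Chain("A")
        for i in range(len(frac)):
            r = gemmi.Residue()
            r.name = "DUM"
            r.seqid = gemmi.SeqId(i + 1, " ")
            a = gemmi.Atom()
            a.name = "X"
            a.element = gemmi.Element(tiny_model.elements[src[i]])
            a.pos = gemmi.Position(
                *tiny_model.cell.orthogonalize(gemmi.Fractional(*frac[i])).tolist())
            a.occ = 1.0
            a.b_iso = 0.0
            r.add_atom(a)
            ch.add_residue(r)
        mdl.add_chain(ch)
        st.add_model(mdl)
        calc = gemmi.StructureFactorCalculatorX(st.cell)
        I = reference_intensity(tiny_model.select_conformer("A"), 8, "zero")
        for hkl in [(1, 2, 3), (0, 0, 4), (-3, 1, 2), (5, -2, -1)]:
            F = calc.calculate_sf_from_model(st[0], hkl)
            mine = I[hkl[0] + 8, hkl[1] + 8, hkl[2] + 8]
            assert mine == pytest.approx(abs(F) ** 2, rel=1e-4)

    def test_model_map_has_laue_symmetry(self, tiny_model):
        I = reference_intensity(tiny_model.select_conformer("A"), 6, "anisotropic")
        assert np.allclose(I, np.flip(I, (0, 2)), rtol=1e-8)
        assert np.allclose(I, np.flip(I, (0, 1, 2)), rtol=1e-8)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            reference_intensity(one_atom_model(element="Xx"), 2, "zero")


class TestKernel:
    def test_origin_value_is_volume_integral(self):
        ker = llm_kernel(7.0, CELL, 6, normalize=False)
        assert ker[6, 6, 6] == pytest.approx(8 * np.pi * 343.0, rel=1e-12)

    def test_quarter_value_at_inverse_gamma(self):
        # gamma^2 q_rad^2 = 1 -> denominator (1+1)^2 = 4
        gamma = 7.0
        q_rad = 1.0 / gamma
        val = 8 * np.pi * gamma ** 3 / (1 + gamma ** 2 * q_rad ** 2) ** 2
        assert val == pytest.approx(8 * np.pi * gamma ** 3 / 4)

    def test_matches_numeric_fourier_transform_of_exponential(self):
        """3D FFT of sampled exp(-r/gamma) reproduces the closed form."""
        gamma = 7.0
        N, L = 96, 42 * gamma
        d = L / N
        ax = (np.arange(N) - N // 2) * d
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(np.exp(-r / gamma)))).real * d ** 3
        k = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(N, d))
        KX, KY, KZ = np.meshgrid(k, k, k, indexing="ij")
        kr2 = KX ** 2 + KY ** 2 + KZ ** 2
        closed = 8 * np.pi * gamma ** 3 / (1 + gamma ** 2 * kr2) ** 2
        sel = np.sqrt(kr2) < 1.0
        assert np.abs(F[sel] - closed[sel]).max() < 0.01 * closed.max()

    def test_grid_integral_close_to_analytic(self):
        """Kernel integrates (grid sum x voxel volume) to the analytic 3D
        integral of exp(-r/gamma) within 1% on a grid whose spacing
        resolves the peak and whose extent covers the q^-4 tail."""
        gamma = 4.0
        cell = gemmi.UnitCell(30, 30, 30, 90, 90, 90)
        ker = llm_kernel(gamma, cell, 150, normalize=False)
        # inverse FT at r=0: integral over q_rad / (2 pi)^3 = exp(0) = 1,
        # i.e. grid sum / cell volume -> 1
        assert ker.sum() / 30.0 ** 3 == pytest.approx(1.0, rel=0.01)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            llm_kernel(-1.0, CELL, 4)


class TestConvolution:
    def test_fft_matches_direct_double_sum(self):
        """Periodic FFT convolution equals the brute-force double sum."""
        rng = np.random.default_rng(0)
        a = rng.random((5, 5, 5))
        k = rng.random((5, 5, 5))
        k /= k.sum()
        got = convolve_periodic(a, k)
        n = 5
        direct = np.zeros_like(a)
        for i in range(n):
            for j in range(n):
                for l in range(n):
                    s = 0.0
                    for di in range(-2, 3):
                        for dj in range(-2, 3):
                            for dl in range(-2, 3):
                                s += (a[(i - di) % n, (j - dj) % n, (l - dl) % n]
                                      * k[di + 2, dj + 2, dl + 2])
                    direct[i, j, l] = s
        assert np.abs(got - direct).max() < 1e-10 * np.abs(direct).max()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convolve_periodic(np.ones((3, 3, 3)), np.ones((5, 5, 5)))


class TestLLMIntensity:
    def test_zero_sigma_gives_zero(self, tiny_ref_zero, tiny_model):
        I = llm_intensity(tiny_ref_zero, 0.0, 7.0, tiny_model.cell)
        assert np.allclose(I, 0.0)

    def test_delta_kernel_limit(self, tiny_ref_zero, tiny_model):
        """gamma huge vs grid: kernel concentrates at q=0 and the result
        is pointwise sigma^2 q_rad^2 exp(-sigma^2 q_rad^2) I0."""
        sigma = 0.4
        I = llm_intensity(tiny_ref_zero, sigma, 1e5, tiny_model.cell)
        _, qmag = grid_qvectors(tiny_model.cell, 12)
        qr2 = (2 * np.pi * qmag) ** 2
        expected = sigma ** 2 * qr2 * np.exp(-sigma ** 2 * qr2) * tiny_ref_zero
        sel = expected > 1e-6 * expected.max()
        assert np.abs(I[sel] - expected[sel]).max() < 0.02 * expected.max()

    def test_scale_free_variant_matches_up_to_constant(self, tiny_ref_zero, tiny_model):
        a = llm_intensity(tiny_ref_zero, 0.5, 6.0, tiny_model.cell,
                          include_scale=True)
        b = llm_intensity(tiny_ref_zero, 0.5, 6.0, tiny_model.cell,
                          include_scale=False)
        assert np.allclose(a, 0.25 * b)


class TestRBT:
    def test_zero_sigma(self, tiny_ref_zero, tiny_model):
        assert np.allclose(rbt_intensity(tiny_ref_zero, 0.0, tiny_model.cell), 0.0)

    def test_small_sigma_linear_regime(self, tiny_ref_zero, tiny_model):
        sigma = 1e-3
        I = rbt_intensity(tiny_ref_zero, sigma, tiny_model.cell)
        _, qmag = grid_qvectors(tiny_model.cell, 12)
        qr2 = (2 * np.pi * qmag) ** 2
        expected = sigma ** 2 * qr2 * tiny_ref_zero
        assert np.allclose(I, expected, rtol=1e-3)

    def test_large_sigma_saturates_to_reference(self, tiny_ref_zero, tiny_model):
        I = rbt_intensity(tiny_ref_zero, 50.0, tiny_model.cell)
        _, qmag = grid_qvectors(tiny_model.cell, 12)
        sel = qmag > 0.05
        assert np.allclose(I[sel], tiny_ref_zero[sel], rtol=1e-6)

    def test_negative_sigma_rejected(self, tiny_ref_zero, tiny_model):
        with pytest.raises(ValueError):
            rbt_intensity(tiny_ref_zero, -0.1, tiny_model.cell)


class TestFitting:
    def test_self_fit_recovers_generating_parameters(self, tiny_ref_zero, tiny_model):
        truth = llm_intensity(tiny_ref_zero, 0.4, 7.0, tiny_model.cell)
        data = process_model_map(truth, tiny_model.cell, "2/m")
        fit = fit_model(data, tiny_ref_zero, "llm", "zero", d_min=3.4,
                        sigma_starts=(0.4,), gamma_starts=(7.0,))
        assert fit.cc == pytest.approx(1.0, abs=1e-6)
        assert fit.sigma == pytest.approx(0.4, abs=0.01)
        assert fit.gamma == pytest.approx(7.0, abs=0.1)

    def test_fit_invariant_to_data_scale(self, tiny_ref_zero, tiny_model):
        truth = llm_intensity(tiny_ref_zero, 0.4, 7.0, tiny_model.cell)
        data = process_model_map(truth, tiny_model.cell, "2/m")
        scaled = data.copy()
        scaled.sum *= 137.0
        f1 = fit_model(data, tiny_ref_zero, "llm", "zero", d_min=3.4,
                       sigma_starts=(0.3,), gamma_starts=(5.0,))
        f2 = fit_model(scaled, tiny_ref_zero, "llm", "zero", d_min=3.4,
                       sigma_starts=(0.3,), gamma_starts=(5.0,))
        assert f1.sigma == pytest.approx(f2.sigma, abs=1e-6)
        assert f1.gamma == pytest.approx(f2.gamma, abs=1e-4)
        assert f1.cc == pytest.approx(f2.cc, abs=1e-10)

    def test_model_selection_llm_vs_rbt(self, tiny_ref_zero, tiny_model):
        """CC_LLM > CC_RBT on LLM-generated data and vice versa."""
        cell = tiny_model.cell
        llm_data = process_model_map(
            llm_intensity(tiny_ref_zero, 0.4, 7.0, cell), cell, "2/m")
        rbt_data = process_model_map(
            rbt_intensity(tiny_ref_zero, 0.4, cell), cell, "2/m")
        kw = dict(d_min=3.4, sigma_starts=(0.2, 0.4), gamma_starts=(4.0, 8.0))
        cc = {
            (d, k): fit_model(vol, tiny_ref_zero, k, "zero", **kw).cc
            for d, vol in (("llm", llm_data), ("rbt", rbt_data))
            for k in ("llm", "rbt")
        }
        assert cc[("llm", "llm")] > cc[("llm", "rbt")]
        assert cc[("rbt", "rbt")] > cc[("rbt", "llm")]

    def test_processed_model_map_self_cc_is_one(self, tiny_ref_zero, tiny_model):
        proc = process_model_map(
            llm_intensity(tiny_ref_zero, 0.4, 7.0, tiny_model.cell),
            tiny_model.cell, "2/m")
        obs = proc.count > 0
        assert pearson_cc(proc.mean()[obs], proc.mean()[obs]) == pytest.approx(1.0)

    def test_box_averaged_kernel_normalized(self, tiny_model):
        k = BoxAveragedKernel(tiny_model.cell, 8)(6.0)
        assert k.sum() == pytest.approx(1.0)
        assert k.max() == k[8, 8, 8]

    def test_unknown_kind_rejected(self, tiny_ref_zero, tiny_model):
        data = process_model_map(tiny_ref_zero, tiny_model.cell, "2/m")
        with pytest.raises(ValueError):
            fit_model(data, tiny_ref_zero, "wiggle", "zero")


class TestADPUtilities:
    def test_isotropic_tensor(self):
        u = 0.02 * np.eye(3)
        assert anisotropy_ratio(u) == 1.0
        assert beq_from_u(u) == pytest.approx(8 * np.pi ** 2 * 0.02)

    def test_diagonal_ratio(self):
        assert anisotropy_ratio(np.diag([0.01, 0.02, 0.04])) == pytest.approx(0.25)

    def test_beq_rotation_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(3, 3))
            u = a @ a.T
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            assert beq_from_u(q @ u @ q.T) == pytest.approx(beq_from_u(u), rel=1e-10)

    def test_traceless_identity_vanishes(self):
        assert np.allclose(traceless(3.3 * np.eye(3)), 0.0)

    def test_rescale_preserves_beq_changes_anisotropy(self, tiny_model):
        delta = np.diag([2.0, -1.0, -1.0])
        out = rescale_adps(tiny_model, delta)
        for i in range(tiny_model.n_atoms):
            assert beq_from_u(out.u_cart[i]) == pytest.approx(
                beq_from_u(tiny_model.u_cart[i]), abs=1e-10)
        ratios_before = [anisotropy_ratio(u) for u in tiny_model.u_cart]
        ratios_after = [anisotropy_ratio(u) for u in out.u_cart]
        assert not np.allclose(ratios_before, ratios_after)

    def test_rescale_round_trip_exact(self, tiny_model):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(3, 3))
        d = d + d.T
        back = rescale_adps(rescale_adps(tiny_model, d), -d)
        assert np.allclose(back.u_cart, tiny_model.u_cart, atol=1e-15)

    def test_identity_delta_is_noop(self, tiny_model):
        out = rescale_adps(tiny_model, 5.0 * np.eye(3))
        assert np.allclose(out.u_cart[tiny_model.has_u],
                           tiny_model.u_cart[tiny_model.has_u], atol=1e-14)

    def test_asymmetric_delta_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            rescale_adps(tiny_model, np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1]]))


class TestPdbIO:
    def test_round_trip_preserves_everything(self, tiny_model, tmp_path):
        path = tmp_path / "model.pdb"
        tiny_model.to_pdb(path)
        back = AtomicModel.from_pdb(path)
        assert back.n_atoms == tiny_model.n_atoms
        assert back.elements == tiny_model.elements
        assert np.abs(back.frac - tiny_model.frac).max() < 1e-3
        # ANISOU records quantized to 1e-4 A^2
        assert np.abs(back.u_cart - tiny_model.u_cart).max() < 1e-4

    def test_conformer_selection(self):
        m = AtomicModel(
            ["C", "C", "N"], np.array([[0.1] * 3, [0.11] * 3, [0.3] * 3]),
            [0.6, 0.4, 1.0], ["A", "B", ""], [10.0, 10.0, 12.0],
            np.full((3, 3, 3), np.nan), CELL, "P 1")
        sel = m.select_conformer("A")
        assert sel.n_atoms == 2
        assert np.allclose(sel.occ, 1.0)
        assert all(a == "" for a in sel.altloc)
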