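"""Merging, symmetrization, isotropic subtraction, completeness, I/O."""

import gemmi
import numpy as np
import pytest

from diffusekit.volume import (
    DiffuseVolume,
    ShellScheme,
    completeness,
    merge_frames_into,
    subtract_isotropic,
    symmetrize,
)

CELL = gemmi.UnitCell(40.0, 42.0, 44.0, 90.0, 95.0, 90.0)


def empty(hmax=6, laue="2/m"):
    return DiffuseVolume(hmax, CELL, laue)


class TestMerge:
    def test_single_pixel_outside_bragg_box(self):
        v = empty()
        merge_frames_into(v, np.array([[2.4, 0.0, 0.0]]), np.array([7.0]),
                          np.array([True]))
        assert v.mean()[2 + 6, 6, 6] == 7.0
        assert v.count[2 + 6, 6, 6] == 1

    def test_two_pixels_average(self):
        v = empty()
        hkl = np.array([[1.4, 0.0, 0.0], [1.45, 0.0, 0.0]])
        merge_frames_into(v, hkl, np.array([4.0, 6.0]), np.ones(2, bool))
        assert v.mean()[1 + 6, 6, 6] == 5.0

    def test_boundary_offset_rejected(self):
        v = empty()
        st = merge_frames_into(v, np.array([[2.25, 0.0, 0.0]]), np.array([1.0]),
                               np.array([True]))
        assert st["n_bragg_rejected"] == 1 and st["n_merged"] == 0

    def test_uniform_accept_fraction(self):
        """Fraction surviving the Bragg box is 1 - 0.5^3 = 0.875."""
        rng = np.random.default_rng(0)
        n = 100_000
        hkl = rng.uniform(-5, 5, size=(n, 3))
        v = empty()
        st = merge_frames_into(v, hkl, np.ones(n), np.ones(n, bool))
        frac = (st["n_merged"] + st["n_outside_grid"]) / n
        assert abs(frac - 0.875) < 3 * np.sqrt(0.875 * 0.125 / n)

    def test_out_of_grid_counted_not_fatal(self):
        v = empty(hmax=2)
        st = merge_frames_into(v, np.array([[8.4, 0.0, 0.0]]), np.array([1.0]),
                               np.array([True]))
        assert st["n_outside_grid"] == 1 and v.count.sum() == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        hkl = rng.uniform(-4, 4, size=(500, 3))
        vals = rng.normal(size=500)
        v1, v2 = empty(), empty()
        merge_frames_into(v1, hkl, vals, np.ones(500, bool))
        perm = rng.permutation(500)
        merge_frames_into(v2, hkl[perm], vals[perm], np.ones(500, bool))
        assert np.allclose(v1.sum, v2.sum) and np.array_equal(v1.count, v2.count)


class TestSymmetrize:
    def test_friedel_pair_average(self):
        v = empty(laue="-1")
        v.sum[1 + 6, 2 + 6, 3 + 6] = 10.0
        v.count[1 + 6, 2 + 6, 3 + 6] = 1.0
        v.sum[-1 + 6, -2 + 6, -3 + 6] = 20.0
        v.count[-1 + 6, -2 + 6, -3 + 6] = 1.0
        s = symmetrize(v, "friedel")
        assert s.mean()[1 + 6, 2 + 6, 3 + 6] == 15.0
        assert s.mean()[-1 + 6, -2 + 6, -3 + 6] == 15.0

    def test_single_member_propagates(self):
        v = empty()
        v.sum[1 + 6, 2 + 6, 3 + 6] = 8.0
        v.count[1 + 6, 2 + 6, 3 + 6] = 2.0
        s = symmetrize(v, "laue")
        orbit = [(1, 2, 3), (-1, 2, -3), (-1, -2, -3), (1, -2, 3)]
        for h, k, l in orbit:
            assert s.mean()[h + 6, k + 6, l + 6] == 4.0

    def test_count_weighted_pooling(self):
        v = empty(laue="-1")
        v.sum[1 + 6, 6, 6] = 30.0   # 3 obs of mean 10
        v.count[1 + 6, 6, 6] = 3.0
        v.sum[-1 + 6, 6, 6] = 20.0  # 1 obs of 20
        v.count[-1 + 6, 6, 6] = 1.0
        s = symmetrize(v, "friedel")
        assert s.mean()[1 + 6, 6, 6] == pytest.approx(12.5)  # (30+20)/4

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        v = empty()
        v.sum = rng.normal(size=v.sum.shape)
        v.count = rng.integers(0, 3, size=v.count.shape).astype(float)
        s1 = symmetrize(v, "laue")
        s2 = symmetrize(s1, "laue")
        obs = s1.count > 0
        assert np.allclose(s2.mean()[obs], s1.mean()[obs])

    def test_group_invariance_exact(self):
        rng = np.random.default_rng(3)
        v = empty()
        v.sum = rng.normal(size=v.sum.shape)
        v.count = np.ones_like(v.sum)
        s = symmetrize(v, "laue").mean()
        assert np.allclose(s, np.flip(s, (0, 2)))
        assert np.allclose(s, np.flip(s, (0, 1, 2)))
        assert np.allclose(s, np.flip(s, (1,)))

    def test_friedel_subgroup_of_laue(self):
        rng = np.random.default_rng(4)
        v = empty()
        v.sum = rng.normal(size=v.sum.shape)
        v.count = np.ones_like(v.sum)
        a = symmetrize(symmetrize(v, "friedel"), "laue")
        b = symmetrize(v, "laue")
        assert np.allclose(a.mean(), b.mean())

    def test_unsupported_group_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            DiffuseVolume(4, CELL, "4/mmm")


class TestIsotropicSubtraction:
    def test_purely_radial_volume_vanishes(self):
        v = empty(hmax=8)
        q = v.qmag()
        v.sum = 5.0 + 3.0 * q ** 2
        v.count = np.ones_like(v.sum)
        out = subtract_isotropic(v)
        assert np.abs(out.mean()).max() < 0.05 * np.abs(v.sum).max()

    def test_constant_volume_vanishes_exactly(self):
        v = empty()
        v.sum = np.full_like(v.sum, 4.0)
        v.count = np.ones_like(v.sum)
        out = subtract_isotropic(v)
        assert np.abs(out.mean()).max() < 1e-10

    def test_anisotropic_part_recovered(self):
        """radial + zero-shell-mean anisotropic decomposes cleanly."""
        v = empty(hmax=8)
        q = v.qmag()
        h, k, l = v.index_grids()
        aniso = np.sign(h + 0.1) * q ** 2  # odd in h: zero mean per shell
        v.sum = (10.0 + 4.0 * q) + aniso
        v.count = np.ones_like(v.sum)
        out = subtract_isotropic(v)
        resid = out.mean() - aniso
        assert np.abs(resid).max() < 0.05 * np.abs(aniso).max() + 1e-9

    def test_shell_weighted_means_vanish(self):
        rng = np.random.default_rng(5)
        v = empty(hmax=10)
        v.sum = rng.normal(5.0, 2.0, v.sum.shape)
        v.count = rng.integers(0, 4, v.count.shape).astype(float)
        v.sum *= v.count
        shells = ShellScheme.uniform_q(d_min=1.0 / float(v.qmag().max()),
                                       n_shells=40)
        out = subtract_isotropic(v, shells)
        q = v.qmag()
        idx = shells.assign(q)
        mean = out.mean()
        scale = np.nanmax(np.abs(v.mean()))
        for b in range(shells.n_shells):
            sel = (idx == b) & (out.count > 0)
            if sel.any():
                wmean = np.sum(mean[sel] * out.count[sel]) / out.count[sel].sum()
                assert abs(wmean) < 1e-8 * scale


class TestCompleteness:
    def test_fully_observed_grid(self):
        v = empty()
        v.count = np.ones_like(v.count)
        shells = ShellScheme.equal_volume(d_min=1.0 / float(v.qmag().max()), n_shells=4)
        per_shell, overall = completeness(v, shells)
        assert overall == 1.0 and np.allclose(per_shell[~np.isnan(per_shell)], 1.0)

    def test_empty_grid(self):
        v = empty()
        shells = ShellScheme.equal_volume(d_min=1.0 / float(v.qmag().max()), n_shells=4)
        _, overall = completeness(v, shells)
        assert overall == 0.0

    def test_half_observed_unique_voxels(self):
        v = empty(laue="-1")
        # observe exactly the +h half-space (h > 0): every unique orbit
        # with h != 0 is observed
        h, k, l = v.index_grids()
        v.count[h > 0] = 1.0
        shells = ShellScheme.equal_volume(d_min=1.0 / float(v.qmag().max()), n_shells=1)
        _, overall = completeness(v, shells)
        n = v.n
        frac_h0 = 1.0 / n  # the h = 0 plane orbits are unobserved
        assert overall == pytest.approx(1.0 - 0.97 * frac_h0, abs=0.05)


class TestShellScheme:
    def test_edges_decreasing_in_d(self):
        s = ShellScheme.equal_volume(1.4, 15)
        assert np.all(np.diff(s.d_edges) < 0)
        assert s.n_shells == 15

    def test_equal_volume_shells(self):
        s = ShellScheme.equal_volume(2.0, 10)
        vol = np.diff(s.q_edges ** 3)
        assert np.allclose(vol, vol[0])

    def test_assign_outside_range(self):
        s = ShellScheme.equal_volume(1.4, 5)
        idx = s.assign(np.array([0.01, 2.0]))
        assert idx[1] == -1

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            ShellScheme(np.array([1.0, 2.0]))


class TestQmag:
    def test_matches_gemmi_d_spacing(self):
        """|q| = 1/d from the reciprocal metric agrees with gemmi for a
        monoclinic cell."""
        v = empty(hmax=5)
        q = v.qmag()
        for hkl in [(1, 0, 0), (0, 2, 0), (0, 0, 3), (1, 2, 3), (-2, 1, -1)]:
            d = CELL.calculate_d(hkl)
            assert q[hkl[0] + 5, hkl[1] + 5, hkl[2] + 5] == pytest.approx(1.0 / d, rel=1e-12)


class TestIO:
    def test_hkl_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        v = empty(hmax=4)
        v.count = rng.integers(0, 3, v.count.shape).astype(float)
        v.sum = rng.normal(size=v.sum.shape) * v.count
        path = tmp_path / "map.hkl"
        v.write_hkl_table(path)
        back = DiffuseVolume.read_hkl_table(path)
        assert back.hmax == 4 and back.laue_group == "2/m"
        obs = v.count > 0
        assert np.allclose(back.count, v.count)
        assert np.allclose(back.mean()[obs], v.mean()[obs], atol=1e-6)

    def test_ccp4_write(self, tmp_path):
        v = empty(hmax=3)
        v.sum = np.ones_like(v.sum)
        v.count = np.ones_like(v.count)
        path = tmp_path / "map.ccp4"
        v.write_ccp4(path)
        m = gemmi.read_ccp4_map(str(path))
        assert m.grid.shape == (7, 7, 7)
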