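import numpy as np
import pytest

import rhizopore as rp
from rhizopore.transport import ladder, fit_convergence

from conftest import make_tube


class TestSampleSubvolumes:
    def test_tiny_roi_fails(self, dexter_volume):
        volume, _ = dexter_volume
        with pytest.raises((RuntimeError, ValueError)):
            rp.sample_subvolumes(volume, n=20, side_um=480.0, seed=0,
                                 max_attempts=2000)

    def test_overlap_constraint_holds_pairwise(self, dexter_volume):
        volume, _ = dexter_volume
        subs = rp.sample_subvolumes(volume, n=8, side_um=400.0, seed=3)
        side = subs.side_vox
        cap = 250.0 / volume.voxel_size
        for i in range(subs.n):
            for j in range(i + 1, subs.n):
                overlap = side - np.abs(subs.origins[i] - subs.origins[j])
                if np.all(overlap > 0):
                    assert np.all(overlap <= cap + 1e-9)

    def test_cubes_avoid_root(self, dexter_volume):
        volume, _ = dexter_volume
        subs = rp.sample_subvolumes(volume, n=6, side_um=400.0, seed=1)
        for i in range(subs.n):
            assert not np.any(subs.cube(volume, i) == rp.ROOT)

    def test_deterministic_per_seed(self, dexter_volume):
        volume, _ = dexter_volume
        a = rp.sample_subvolumes(volume, n=4, side_um=400.0, seed=7)
        b = rp.sample_subvolumes(volume, n=4, side_um=400.0, seed=7)
        assert np.array_equal(a.origins, b.origins)


class TestLadder:
    def test_first_step_is_parent_side(self):
        lad = ladder((0, 0, 0), 100, 5.0)
        assert lad.sides_vox[0] == 100
        assert lad.sides_um[0] == 500.0

    def test_step_three_from_500um_is_quarter_mm(self):
        lad = ladder((0, 0, 0), 100, 5.0)
        assert lad.sides_um[3] == pytest.approx(250.0)

    def test_volumes_halve_each_step(self):
        lad = ladder((0, 0, 0), 100, 5.0)
        v = lad.sides_vox.astype(float) ** 3
        ratio = v[1:] / v[:-1]
        # voxel rounding to even sides perturbs the exact halving
        assert np.all(np.abs(ratio - 0.5) < 0.12)

    def test_nested_with_common_centre(self):
        lad = ladder((10, 10, 10), 40, 5.0)
        centres = lad.origins + lad.sides_vox[:, None] / 2.0
        assert np.all(np.abs(centres - centres[0]) <= 1.0)
        for i in range(1, lad.n_steps):
            assert np.all(lad.origins[i] >= lad.origins[i - 1])
            assert np.all(
                lad.origins[i] + lad.sides_vox[i]
                <= lad.origins[i - 1] + lad.sides_vox[i - 1]
            )


class TestEffectiveDiffusion:
    def test_fully_fluid_cube_is_unity(self):
        res = rp.effective_diffusion(np.ones((16, 16, 16), bool), "z")
        assert res.d_eff == pytest.approx(1.0, abs=1e-6)

    def test_straight_channel_is_unity(self):
        chan = np.zeros((16, 21, 21), bool)
        chan[:, 8:13, 8:13] = True
        res = rp.effective_diffusion(chan, "z")
        assert res.d_eff == pytest.approx(1.0, abs=1e-6)

    def test_blocked_axis_is_zero_and_flagged(self):
        cube = np.ones((12, 12, 12), bool)
        cube[6] = False
        res = rp.effective_diffusion(cube, "z")
        assert res.d_eff == 0.0
        assert not res.percolates

    def test_invariant_under_fluid_subphase_relabelling(self, plain_volume):
        labels = plain_volume.labels
        fluid_a = np.isin(labels, (rp.PORE, rp.MIXED))
        swapped = labels.copy()
        swapped[labels == rp.PORE] = rp.MIXED
        swapped[labels == rp.MIXED] = rp.PORE
        fluid_b = np.isin(swapped, (rp.PORE, rp.MIXED))
        assert np.array_equal(fluid_a, fluid_b)

    def test_axis_rotation_symmetry(self):
        rng = np.random.default_rng(4)
        from scipy import ndimage

        blob = ndimage.gaussian_filter(rng.standard_normal((14, 14, 14)), 1.2) > -0.4
        a = rp.effective_diffusion(blob, "x").d_eff
        b = rp.effective_diffusion(np.swapaxes(blob, 1, 2), "y").d_eff
        assert a > 0
        assert a == pytest.approx(b, rel=1e-9)


class TestPermeability:
    def test_tube_matches_hagen_poiseuille(self):
        R, C, L = 10.0, 31, 12
        tube = make_tube(R, C, L)
        res = rp.permeability(tube, "z", voxel_size=1.0)
        k_theory = np.pi * R**4 / (8 * C * C)
        assert res.k_lattice == pytest.approx(k_theory, rel=0.10)

    def test_slit_matches_plane_poiseuille(self):
        gap, height = 20, 40
        slit = np.zeros((12, height, 8), bool)
        slit[:, 10:30, :] = True
        res = rp.permeability(slit, "z", voxel_size=1.0, side_walls="free-slip")
        assert res.k_lattice == pytest.approx(gap**3 / (12 * height), rel=0.10)

    def test_blocked_axis_is_zero(self):
        cube = np.ones((10, 10, 10), bool)
        cube[5] = False
        res = rp.permeability(cube, "z", voxel_size=1.0)
        assert res.k_cm2 == 0.0 and not res.percolates

    def test_mesh_convergence_toward_closed_form(self):
        errs = []
        for R, C, L in [(5.0, 15, 8), (10.0, 31, 12)]:
            tube = make_tube(R, C, L)
            k = rp.permeability(tube, "z", voxel_size=1.0).k_lattice
            errs.append(abs(k / (np.pi * R**4 / (8 * C * C)) - 1.0))
        assert errs[1] < errs[0]

    def test_unit_conversion_scales_with_voxel_area(self):
        tube = make_tube(4.0, 11, 8)
        a = rp.permeability(tube, "z", voxel_size=1.0)
        b = rp.permeability(tube, "z", voxel_size=10.0)
        assert b.k_cm2 == pytest.approx(a.k_cm2 * 100.0)


class TestFitConvergence:
    def test_noiseless_recovery(self):
        L = np.array([0.5, 0.4, 0.31, 0.25, 0.2, 0.16, 0.12])
        y = 0.8 - 0.3 * np.exp(-2.0 * L)
        fit = fit_convergence(list(zip(L, y)), "diffusion")
        assert fit.a == pytest.approx(0.8, rel=1e-3)
        assert fit.b == pytest.approx(-0.3, rel=1e-3)
        assert fit.c == pytest.approx(2.0, rel=1e-3)
        assert fit.accepted

    def test_constant_series_flagged(self):
        L = np.array([0.5, 0.4, 0.3, 0.2])
        fit = fit_convergence(list(zip(L, np.full(4, 0.7))), "diffusion")
        assert fit.degenerate and not fit.accepted
        assert fit.a == pytest.approx(0.7)

    def test_slow_exponent_rejected(self):
        L = np.array([0.5, 0.4, 0.31, 0.25, 0.2, 0.16, 0.12])
        y = 0.8 - 0.3 * np.exp(-0.1 * L)
        fit = fit_convergence(list(zip(L, y)), "diffusion")
        assert not fit.accepted

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_convergence([(0.5, 1.0), (0.4, 0.9), (0.3, 0.8)], "diffusion")


class TestCampaign:
    def test_bookkeeping_and_isotropy_on_fully_fluid_medium(self):
        labels = np.zeros((40, 40, 40), dtype=np.uint8)  # all pore
        volume = rp.LabelledVolume(labels, voxel_size=8.0)
        subs = rp.sample_subvolumes(volume, n=2, side_um=128.0, seed=0)
        runs, fits, summary = rp.transport_campaign(
            volume, subs, quantities=("diffusion",)
        )
        lad = ladder((0, 0, 0), subs.side_vox, 8.0)
        assert len(runs) == 2 * lad.n_steps * 3
        # free water: every axis and step returns exactly 1
        assert np.allclose(runs["value"], 1.0, atol=1e-6)

    def test_deff_correlates_with_fluid_fraction(self, dexter_volume):
        volume, _ = dexter_volume
        rng = np.random.default_rng(2)
        fluid = np.isin(volume.labels, (rp.PORE, rp.MIXED))
        deffs, fracs = [], []
        for _ in range(12):
            o = [rng.integers(0, s - 14) for s in volume.shape]
            cube = fluid[o[0] : o[0] + 14, o[1] : o[1] + 14, o[2] : o[2] + 14]
            res = rp.effective_diffusion(cube, "z")
            deffs.append(res.d_eff)
            fracs.append(cube.mean())
        r, _ = rp.pearson(deffs, fracs)
        assert r > 0
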