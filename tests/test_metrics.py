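import numpy as np
import pytest

from svrsr.core import ImageGrid, RigidTransform, Volume
from svrsr.metrics import (leave_one_out, match_volume_to_reference, nrmse,
                           psnr, tre, tre_included_mask)

from conftest import make_slice, make_volume, random_rigid


class TestNRMSE:
    def test_identity_zero(self):
        v = make_volume(np.random.default_rng(0).uniform(1, 5, (6, 6, 6)))
        assert nrmse(v, v) == 0.0

    def test_constant_offset_closed_form(self):
        ref = make_volume(np.full((4, 4, 4), 2.0))
        rec = make_volume(np.full((4, 4, 4), 3.0))
        assert nrmse(rec, ref) == pytest.approx(0.5)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 9, (5, 5, 5))
        b = rng.uniform(1, 9, (5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.4
        got = nrmse(make_volume(a), make_volume(b), mask)
        expected = (np.sqrt(((a[mask] - b[mask]) ** 2).mean())
                    / b[mask].mean())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_mean_reference_rejected(self):
        ref = make_volume(np.zeros((3, 3, 3)))
        rec = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            nrmse(rec, ref)


class TestPSNR:
    def test_rmse_equals_max_is_zero_db(self):
        ref = make_volume(np.full((4, 4, 4), 10.0))
        rec = make_volume(np.full((4, 4, 4), 20.0))  # RMSE 10 == MAX 10
        assert psnr(rec, ref) == pytest.approx(0.0, abs=1e-12)

    def test_decade_is_twenty_db(self):
        ref = make_volume(np.full((4, 4, 4), 10.0))
        rec = make_volume(np.full((4, 4, 4), 11.0))  # RMSE 1 == MAX/10
        assert psnr(rec, ref) == pytest.approx(20.0, abs=1e-9)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 9, (5, 5, 5))
        b = rng.uniform(1, 9, (5, 5, 5))
        rmse = np.sqrt(((a - b) ** 2).mean())
        expected = 20 * np.log10(b.max() / rmse)
        assert psnr(make_volume(a), make_volume(b)) == pytest.approx(expected, abs=1e-9)

    def test_identical_infinite(self):
        v = make_volume(np.ones((3, 3, 3)))
        assert psnr(v, v) == float("inf")

    def test_consistency_with_nrmse(self):
        rng = np.random.default_rng(3)
        ref = make_volume(rng.uniform(1, 9, (6, 6, 6)))
        rec1 = make_volume(ref.values + rng.normal(0, 0.1, (6, 6, 6)))
        rec2 = make_volume(ref.values + rng.normal(0, 0.5, (6, 6, 6)))
        assert nrmse(rec1, ref) < nrmse(rec2, ref)
        assert psnr(rec1, ref) > psnr(rec2, ref)


class TestTRE:
    def _slices(self, n=4, shape=(8, 8)):  # 64 voxels: above the ROI floor
        return [make_slice(np.ones(shape), origin=(0.0, 0.0, 3.0 * k))
                for k in range(n)]

    def test_identical_transforms_zero(self):
        slices = self._slices()
        ts = [RigidTransform.identity() for _ in slices]
        mean, per = tre(ts, ts, slices)
        assert mean == 0.0
        assert np.allclose(per, 0.0)

    def test_pure_translation(self):
        slices = self._slices()
        true = [RigidTransform.identity() for _ in slices]
        est = [t.copy() for t in true]
        est[1] = RigidTransform(np.eye(3), (3.0, 0.0, 0.0))
        mean, per = tre(true, est, slices)
        assert per[1] == pytest.approx(3.0)
        assert per[0] == pytest.approx(0.0)

    def test_per_point_oracle(self):
        rng = np.random.default_rng(4)
        slices = self._slices(3)
        true = [random_rigid(rng, max_rot=0.1, max_trans=2.0) for _ in slices]
        est = [random_rigid(rng, max_rot=0.1, max_trans=2.0) for _ in slices]
        mean, per = tre(true, est, slices)
        # brute-force per-voxel distance averaging
        tot, cnt = 0.0, 0
        for s, tt, te in zip(slices, true, est):
            for a in range(s.values.shape[0]):
                for b in range(s.values.shape[1]):
                    p = s.grid.voxel_to_world((a, b, 0))
                    tot += np.linalg.norm(tt.apply(p) - te.apply(p))
                    cnt += 1
        assert mean == pytest.approx(tot / cnt, abs=1e-9)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(5)
        slices = self._slices(3)
        true = [random_rigid(rng, max_rot=0.2, max_trans=3.0) for _ in slices]
        est = [random_rigid(rng, max_rot=0.2, max_trans=3.0) for _ in slices]
        g = random_rigid(rng)
        m1, _ = tre(true, est, slices)
        m2, _ = tre([g.compose(t) for t in true], [g.compose(t) for t in est],
                    slices)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_exclusion_rules(self):
        slices = self._slices(4)
        slices[3].mask[:] = False
        slices[3].mask[0, 0] = True  # tiny ROI
        labels = ["clean", "corrupted", "displaced", "clean"]
        inc = tre_included_mask(labels, slices)
        assert list(inc) == [True, False, False, False]

    def test_no_included_slices_raises(self):
        slices = self._slices(2)
        ts = [RigidTransform.identity()] * 2
        with pytest.raises(ValueError):
            tre(ts, ts, slices, included=np.array([False, False]))


class TestMatchVolume:
    def test_gain_and_bias_recovery(self):
        rng = np.random.default_rng(6)
        ref_vals = rng.uniform(20, 100, (24, 24, 24))
        grid = ImageGrid((24, 24, 24), (1.0,) * 3)
        ref = Volume(grid, ref_vals, np.ones((24, 24, 24), bool))
        xx = np.linspace(0, 2 * np.pi, 24)
        b = 0.1 * np.sin(xx)[:, None, None] * np.ones((24, 24, 24))
        rec = Volume(grid, 0.5 * np.exp(-b) * ref_vals, ref.mask)
        matched = match_volume_to_reference(rec, ref)
        assert nrmse(matched, ref) < nrmse(rec, ref)


class TestLeaveOneOut:
    def test_from_stacks_redundant_stack_near_noise_floor(self, phantom):
        # held-out stack statistically identical to a retained one
        from svrsr.metrics import leave_one_out_from_stacks
        from svrsr.simulator import SimulationSpec, simulate_acquisition
        from svrsr.superres import ReconSettings
        spec = SimulationSpec(slices_per_stack=10, n_displaced=0,
                              n_corrupted=0, bias_amplitude=0.0,
                              scale_range=(1.0, 1.0),
                              max_rotation_deg=0.0, max_translation_mm=0.0,
                              seed=13)
        stacks, _ = simulate_acquisition(phantom, spec)
        value, info = leave_one_out_from_stacks(
            stacks, 0, ReconSettings(em_iterations=10), register=False,
            max_alternations=3)
        noise_ratio = spec.noise_fraction  # sigma relative to volume mean
        assert value < 6 * noise_ratio

    def test_from_stacks_requires_two(self, phantom):
        from svrsr.metrics import leave_one_out_from_stacks
        from svrsr.simulator import SimulationSpec, simulate_acquisition
        spec = SimulationSpec(slices_per_stack=6, seed=14)
        stacks, _ = simulate_acquisition(phantom, spec)
        with pytest.raises(ValueError):
            leave_one_out_from_stacks(stacks[:1], 0)

    def test_noise_floor_oracle(self, phantom):
        # held-out stack simulated exactly from a known volume with additive
        # noise; scoring against that very volume gives ~ the noise ratio
        from svrsr.simulator import SimulationSpec, simulate_acquisition
        noise_frac = 0.03
        spec = SimulationSpec(slices_per_stack=10, n_displaced=0, n_corrupted=0,
                              bias_amplitude=0.0, scale_range=(1.0, 1.0),
                              noise_fraction=noise_frac,
                              max_rotation_deg=0.0, max_translation_mm=0.0,
                              seed=11)
        stacks, truth = simulate_acquisition(phantom, spec)
        vol = phantom.copy()
        vol.mask = np.ones(vol.grid.shape, bool)
        value, info = leave_one_out(vol, stacks[0], register=False,
                                    max_alternations=3)
        sigma = noise_frac * phantom.values.mean()
        expected = sigma / phantom.values.mean()
        # in-mask slice voxels only; ratio within a factor accounting for
        # masking of low-intensity voxels
        assert value == pytest.approx(expected, rel=0.35)

    def test_ssd_history_non_increasing(self, phantom):
        from svrsr.simulator import SimulationSpec, simulate_acquisition
        spec = SimulationSpec(slices_per_stack=10, n_displaced=0, n_corrupted=0,
                              seed=12, max_rotation_deg=0.0,
                              max_translation_mm=0.0)
        stacks, _ = simulate_acquisition(phantom, spec)
        vol = phantom.copy()
        vol.mask = np.ones(vol.grid.shape, bool)
        _, info = leave_one_out(vol, stacks[1], register=False,
                                max_alternations=6)
        h = info["ssd_history"]
        assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))
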