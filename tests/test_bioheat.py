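"""Bioheat solver: warping, stepping, dose, perfusion, conservation."""

import numpy as np
import pytest

from hifufusion import bioheat as bh
from hifufusion.grids import Grid
from hifufusion.motion import MotionTrace, ventilator_motion


def make_grid(n=21, h=0.5, origin=None):
    if origin is None:
        origin = (-(n - 1) / 2 * h,) * 3
    return Grid(origin, (h, h, h), (n, n, n))


def gaussian_q(grid, amp, sigma_mm=1.0, center=(0.0, 0.0, 0.0)):
    X, Y, Z = grid.meshgrid()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    return amp * np.exp(-r2 / (2 * sigma_mm**2))


class TestWarpHeat:
    def test_zero_shift_is_identity(self):
        g = make_grid(11)
        q = gaussian_q(g, 1e6)
        out = bh.warp_heat(q, g.spacing, (0.0, 0.0))
        assert np.array_equal(out, q)

    def test_integer_voxel_shift_conserves_total_power(self):
        g = make_grid(31)
        q = np.zeros(g.shape)
        q[12:18, 12:18, 12:18] = np.random.default_rng(0).random((6, 6, 6))
        out = bh.warp_heat(q, g.spacing, (2 * g.spacing[0], -3 * g.spacing[2]))
        assert abs(out.sum() - q.sum()) <= 1e-12 * q.sum()

    def test_fractional_interior_shift_conserves_total_power(self):
        g = make_grid(31)
        q = np.zeros(g.shape)
        q[13:18, 13:18, 13:18] = 1.0
        out = bh.warp_heat(q, g.spacing, (0.37, -0.81))
        assert out.sum() == pytest.approx(q.sum(), rel=1e-6)

    def test_clipped_shift_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        g = make_grid(12, h=1.0, origin=(0.0, 0.0, 0.0))
        q = rng.random(g.shape)
        shift_vox = (7, 0, -5)  # integer voxels so the oracle is exact
        out = bh.warp_heat(
            q, g.spacing, (shift_vox[0] * 1.0, shift_vox[2] * 1.0), mode="nearest"
        )
        # brute-force voxel relabeling oracle
        expect = np.zeros_like(q)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    si, sk = i - shift_vox[0], k - shift_vox[2]
                    if 0 <= si < 12 and 0 <= sk < 12:
                        expect[i, j, k] = q[si, j, sk]
        assert np.array_equal(out, expect)

    def test_nonfinite_motion_rejected(self):
        g = make_grid(5)
        with pytest.raises(ValueError):
            bh.warp_heat(np.zeros(g.shape), g.spacing, (np.nan, 0.0))


class TestStepBhte:
    def test_equilibrium_is_stationary(self):
        g = make_grid(15)
        tissue = bh.TissueModel(g)
        state = bh.ThermalState.initial(tissue)
        q = np.zeros(g.shape)
        for _ in range(5):
            bh.step_bhte(state, q, tissue, 0.8 * bh.stability_dt(tissue))
        assert np.allclose(state.temperature, 37.0, atol=1e-12)

    def test_perfusion_decay_matches_closed_form(self):
        # uniform hot tissue, no gradients: T(t) = Tb + (T0-Tb) exp(-t/tau)
        # with tau = rho_t C_t / (omega_b C_b) = 34.7 s for the defaults
        g = make_grid(9, h=1.0)
        tissue = bh.TissueModel(g, t_0=50.0)
        state = bh.ThermalState.initial(tissue)
        tau = 3700.0 * 1060.0 / (30.0 * 3770.0)
        assert tau == pytest.approx(34.7, abs=0.05)
        dt = 0.02
        q = np.zeros(g.shape)
        while state.t < tau:
            bh.step_bhte(state, q, tissue, min(dt, tau - state.t), bc="neumann")
        expected = 37.0 + 13.0 / np.e
        assert state.temperature[4, 4, 4] == pytest.approx(expected, rel=1e-3)

    def test_impulse_spreads_as_heat_kernel(self):
        # point temperature impulse with no perfusion: Gaussian profile with
        # variance 2 (k / rho C) t, matched within 2% at interior points
        n, h = 61, 0.5
        g = make_grid(n, h=h)
        tissue = bh.TissueModel(g, omega_b=0.0)
        state = bh.ThermalState.initial(tissue)
        dT0 = 1000.0
        c = n // 2
        state.temperature[c, c, c] += dT0
        D = tissue.k / (tissue.rho_t * tissue.c_t)  # m^2/s
        t_end = 30.0
        dt = 0.8 * bh.stability_dt(tissue)
        q = np.zeros(g.shape)
        while state.t < t_end - 1e-9:
            bh.step_bhte(state, q, tissue, min(dt, t_end - state.t), bc="neumann")
        sig2 = 2.0 * D * state.t  # m^2
        hm = h * 1e-3
        X, Y, Z = g.meshgrid()
        r2 = (X**2 + Y**2 + Z**2) * 1e-6
        expected = 37.0 + dT0 * hm**3 / (2 * np.pi * sig2) ** 1.5 * np.exp(-r2 / (2 * sig2))
        dTexp = expected - 37.0
        sel = dTexp > 0.02 * dTexp.max()
        err = np.abs(state.temperature - expected)[sel] / dTexp.max()
        assert err.max() < 0.02

    def test_vessel_voxels_held_at_blood_temperature(self):
        g = make_grid(11)
        vm = np.zeros(g.shape, dtype=bool)
        vm[5, 5, 5] = True
        tissue = bh.TissueModel(g, vessel_mask=vm)
        state = bh.ThermalState.initial(tissue)
        q = np.full(g.shape, 5e6)
        for _ in range(10):
            bh.step_bhte(state, q, tissue, 0.8 * bh.stability_dt(tissue))
        assert state.temperature[5, 5, 5] == 37.0
        assert state.temperature[3, 3, 3] > 37.5

    def test_unstable_step_refused_with_bound(self):
        g = make_grid(7)
        tissue = bh.TissueModel(g)
        state = bh.ThermalState.initial(tissue)
        with pytest.raises(ValueError, match="stability bound"):
            bh.step_bhte(state, np.zeros(g.shape), tissue, 10.0 * bh.stability_dt(tissue))

    def test_discrete_maximum_principle(self):
        rng = np.random.default_rng(2)
        g = make_grid(13)
        tissue = bh.TissueModel(g, omega_b=0.0)
        state = bh.ThermalState.initial(tissue)
        state.temperature += rng.random(g.shape) * 20.0
        q = np.zeros(g.shape)
        prev_max = state.temperature.max()
        for _ in range(20):
            bh.step_bhte(state, q, tissue, 0.8 * bh.stability_dt(tissue))
            assert state.temperature.max() <= prev_max + 1e-12
            prev_max = state.temperature.max()

    def test_energy_conserved_with_insulated_walls(self):
        rng = np.random.default_rng(3)
        g = make_grid(13)
        tissue = bh.TissueModel(g, omega_b=0.0)
        state = bh.ThermalState.initial(tissue)
        state.temperature += rng.random(g.shape) * 10.0
        e0 = state.temperature.sum()
        q = np.zeros(g.shape)
        for _ in range(100):
            bh.step_bhte(state, q, tissue, 0.8 * bh.stability_dt(tissue), bc="neumann")
        assert abs(state.temperature.sum() - e0) / e0 < 1e-9


class TestDose:
    def _state(self, temp):
        g = make_grid(3, h=1.0)
        tissue = bh.TissueModel(g)
        s = bh.ThermalState.initial(tissue)
        s.temperature[:] = temp
        return s

    def test_reference_temperature_accumulates_real_minutes(self):
        s = self._state(43.0)
        bh.accumulate_dose(s, 240.0 * 60.0)
        assert s.dose_cem[1, 1, 1] == pytest.approx(240.0, rel=1e-12)

    def test_one_second_at_56C(self):
        s = self._state(56.0)
        bh.accumulate_dose(s, 1.0)
        assert s.dose_cem[1, 1, 1] == pytest.approx(0.5**-13 / 60.0, rel=1e-12)
        assert s.dose_cem[1, 1, 1] == pytest.approx(136.5, abs=0.05)

    def test_below_37C_accumulates_nothing(self):
        s = self._state(36.0)
        bh.accumulate_dose(s, 1e6)
        assert np.all(s.dose_cem == 0.0)

    def test_dose_non_decreasing(self):
        s = self._state(45.0)
        prev = 0.0
        for _ in range(5):
            bh.accumulate_dose(s, 1.0)
            now = s.dose_cem[1, 1, 1]
            assert now > prev
            prev = now


class TestPerfusion:
    def test_threshold_inclusive_and_irreversible(self):
        g = make_grid(3, h=1.0)
        tissue = bh.TissueModel(g)
        s = bh.ThermalState.initial(tissue)
        s.dose_cem[1, 1, 1] = 240.0
        s.dose_cem[0, 0, 0] = 239.999
        bh.update_perfusion(s)
        assert s.omega[1, 1, 1] == 0.0
        assert s.omega[0, 0, 0] == 30.0
        s.temperature[:] = 37.0  # cooled below threshold temperature
        bh.update_perfusion(s)
        assert s.omega[1, 1, 1] == 0.0


class TestRunTreatment:
    def test_motion_trace_too_short_rejected(self):
        g = make_grid(9)
        tissue = bh.TissueModel(g)
        plan = bh.ExposurePlan.single_spherical(on_s=5.0)
        short = MotionTrace(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="shorter"):
            bh.run_treatment(plan, tissue, np.zeros(g.shape), motion=short, cooldown_s=0.0)

    def test_periodic_interior_motion_conserves_deposited_energy(self):
        # a full motion period deposits the same total heat as no motion
        # when the warped support never leaves the domain
        g = make_grid(41, h=0.5)
        q = gaussian_q(g, 1.0, sigma_mm=1.0)
        motion = ventilator_motion(duration=10.0, amp_cc=3.0, amp_ap=1.0)
        dt = 0.05
        total = np.zeros(g.shape)
        t = 0.0
        while t < 5.0 - 1e-9:
            dx, dz = motion.sample(t)
            total += bh.warp_heat(q, g.spacing, (dx, dz)) * dt
            t += dt
        stationary = q * 5.0
        assert total.sum() == pytest.approx(stationary.sum(), rel=1e-6)

    def test_lesion_grows_monotonically_and_control_reproducible(self):
        g = make_grid(25, h=0.5)
        tissue = bh.TissueModel(g)
        q = gaussian_q(g, 4e8, sigma_mm=0.8)
        plan = bh.ExposurePlan([((0.0, 0.0, 0.0), 3.0, 0.0, 30.0)], "custom")
        s1, m1 = bh.run_treatment(plan, tissue, q, cooldown_s=5.0)
        s2, m2 = bh.run_treatment(plan, bh.TissueModel(g), q, cooldown_s=5.0)
        assert np.array_equal(s1.dose_cem, s2.dose_cem)  # deterministic
        assert m1.sum() > 0
        # dose monotonicity: lesion after cooldown includes lesion at end of heating
        s3 = bh.ThermalState.initial(bh.TissueModel(g))
        t3 = bh.TissueModel(g)
        dt = 0.8 * bh.stability_dt(t3)
        t = 0.0
        while t < 3.0:
            bh.step_bhte(s3, q, t3, dt)
            bh.accumulate_dose(s3, dt)
            t += dt
        assert np.all(m1[s3.dose_cem >= 240.0])

    def test_grid_refinement_changes_lesion_volume_below_10pct(self):
        vols = []
        for h in (1.0, 0.5):
            n = int(24 / h) + 1
            g = make_grid(n, h=h)
            tissue = bh.TissueModel(g)
            q = gaussian_q(g, 2.5e8, sigma_mm=1.5)
            plan = bh.ExposurePlan([((0.0, 0.0, 0.0), 4.0, 0.0, 30.0)], "custom")
            _, mask = bh.run_treatment(plan, tissue, q, cooldown_s=6.0)
            vols.append(mask.sum() * g.voxel_volume_mm3)
        assert abs(vols[1] - vols[0]) / vols[1] < 0.10


class TestGridHelpers:
    def test_block_average_conserves_mean_and_embeds_back(self):
        g = Grid((0.0, 0.0, 0.0), (0.25, 0.25, 0.25), (8, 8, 8))
        rng = np.random.default_rng(4)
        q = rng.random(g.shape)
        coarse, cg = bh.block_average(q, g, 2)
        assert coarse.shape == (4, 4, 4)
        assert coarse.mean() == pytest.approx(q.mean(), rel=1e-12)
        big = Grid((cg.origin[0] - 1.0, cg.origin[1] - 1.0, cg.origin[2] - 1.0), cg.spacing, (8, 8, 8))
        emb = bh.embed_map(coarse, cg, big)
        assert emb.sum() == pytest.approx(coarse.sum(), rel=1e-12)

    def test_embed_rejects_misaligned_grids(self):
        a = Grid((0.1, 0.0, 0.0), (0.5, 0.5, 0.5), (4, 4, 4))
        b = Grid((0.0, 0.0, 0.0), (0.5, 0.5, 0.5), (8, 8, 8))
        with pytest.raises(ValueError, match="whole voxels"):
            bh.embed_map(np.zeros(a.shape), a, b)
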