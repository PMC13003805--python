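"""Field computation and Bloch-Torrey evolution against closed-form oracles."""

import numpy as np
import pytest

from vsdprint.core import BinaryVascularVolume, VoxelGrid
from vsdprint.gesfide import (
    GAMMA_RAD_S_T,
    FieldMap,
    GesfideCurve,
    SimulationConfig,
    compute_field,
    concentration_from_susceptibility,
    delta_r2,
    delta_r2_star,
    evolve_bloch_torrey,
    simulate_gesfide,
    simulate_gesfide_batch,
    susceptibility_map,
)


def _cylinder_mask(n, radius_vox, axis, voxel_size=2.0):
    """Infinite cylinder through the periodic box along one coordinate axis."""
    grid = VoxelGrid((n, n, n), voxel_size)
    ax = np.arange(n, dtype=float)
    # axis through the box center, off-lattice to avoid digitization symmetry
    u, v = np.meshgrid(ax - n / 2 + 0.28, ax - n / 2 + 0.37, indexing="ij")
    disk = u**2 + v**2 <= radius_vox**2
    if axis == 2:  # along z
        mask = np.broadcast_to(disk[:, :, None], (n, n, n)).copy()
    else:  # along x
        mask = np.broadcast_to(disk[None, :, :], (n, n, n)).copy()
    return BinaryVascularVolume(mask, grid), disk


class TestSusceptibility:
    def test_empty_and_full(self):
        grid = VoxelGrid((8, 8, 8), 1.8)
        cfg = SimulationConfig()
        empty = BinaryVascularVolume(np.zeros((8, 8, 8), bool), grid)
        assert not susceptibility_map(empty, cfg).any()
        full = BinaryVascularVolume(np.ones((8, 8, 8), bool), grid)
        chi = susceptibility_map(full, cfg)
        assert np.allclose(chi, cfg.delta_chi)
        # constant susceptibility -> zero field after k=0 removal
        fmap = compute_field(chi, cfg, grid)
        assert np.allclose(fmap.delta_b, 0.0, atol=1e-18)

    def test_cgs_convention_scales_by_4pi(self):
        grid = VoxelGrid((8, 8, 8), 1.8)
        mask = BinaryVascularVolume(np.random.default_rng(0).random((8, 8, 8)) > 0.5, grid)
        si = susceptibility_map(mask, SimulationConfig(chi_convention="si_ppm"))
        cgs = susceptibility_map(mask, SimulationConfig(chi_convention="cgs_4pi"))
        assert np.allclose(cgs, 4 * np.pi * si)


class TestFieldOracles:
    def test_parallel_cylinder_no_extravascular_variation(self):
        vol, disk = _cylinder_mask(64, 6.0, axis=2)
        cfg = SimulationConfig()
        fmap = compute_field(susceptibility_map(vol, cfg), cfg, vol.grid)
        outside = ~vol.mask
        scale = cfg.delta_chi * cfg.b0
        # analytic: uniform shift everywhere outside (zero up to the demeaning offset)
        assert np.ptp(fmap.delta_b[outside]) <= 1e-3 * scale
        expected_out = -scale * vol.cbv / 3.0
        assert fmap.delta_b[outside].mean() == pytest.approx(expected_out, rel=1e-6)

    def test_perpendicular_cylinder_dipolar_pattern(self):
        n, a_vox, h = 128, 4.0, 2.0
        grid = VoxelGrid((n, n, n), h)
        cfg = SimulationConfig()
        # partial-volume cross-section (the package's coarse-grid pathway):
        # sub-voxel occupancy of the ideal disk, axis along x, B0 along z
        ss = 8
        ax = (np.arange(n * ss) + 0.5) / ss - 0.5
        u, v = np.meshgrid(ax - n / 2 + 0.28, ax - n / 2 + 0.37, indexing="ij")
        disk = (u**2 + v**2 <= a_vox**2).astype(float).reshape(n, ss, n, ss).mean(axis=(1, 3))
        chi = cfg.delta_chi * np.broadcast_to(disk[None, :, :], (n, n, n)).copy()
        fmap = compute_field(chi, cfg, grid)
        a = a_vox * h
        yy = (np.arange(n) - n / 2 + 0.28) * h
        zz = (np.arange(n) - n / 2 + 0.37) * h
        y, z = np.meshgrid(yy, zz, indexing="ij")
        rho2 = y**2 + z**2
        cos2phi = (z**2 - y**2) / rho2  # φ measured from the B0 (z) axis
        scale = cfg.delta_chi * cfg.b0
        # closed form: (Δχ/2)B0 (a/ρ)² cos2φ outside, (Δχ/6)B0 inside
        analytic = np.where(
            rho2 > a**2, 0.5 * scale * (a**2 / rho2) * cos2phi, scale / 6.0
        )
        # compare in the mid-plane, 2–3 radii from the axis, against the
        # field envelope at that distance (both fields taken mean-free)
        numeric = fmap.delta_b[n // 2] - fmap.delta_b[n // 2].mean()
        band = (rho2 >= (2 * a) ** 2) & (rho2 <= (3 * a) ** 2)
        envelope = 0.5 * scale * (a**2 / rho2[band])
        err = np.abs(numeric[band] - (analytic[band] - analytic.mean()))
        assert np.max(err / envelope) <= 0.05

    def test_field_linearity_and_realness(self):
        rng = np.random.default_rng(1)
        grid = VoxelGrid((16, 16, 16), 2.0)
        cfg = SimulationConfig()
        chi_a = rng.random((16, 16, 16)) * 1e-6
        chi_b = rng.random((16, 16, 16)) * 1e-6
        fa = compute_field(chi_a, cfg, grid).delta_b
        fb = compute_field(chi_b, cfg, grid).delta_b
        fab = compute_field(chi_a + chi_b, cfg, grid).delta_b
        assert np.allclose(fab, fa + fb, atol=1e-18)
        assert np.isrealobj(fa)

    def test_nan_input_rejected(self):
        grid = VoxelGrid((8, 8, 8), 2.0)
        chi = np.zeros((8, 8, 8))
        chi[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            compute_field(chi, SimulationConfig(), grid)


class TestBlochTorrey:
    def test_zero_field_gives_unit_signal(self):
        grid = VoxelGrid((12, 12, 12), 5.0)
        cfg = SimulationConfig(dt=1e-3)
        fmap = FieldMap(np.zeros((12, 12, 12)), grid)
        signal = evolve_bloch_torrey(fmap, cfg=cfg)
        assert np.allclose(signal, 1.0, atol=1e-12)
        assert signal.shape == (18,)

    def test_static_spins_refocus_perfectly_at_spin_echo(self):
        rng = np.random.default_rng(2)
        grid = VoxelGrid((12, 12, 12), 5.0)
        cfg = SimulationConfig(diffusivity_mm2_s=0.0, dt=1e-3)
        fmap = FieldMap(rng.normal(0, 2e-6, (12, 12, 12)), grid)  # strong arbitrary field
        signal = evolve_bloch_torrey(fmap, cfg=cfg)
        se_idx = np.nonzero(np.isclose(cfg.echo_times, 0.120))[0][0]
        assert signal[se_idx] == pytest.approx(1.0, abs=1e-10)
        assert signal[5] < 0.9  # but the FID echoes do dephase

    def test_uniform_gradient_free_diffusion_decay(self):
        """Local |M(t)| = exp(−γ²G²D·t³/3) for unrefocused diffusion in a
        linear field (the closed-form Bloch-Torrey solution
        M(z,t) = exp(−iγGzt − γ²G²Dt³/3) has a uniform magnitude; the net
        signal additionally carries the trivial sinc dephasing factor)."""
        n = 1024
        h = 2.0  # µm
        grid = VoxelGrid((2, 2, n), h)
        gamma_g = 2.0  # γG in rad s⁻¹ µm⁻¹
        z = (np.arange(n) - n / 2) * h
        field = np.broadcast_to(gamma_g * z / GAMMA_RAD_S_T, (2, 2, n)).copy()
        d_um2_s = 1e-3 * 1e6
        for t in (0.01, 0.02, 0.03, 0.04):
            cfg = SimulationConfig(dt=0.5e-3, echo_times=np.array([t]), refocus_time=t / 2)
            _, m = evolve_bloch_torrey(
                FieldMap(field, grid), cfg=cfg, refocus=False, return_magnetization=True
            )
            # interior voxel far from the periodic field discontinuity
            local = abs(m[0, 0, n // 2])
            expected = np.exp(-(gamma_g**2) * d_um2_s * t**3 / 3.0)
            assert local == pytest.approx(expected, rel=0.02), t

    def test_unstable_dt_refused(self):
        grid = VoxelGrid((8, 8, 8), 2.0)  # stability bound: 4/(6·1000) ≈ 0.67 ms
        cfg = SimulationConfig(dt=2e-3)
        fmap = FieldMap(np.zeros((8, 8, 8)), grid)
        with pytest.raises(ValueError, match="stability"):
            evolve_bloch_torrey(fmap, cfg=cfg)


class TestGesfide:
    def test_empty_mask_unit_ratio(self):
        grid = VoxelGrid((12, 12, 12), 5.0)
        curve = simulate_gesfide(
            BinaryVascularVolume(np.zeros((12, 12, 12), bool), grid), SimulationConfig(dt=1e-3)
        )
        assert np.allclose(curve.ratio, 1.0)
        assert np.allclose(curve.s_pre, 1.0)

    def test_spin_echo_recovers_static_dephasing(self):
        vol, _ = _cylinder_mask(24, 3.0, axis=0, voxel_size=4.0)
        cfg = SimulationConfig(dt=1e-3)
        chi = susceptibility_map(vol, cfg)
        fmap = compute_field(chi, cfg, vol.grid)
        refocused = evolve_bloch_torrey(fmap, cfg=cfg, refocus=True)
        fid_only = evolve_bloch_torrey(fmap, cfg=cfg, refocus=False)
        se_idx = np.nonzero(np.isclose(cfg.echo_times, 0.120))[0][0]
        assert refocused[se_idx] > fid_only[se_idx]

    def test_higher_cbv_lowers_ratio_at_60ms(self):
        from vsdprint.synth import generate_network

        grid = VoxelGrid((24, 24, 24), 221.4 / 24)
        cfg = SimulationConfig(dt=2.5e-3)
        sampler = {"kind": "uniform", "low": 5.0, "high": 10.0}
        curves = []
        for target in (0.03, 0.15):
            vol, _ = generate_network(grid, target, sampler, seed=8)
            curves.append(simulate_gesfide(vol, cfg))
        idx = np.nonzero(np.isclose(cfg.echo_times, 0.060))[0][0]
        assert curves[1].ratio[idx] < curves[0].ratio[idx]

    def test_batch_matches_single_simulation(self):
        from vsdprint.synth import generate_network

        grid = VoxelGrid((16, 16, 16), 8.0)
        cfg = SimulationConfig(dt=2e-3)
        vol, _ = generate_network(grid, 0.08, {"kind": "uniform", "low": 6, "high": 12}, seed=4)
        single = simulate_gesfide(vol, cfg).ratio
        batch = simulate_gesfide_batch(
            vol.mask.astype(np.float32)[None], grid, cfg
        )[0]
        assert np.allclose(batch, single, atol=2e-4)  # float32 batch vs float64 single


class TestRelaxationRates:
    def _curve(self, ratios_by_time):
        times = np.array(sorted(ratios_by_time))
        full = SimulationConfig().echo_times
        s_post = np.ones_like(full)
        for t, r in ratios_by_time.items():
            s_post[np.isclose(full, t)] = r
        return GesfideCurve(full, np.ones_like(full), s_post)

    def test_delta_r2_star_hand_value(self):
        curve = self._curve({0.010: 0.90, 0.040: 0.60})
        assert delta_r2_star(curve) == pytest.approx(np.log(1.5) / 0.030, abs=1e-9)
        assert delta_r2_star(curve) == pytest.approx(13.52, abs=0.01)

    def test_delta_r2_star_inverse_construction(self):
        curve = self._curve({0.010: 0.5 * np.exp(0.3), 0.040: 0.5})
        assert delta_r2_star(curve) == pytest.approx(10.0, abs=1e-9)
        flat = self._curve({0.010: 0.7, 0.040: 0.7})
        assert delta_r2_star(flat) == 0.0

    def test_delta_r2_values(self):
        assert delta_r2(self._curve({0.120: 0.80})) == pytest.approx(1.8595, abs=1e-4)
        assert delta_r2(self._curve({0.120: 1.0})) == 0.0
        assert delta_r2(self._curve({0.120: np.exp(-0.12)})) == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta_r2(self._curve({0.120: 0.0}))


class TestCalibration:
    def test_iron_concentration_from_one_ppm(self):
        mg_per_ml, mm = concentration_from_susceptibility(1.0, 11.6, 55.845)
        assert mg_per_ml == pytest.approx(0.086, abs=0.001)
        assert mm == pytest.approx(1.54, abs=0.01)

    def test_zero_shift_and_bad_slope(self):
        assert concentration_from_susceptibility(0.0) == (0.0, 0.0)
        with pytest.raises(ValueError):
            concentration_from_susceptibility(1.0, 0.0)


class TestConfig:
    def test_echo_times_must_include_spin_echo(self):
        with pytest.raises(ValueError, match="spin-echo"):
            SimulationConfig(echo_times=np.array([0.01, 0.02]), refocus_time=0.060)

    def test_auto_dt_respects_stability_and_cap(self):
        cfg = SimulationConfig()
        # coarse grid: capped at 0.5 ms
        assert cfg.resolve_dt(10.0) == pytest.approx(0.5e-3)
        # fine grid (1.8 µm): stability bound 0.54 ms... check consistency
        dt = cfg.resolve_dt(1.8)
        assert dt <= cfg.stability_dt(1.8)
        assert (0.010 / dt) == pytest.approx(round(0.010 / dt))
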