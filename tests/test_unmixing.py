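"""Wavelength-set averaging, energy-normalized NNLS unmixing, SO2 maps, and
ICG time-activity curves."""

import numpy as np
import pytest

from fuspa.synth import ChromophorePhantom, PAStack, simulate_mspa_stack
from fuspa.unmixing import (
    ConcentrationMaps,
    average_wavelength_sets,
    build_system_matrix,
    compute_so2,
    default_extinction_table,
    icg_time_activity,
    split_frame_block,
    unmix_stack,
)

TABLE = default_extinction_table()
WL = (750.0, 800.0, 850.0)


def stack_of(images, energies=(1.0, 1.0, 1.0)):
    return PAStack(images=images, wavelengths_nm=WL, pulse_energies_mj=energies)


class TestAveraging:
    def test_identical_sets_average_to_any_set(self):
        one = np.random.default_rng(0).uniform(size=(3, 4, 4))
        stack = stack_of(np.repeat(one[None], 5, axis=0))
        assert np.allclose(average_wavelength_sets(stack), one)

    def test_noise_drops_as_sqrt_of_sets(self):
        rng = np.random.default_rng(1)
        clean = np.ones((3, 24, 24))
        images = clean[None] + rng.normal(scale=0.2, size=(5, 3, 24, 24))
        avg = average_wavelength_sets(stack_of(images))
        residual = (avg - clean).std()
        assert residual == pytest.approx(0.2 / np.sqrt(5), rel=0.10)

    def test_sixteen_frame_block_keeps_five_sets(self):
        frames = np.arange(16)[:, None, None] * np.ones((16, 2, 2))
        sets = split_frame_block(frames, n_wavelengths=3)
        assert sets.shape == (5, 3, 2, 2)
        assert sets[-1, -1, 0, 0] == 14  # frame 15 (the spare) was dropped

    def test_incomplete_block_rejected(self):
        with pytest.raises(ValueError):
            split_frame_block(np.ones((2, 2, 2)), n_wavelengths=3)


class TestSystemMatrix:
    def test_equal_energies_reproduce_raw_extinction(self):
        e = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        raw = np.array([[TABLE.epsilon(ch, wl) for ch in ("HbO", "HbD", "ICG")] for wl in WL])
        assert np.allclose(e, raw)

    def test_doubling_one_energy_scales_that_row_only(self):
        e1 = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        e2 = build_system_matrix(TABLE, WL, (1.0, 2.0, 1.0))
        assert np.allclose(e2[1], 2 * e1[1])
        assert np.allclose(e2[0], e1[0]) and np.allclose(e2[2], e1[2])

    def test_embedded_table_is_well_conditioned(self):
        e = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        # normalize columns to compare spectral shapes, not magnitudes
        cond = np.linalg.cond(e / np.linalg.norm(e, axis=0))
        assert np.isfinite(cond) and cond < 100

    def test_mismatched_energies_rejected(self):
        with pytest.raises(ValueError):
            build_system_matrix(TABLE, WL, (1.0, 1.0))


class TestNNLS:
    def test_exact_forward_model_inverted(self):
        e = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        p = (e @ np.array([1.0, 0.0, 0.0]))[:, None, None] * np.ones((3, 2, 2))
        conc = unmix_stack(p, e)
        assert conc.HbO[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert conc.HbD[0, 0] == pytest.approx(0.0, abs=1e-8)
        assert conc.ICG[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_negative_data_clipped_to_zero(self):
        e = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        p = -(e @ np.array([1.0, 0.0, 0.0]))[:, None, None] * np.ones((3, 1, 1))
        conc = unmix_stack(p, e)
        assert conc.HbO[0, 0] == 0.0
        assert conc.HbD[0, 0] == 0.0
        assert conc.ICG[0, 0] == 0.0

    def test_nnls_beats_brute_force_grid(self):
        """The NNLS objective is at least as small as every candidate on a
        50^3 non-negative grid (independent brute-force oracle)."""
        rng = np.random.default_rng(4)
        e = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        e_scaled = e / np.linalg.norm(e, axis=0)  # comparable concentration scales
        for _ in range(5):
            p = rng.uniform(0, 1, size=3)
            conc = unmix_stack(p[:, None, None] * np.ones((3, 1, 1)), e_scaled)
            fitted = np.array([conc.HbO[0, 0], conc.HbD[0, 0], conc.ICG[0, 0]])
            obj = np.linalg.norm(e_scaled @ fitted - p)
            grid = np.linspace(0, 2.0, 50)
            gh, gd, gi = np.meshgrid(grid, grid, grid, indexing="ij")
            cand = np.stack([gh.ravel(), gd.ravel(), gi.ravel()])
            objs = np.linalg.norm(e_scaled @ cand - p[:, None], axis=0)
            assert obj <= objs.min() + 1e-9

    def test_scale_equivariance_energy_and_images(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 1, size=(3, 4, 4))
        e1 = build_system_matrix(TABLE, WL, (1.0, 1.0, 1.0))
        e2 = build_system_matrix(TABLE, WL, (3.0, 3.0, 3.0))
        c1 = unmix_stack(p, e1)
        c2 = unmix_stack(3.0 * p, e2)
        assert np.allclose(c1.HbO, c2.HbO, rtol=1e-8)
        assert np.allclose(c1.ICG, c2.ICG, rtol=1e-8)


class TestSO2:
    def test_basic_ratios(self):
        maps = ConcentrationMaps(
            HbO=np.array([[1.0, 1.0, 0.0]]),
            HbD=np.array([[1.0, 0.0, 0.0]]),
            ICG=np.zeros((1, 3)),
            residual=np.zeros((1, 3)),
        )
        so2 = compute_so2(maps, floor=1e-6)
        assert so2.so2[0, 0] == pytest.approx(0.5)
        assert so2.so2[0, 1] == pytest.approx(1.0)
        assert np.isnan(so2.so2[0, 2]) and not so2.support_mask[0, 2]

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        hbo = rng.uniform(0.1, 1, (4, 4))
        hbd = rng.uniform(0.1, 1, (4, 4))
        a = compute_so2(ConcentrationMaps(hbo, hbd, 0 * hbo, 0 * hbo), floor=0.0)
        b = compute_so2(ConcentrationMaps(7 * hbo, 7 * hbd, 0 * hbo, 0 * hbo), floor=0.0)
        assert np.allclose(a.so2, b.so2)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_so2_recovered_at_30db_snr(self, seed):
        rng = np.random.default_rng(1000 + seed)
        hbo = rng.uniform(0.2, 1, (32, 32))
        hbd = rng.uniform(0.2, 1, (32, 32))
        icg = rng.uniform(0.1, 1, (32, 32)) * 3e-3
        clean = simulate_mspa_stack(
            ChromophorePhantom(maps={"HbO": hbo, "HbD": hbd, "ICG": icg}),
            n_sets=1, seed=0,
        ).images
        sigma = np.sqrt((clean**2).mean()) / 10 ** (30 / 20)
        phantom = ChromophorePhantom(
            maps={"HbO": hbo, "HbD": hbd, "ICG": icg}, noise_sigma=sigma
        )
        stack = simulate_mspa_stack(phantom, n_sets=5, seed=seed)
        e = build_system_matrix(TABLE, stack.wavelengths_nm, stack.pulse_energies_mj)
        conc = unmix_stack(average_wavelength_sets(stack), e)
        so2 = compute_so2(conc)
        truth = hbo / (hbo + hbd)
        mask = so2.support_mask
        assert np.abs(so2.so2[mask] - truth[mask]).mean() < 0.02
        # the reported quantity for ICG is the ROI mean (time-activity curves)
        assert abs(conc.ICG.mean() - icg.mean()) / icg.mean() < 0.05


class TestICGTimeActivity:
    def make_maps(self, series):
        out = []
        for v in series:
            icg = np.full((4, 4), v)
            out.append(ConcentrationMaps(0 * icg, 0 * icg, icg, 0 * icg))
        return out

    def test_constant_map_gives_flat_series(self):
        maps = self.make_maps([2.0] * 6)
        roi = np.ones((4, 4), dtype=bool)
        res = icg_time_activity(maps, {"all": roi})
        assert np.allclose(res["all"]["raw"], 2.0)
        assert np.allclose(res["all"]["smoothed"], 2.0)

    def test_bolus_peak_found_within_one_frame(self):
        t = np.arange(40, dtype=float)
        t0, alpha, beta = 8.0, 3.0, 4.0  # gamma-variate bolus, peak at t0+alpha*beta
        bolus = np.where(t > t0, ((t - t0) ** alpha) * np.exp(-(t - t0) / beta), 0.0)
        maps = self.make_maps(bolus)
        roi = np.ones((4, 4), dtype=bool)
        res = icg_time_activity(maps, {"roi": roi}, smooth_window=3)
        assert abs(int(np.argmax(res["roi"]["raw"])) - (t0 + alpha * beta)) <= 1

    def test_window_one_is_identity(self):
        maps = self.make_maps([1.0, 3.0, 2.0, 5.0])
        roi = np.ones((4, 4), dtype=bool)
        res = icg_time_activity(maps, {"r": roi}, smooth_window=1)
        assert np.array_equal(res["r"]["raw"], res["r"]["smoothed"])

    def test_empty_roi_rejected(self):
        maps = self.make_maps([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            icg_time_activity(maps, {"r": np.zeros((4, 4), dtype=bool)})
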