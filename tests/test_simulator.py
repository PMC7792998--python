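"""Simulator: superellipsoid geometry, correlated phase fields, rotations,
randomized particle sampling."""

import numpy as np
import pytest
from scipy import stats

import cdinvert as ci
from cdinvert.simulator import scale_phase, unscale_phase


@pytest.fixture(scope="module")
def grid64():
    return ci.GridSpec(64, 64)


class TestVoxelizeSuperellipsoid:
    def test_sphere_limit_exact(self, grid64):
        """e = n = 1 reduces exactly to the voxelized ball."""
        mask = ci.voxelize_superellipsoid(
            grid64, ci.SuperellipsoidParams(10, 10, 10, 1, 1)
        )
        x = grid64.axis_coords()
        ball = (
            x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        ) <= 100.0
        assert np.array_equal(mask, ball)

    def test_sphere_volume(self, grid64):
        """Voxel count matches the analytic ball volume within 2%."""
        mask = ci.voxelize_superellipsoid(
            grid64, ci.SuperellipsoidParams(10, 10, 10, 1, 1)
        )
        vol = 4 / 3 * np.pi * 10**3
        assert abs(mask.sum() - vol) / vol < 0.02

    def test_octahedron_limit_exact(self, grid64):
        """e = n = 2 reduces exactly to the voxelized octahedron."""
        mask = ci.voxelize_superellipsoid(
            grid64, ci.SuperellipsoidParams(10, 10, 10, 2, 2)
        )
        x = grid64.axis_coords()
        octa = (
            np.abs(x[:, None, None]) + np.abs(x[None, :, None]) + np.abs(x[None, None, :])
        ) <= 10.0
        assert np.array_equal(mask, octa)

    @pytest.mark.parametrize("e,n", [(0.5, 0.5), (1.0, 2.0), (3.0, 1.5)])
    def test_negation_symmetry(self, grid64, e, n):
        mask = ci.voxelize_superellipsoid(
            grid64, ci.SuperellipsoidParams(9, 7, 11, e, n)
        )
        for ax in range(3):
            flipped = np.flip(mask, axis=ax)
            assert np.array_equal(mask, flipped)

    def test_oversized_axis_rejected(self, grid64):
        with pytest.raises(ValueError, match="semi-axis b"):
            ci.voxelize_superellipsoid(
                grid64, ci.SuperellipsoidParams(10, 20, 10, 1, 1)
            )


class TestPhaseField:
    def test_isotropic_statistics(self, grid64):
        """Equal correlation lengths give matching autocorrelation widths."""
        widths = _mean_halfwidths(grid64, (5.0, 5.0, 5.0), n_seeds=20)
        assert np.ptp(widths) / widths.mean() < 0.1

    def test_infinite_correlation_limit(self, grid64):
        """L much larger than the lag makes the field effectively constant
        across that scale: the normalized autocorrelation at the lag
        approaches 1 (Gaussian prediction exp(-lag^2/(2 L^2)) = 0.97 for
        L = 16, lag = 4), while for L of a couple of voxels it is near 0."""
        assert _autocorr_at_lag(grid64, L=16.0, lag=4) > 0.9
        assert _autocorr_at_lag(grid64, L=2.0, lag=4) < 0.25

    def test_correlation_lengths_recovered(self, grid64):
        """1/e autocorrelation half-widths match sqrt(2)*L within 15%.

        The white noise is convolved with the kernel exp(-x^2/L^2), whose
        self-correlation is a Gaussian with 1/e half-width sqrt(2)*L.
        """
        L = np.array([4.0, 8.0, 4.0])
        widths = _mean_halfwidths(grid64, tuple(L), n_seeds=50)
        expected = np.sqrt(2.0) * L
        assert np.all(np.abs(widths - expected) / expected < 0.15)

    def test_span_and_determinism(self, grid64):
        p = ci.PhaseFieldParams(4, 4, 4, phase_span=np.pi, seed=5)
        f1 = ci.sample_phase_field(grid64, p)
        f2 = ci.sample_phase_field(grid64, p)
        assert np.array_equal(f1, f2)
        assert f1.min() >= -np.pi / 2 - 1e-12
        assert f1.max() <= np.pi / 2 + 1e-12
        assert np.isclose(f1.max() - f1.min(), np.pi)


def _autocorr_at_lag(grid, L, lag, n_seeds=10):
    vals = []
    for seed in range(n_seeds):
        fld = ci.sample_phase_field(
            grid, ci.PhaseFieldParams(L, L, L, phase_span=2 * np.pi, seed=seed)
        )
        fld = fld - fld.mean()
        F = np.fft.fftn(fld)
        ac = np.fft.ifftn(np.abs(F) ** 2).real
        vals.append(ac[lag, 0, 0] / ac[0, 0, 0])
    return float(np.mean(vals))


def _mean_halfwidths(grid, Ls, n_seeds):
    widths = []
    for seed in range(n_seeds):
        fld = ci.sample_phase_field(
            grid, ci.PhaseFieldParams(*Ls, phase_span=2 * np.pi, seed=seed)
        )
        fld = fld - fld.mean()
        F = np.fft.fftn(fld)
        ac = np.fft.ifftn(np.abs(F) ** 2).real
        ac /= ac.flat[0]
        row = []
        for ax in range(3):
            prof = ac
            for other in range(3):
                if other != ax:
                    prof = np.take(prof, 0, axis=0 if other < ax else 1)
            prof = np.ravel(prof)[: grid.n_obj // 2]
            idx = int(np.argmax(prof < 1 / np.e))
            y0, y1 = prof[idx - 1], prof[idx]
            row.append(idx - 1 + (y0 - 1 / np.e) / (y0 - y1))
        widths.append(row)
    return np.mean(widths, axis=0)


class TestAssembleObject:
    def test_zero_sigma_identity(self, grid64):
        mask = ci.voxelize_superellipsoid(grid64, ci.SuperellipsoidParams(8, 8, 8, 1, 1))
        fld = ci.sample_phase_field(grid64, ci.PhaseFieldParams(4, 4, 4, seed=1))
        obj = ci.assemble_object(mask, fld, smoothing_sigma=0.0)
        assert np.array_equal(obj.amplitude, mask.astype(float))

    def test_phase_masked(self, grid64):
        mask = ci.voxelize_superellipsoid(grid64, ci.SuperellipsoidParams(8, 8, 8, 1, 1))
        fld = ci.sample_phase_field(grid64, ci.PhaseFieldParams(4, 4, 4, seed=1))
        obj = ci.assemble_object(mask, fld, smoothing_sigma=1.0)
        assert np.all(obj.phase[~mask] == 0)
        assert np.all(obj.phase[obj.amplitude == 0] == 0)

    def test_blur_preserves_half_maximum_edge(self, grid64):
        """The 0.5 level set of the blurred ball stays within 1 voxel of r=10."""
        mask = ci.voxelize_superellipsoid(grid64, ci.SuperellipsoidParams(10, 10, 10, 1, 1))
        obj = ci.assemble_object(mask, np.zeros_like(mask, dtype=float), 1.0)
        x = grid64.axis_coords()
        r = np.sqrt(
            x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        )
        shell = obj.amplitude >= 0.5
        assert abs(r[shell].max() - 10.0) <= 1.0
        assert obj.amplitude.max() == 1.0

    def test_empty_mask_rejected(self, grid64):
        empty = np.zeros((64, 64, 64), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            ci.assemble_object(empty, np.zeros((64, 64, 64)), 1.0)


class TestRotateObject:
    def test_identity(self, particle32):
        obj, _ = particle32
        out = ci.rotate_object(obj, ci.Orientation((1.0, 0.0, 0.0, 0.0)))
        assert np.abs(out.amplitude - obj.amplitude).max() <= 1e-6
        assert np.abs(out.phase - obj.phase).max() <= 1e-6

    def test_quarter_turn_exact(self, particle32):
        """90 degrees about a grid axis is a lattice-preserving rotation."""
        obj, _ = particle32
        q = ci.Orientation((np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)))
        out = ci.rotate_object(obj, q)
        ref = np.rot90(obj.amplitude, k=1, axes=(0, 1))
        assert np.abs(out.amplitude - ref).max() < 1e-12

    def test_energy_approximately_conserved(self, particle32):
        """Trilinear resampling is near-unitary: total |amplitude|^2 within 10%."""
        obj, _ = particle32
        e0 = (obj.amplitude**2).sum()
        rng = np.random.default_rng(99)
        for _ in range(20):
            out = ci.rotate_object(obj, ci.random_orientation(rng))
            ratio = (out.amplitude**2).sum() / e0
            assert 0.9 < ratio < 1.005


class TestSampleRandomParticle:
    def test_deterministic(self, config32):
        a, pa = ci.sample_random_particle(config32, 77)
        b, pb = ci.sample_random_particle(config32, 77)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert np.array_equal(a.phase, b.phase)
        assert pa == pb

    def test_invariants_over_many_seeds(self, config32):
        for seed in range(200):
            obj, _ = ci.sample_random_particle(config32, seed)
            assert obj.amplitude.min() >= 0 and obj.amplitude.max() <= 1
            assert np.all(obj.phase[obj.amplitude == 0] == 0)
            keep = np.zeros(obj.amplitude.shape, dtype=bool)
            keep[obj.grid.central_cube()] = True
            assert not np.any(obj.amplitude[~keep] > 0)
            span = obj.phase.max() - obj.phase.min()
            assert span <= 2 * np.pi + 1e-9

    def test_exponent_distribution_uniform(self, config32):
        es = np.array(
            [ci.sample_random_particle(config32, s)[1]["e"] for s in range(400)]
        )
        lo, hi = config32.exponent_range
        stat = stats.kstest(es, stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert stat.pvalue > 0.01

    def test_empty_range_rejected(self, grid64=None):
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32), semi_axis_range=(8.0, 8.0))
        with pytest.raises(ValueError, match="empty"):
            ci.sample_random_particle(cfg, 0)


class TestTrainingSample:
    def test_target_shapes_and_masking(self, sample32):
        s = sample32
        assert s.target_amplitude.shape == (16, 16)
        assert s.target_phase_scaled.shape == (16, 16)
        assert np.all(s.target_phase_scaled[s.target_amplitude == 0] == 0)
        assert s.target_amplitude.min() >= 0 and s.target_amplitude.max() == 1.0
        assert s.target_phase_scaled.min() >= 0 and s.target_phase_scaled.max() <= 1

    def test_phase_scaling_roundtrip(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, size=(16, 16))
        support = rng.uniform(size=(16, 16)) > 0.3
        phase = np.where(support, phase, 0.0)
        scaled = scale_phase(phase, support)
        back = unscale_phase(scaled, support)
        assert np.allclose(back[support], phase[support], atol=1e-12)
        assert np.all(back[~support] == 0)

    def test_split_fractions(self, corpus32):
        n = len(corpus32)
        assert len(corpus32.train_idx) == round(0.95 * n)
        assert len(corpus32.val_idx) == n - len(corpus32.train_idx)
        assert not set(corpus32.train_idx) & set(corpus32.val_idx)
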