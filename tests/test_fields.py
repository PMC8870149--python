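"""Virtual-patient field generation, embedding, interpolation, and NIfTI I/O."""

import numpy as np
import pytest

from gliomech.fields import (FieldGeneratorSpec, InvalidSpecError, TumorSeedSpec,
                             VoxelField, embed_tumor_data, generate_dti_field,
                             generate_modulus_field, interpolate_to_mesh,
                             read_nifti, write_nifti)


def _grid(n=32, spacing=2.0):
    return VoxelField(origin=np.full(3, -(n - 1) * spacing / 2),
                      spacing=np.full(3, spacing), dims=(n, n, n))


class TestGenerateModulusField:
    def test_determinism(self):
        spec = FieldGeneratorSpec(seed=9)
        a = generate_modulus_field(spec, _grid())
        b = generate_modulus_field(spec, _grid())
        assert np.array_equal(a.channels["storage_modulus_Pa"],
                              b.channels["storage_modulus_Pa"])
        assert np.array_equal(a.channels["loss_modulus_Pa"],
                              b.channels["loss_modulus_Pa"])

    def test_zero_sd_constant(self):
        spec = FieldGeneratorSpec(target_mean=1500.0, target_sd=0.0, seed=1)
        out = generate_modulus_field(spec, _grid(16))
        assert np.allclose(out.channels["storage_modulus_Pa"], 1500.0)

    def test_mean_sd_targets(self):
        means, sds = [], []
        for seed in range(10):
            spec = FieldGeneratorSpec(target_mean=1500.0, target_sd=400.0,
                                      correlation_length=8.0, seed=seed)
            gp = generate_modulus_field(spec, _grid()).channels["storage_modulus_Pa"]
            means.append(gp.mean())
            sds.append(gp.std())
        assert np.mean(means) == pytest.approx(1500.0, rel=0.02)
        assert np.mean(sds) == pytest.approx(400.0, rel=0.15)

    def test_loss_fraction_and_floor(self):
        spec = FieldGeneratorSpec(target_mean=300.0, target_sd=400.0,
                                  clip_floor=100.0, loss_to_storage_ratio=0.4, seed=2)
        out = generate_modulus_field(spec, _grid())
        gp = out.channels["storage_modulus_Pa"]
        assert gp.min() >= 100.0
        assert np.allclose(out.channels["loss_modulus_Pa"], 0.4 * gp)

    def test_grid_too_small(self):
        with pytest.raises(InvalidSpecError):
            generate_modulus_field(FieldGeneratorSpec(seed=0), _grid(3))

    def test_invalid_specs(self):
        with pytest.raises(InvalidSpecError):
            FieldGeneratorSpec(target_mean=-1.0).validate()
        with pytest.raises(InvalidSpecError):
            FieldGeneratorSpec(correlation_length=0.0).validate()
        with pytest.raises(InvalidSpecError):
            FieldGeneratorSpec(loss_to_storage_ratio=1.5).validate()
        with pytest.raises(InvalidSpecError):
            VoxelField(origin=np.zeros(3), spacing=np.array([1.0, -1.0, 1.0]),
                       dims=(4, 4, 4))


class TestGenerateDtiField:
    def test_isotropic_limit(self):
        out = generate_dti_field(0.05, 0.0, 3, _grid(12))
        d = out.channels["dti_mm2_per_day"]
        # lower-triangular channel order (xx, yx, yy, zx, zy, zz)
        assert np.allclose(d[..., [0, 2, 5]], 0.05)   # diagonal
        assert np.allclose(d[..., [1, 3, 4]], 0.0)    # off-diagonal

    def test_spd_everywhere(self):
        d = generate_dti_field(0.05, 0.5, 4, _grid(12)).channels["dti_mm2_per_day"]
        full = np.zeros(d.shape[:3] + (3, 3))
        tri = ((0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2))
        for c, (i, j) in enumerate(tri):
            full[..., i, j] = d[..., c]
            full[..., j, i] = d[..., c]
        assert np.linalg.eigvalsh(full).min() > 0.0

    def test_trace_target(self):
        traces = []
        for seed in range(10):
            d = generate_dti_field(0.05, 0.5, seed, _grid(12)).channels["dti_mm2_per_day"]
            traces.append(d[..., [0, 2, 5]].sum(axis=-1).mean() / 3.0)
        assert np.mean(traces) == pytest.approx(0.05, rel=0.05)

    def test_invalid_anisotropy(self):
        with pytest.raises(InvalidSpecError):
            generate_dti_field(0.05, 1.0, 0, _grid(8))
        with pytest.raises(InvalidSpecError):
            generate_dti_field(-0.05, 0.3, 0, _grid(8))


class TestEmbedTumorData:
    def _setup(self):
        grid = _grid(16, spacing=4.0)
        seed = TumorSeedSpec(center=np.zeros(3), radius=5.0)
        bbox = np.array([[-20.0, 12.0], [-8.0, 24.0], [0.0, 16.0]])
        return grid, seed, bbox

    def test_constant_preserved(self):
        grid, seed, bbox = self._setup()
        grid.channels["storage_modulus_Pa"] = np.full(grid.dims, 1200.0)
        pts = np.random.default_rng(0).uniform(-4, 4, (50, 3))
        out = embed_tumor_data(grid, "storage_modulus_Pa", bbox, seed, pts)
        assert np.allclose(out, 1200.0)

    def test_linear_field_affine(self):
        grid, seed, bbox = self._setup()
        x = grid.origin[0] + np.arange(grid.dims[0]) * grid.spacing[0]
        grid.channels["storage_modulus_Pa"] = np.broadcast_to(
            x[:, None, None], grid.dims).copy()
        pts = np.array([[-5.0, 0.0, 0.0], [0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        out = embed_tumor_data(grid, "storage_modulus_Pa", bbox, seed, pts)
        # seed cube x in [-5, 5] maps onto bbox x in [-20, 12]
        assert out[0] == pytest.approx(-20.0, abs=1e-9)
        assert out[1] == pytest.approx(-4.0, abs=1e-9)
        assert out[2] == pytest.approx(12.0, abs=1e-9)

    def test_degenerate_bbox(self):
        grid, seed, bbox = self._setup()
        grid.channels["storage_modulus_Pa"] = np.full(grid.dims, 1.0)
        bbox[2] = [3.0, 3.0]
        with pytest.raises(InvalidSpecError):
            embed_tumor_data(grid, "storage_modulus_Pa", bbox, seed,
                             np.zeros((1, 3)))


class TestInterpolateToMesh:
    def test_constant(self):
        grid = _grid(8)
        grid.channels["f"] = np.full(grid.dims, 7.5)
        pts = np.random.default_rng(1).uniform(-5, 5, (40, 3))
        assert np.allclose(interpolate_to_mesh(grid, "f", pts), 7.5)

    def test_linear_exact(self):
        grid = _grid(8)
        idx = np.indices(grid.dims).astype(float)
        x = grid.origin[0] + idx[0] * grid.spacing[0]
        y = grid.origin[1] + idx[1] * grid.spacing[1]
        z = grid.origin[2] + idx[2] * grid.spacing[2]
        grid.channels["f"] = 2 * x + 3 * y - z
        pts = np.random.default_rng(2).uniform(-5, 5, (60, 3))
        out = interpolate_to_mesh(grid, "f", pts)
        expect = 2 * pts[:, 0] + 3 * pts[:, 1] - pts[:, 2]
        assert np.allclose(out, expect, atol=1e-10)

    def test_outside_clamps_to_nearest(self):
        grid = _grid(8)
        idx = np.indices(grid.dims).astype(float)
        grid.channels["f"] = grid.origin[0] + idx[0] * grid.spacing[0]
        hi = grid.origin[0] + (grid.dims[0] - 1) * grid.spacing[0]
        out = interpolate_to_mesh(grid, "f", np.array([[hi + 3.0, 0.0, 0.0]]))
        assert out[0] == pytest.approx(hi, abs=1e-10)

    def test_empty(self):
        grid = _grid(8)
        grid.channels["f"] = np.zeros(grid.dims)
        with pytest.raises(ValueError):
            interpolate_to_mesh(grid, "f", np.zeros((0, 3)))


class TestNiftiRoundTrip:
    def test_round_trip(self, tmp_path):
        spec = FieldGeneratorSpec(seed=5)
        field = generate_modulus_field(spec, _grid(10))
        path = tmp_path / "g.nii.gz"
        write_nifti(field, "storage_modulus_Pa", path)
        back = read_nifti(path, "storage_modulus_Pa")
        assert np.allclose(back.channels["storage_modulus_Pa"],
                           field.channels["storage_modulus_Pa"], rtol=1e-12)
        assert np.allclose(back.origin, field.origin)
        assert np.allclose(back.spacing, field.spacing)
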