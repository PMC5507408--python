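"""Grid DVC: field recovery on phantoms with known imposed displacements,
interpolation, grid strain, and the repeat-scan precision protocol.

Registrations are expensive, so each image pair is registered once per
module and the result shared across assertions.  Recovery errors are
evaluated at well-embedded nodes (data weight >= 0.9), the nodes a grid
DVC reports as measurements.
"""

import numpy as np
import pytest

from microval import dvc
from microval.errors import MicrovalError, OutOfDomainError, ParameterError
from microval.io import GreyVolume
from microval.phantom import FieldSpec, make_field, warp_volume
from conftest import noisy

H = 39.0
NS = 16


@pytest.fixture(scope="module")
def grid(phantom64):
    grey, _, _ = phantom64
    return dvc.GridSpec.cover(grey.shape, NS)


def truth_at_nodes(field, grid):
    pz, py, px = [np.asarray(p) * H for p in grid.node_positions_vox()]
    Z, Y, X = np.meshgrid(pz, py, px, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return field(pts).reshape(tuple(grid.node_counts) + (3,))


def recovery_rms(result, field, grid):
    """RMS nodal error in voxels over well-embedded nodes."""
    weight = result.convergence["node_weight"]
    embedded = weight >= 0.9
    err = (result.u - truth_at_nodes(field, grid)) / H
    return float(np.sqrt((err[embedded] ** 2).sum(axis=-1).mean()))


def register_imposed(phantom64, mask, grid, spec, noise_sigma=0.0, seed=7):
    grey, _, _ = phantom64
    field = make_field(spec, grey.shape, H)
    loaded = warp_volume(grey, field)
    fixed = grey
    if noise_sigma > 0:
        fixed = noisy(grey, noise_sigma, seed)
        loaded = noisy(loaded, noise_sigma, seed + 1)
    return dvc.register(fixed, loaded, mask, grid), field


class TestRegister:
    def test_identical_images_give_zero_field(self, phantom64, phantom64_mask, grid):
        grey, _, _ = phantom64
        res = dvc.register(grey, grey, phantom64_mask, grid)
        assert np.abs(res.u).max() == 0.0
        assert res.convergence["warning"] is None

    def test_integer_translation_recovered_exactly(self, phantom64, phantom64_mask, grid):
        spec = FieldSpec("translation", {"shift": (3 * H, 0.0, 0.0)})
        res, field = register_imposed(phantom64, phantom64_mask, grid, spec)
        assert recovery_rms(res, field, grid) < 0.1
        mean_vox = res.u.reshape(-1, 3).mean(axis=0) / H
        np.testing.assert_allclose(mean_vox, [3.0, 0.0, 0.0], atol=0.1)

    def test_affine_field_recovered(self, phantom64, phantom64_mask, grid):
        spec = FieldSpec(
            "affine", {"matrix": np.diag([0.005, 0.005, -0.02]), "offset": (20.0, -10.0, 5.0)}
        )
        res, field = register_imposed(phantom64, phantom64_mask, grid, spec)
        assert recovery_rms(res, field, grid) < 0.1

    def test_noisy_sinusoidal_field_recovered(self, phantom64, phantom64_mask, grid):
        # amplitude 2 voxels, period 4 NS, grey noise 2% of the bone level
        spec = FieldSpec("sinusoidal", {"amplitude": 2 * H, "period": 4 * NS * H})
        res, field = register_imposed(phantom64, phantom64_mask, grid, spec, noise_sigma=0.02 * 130)
        assert recovery_rms(res, field, grid) < 0.3

    def test_empty_mask_rejected(self, phantom64, grid):
        grey, _, _ = phantom64
        from microval.segmentation import MaskVolume

        bad = MaskVolume(np.ones(grey.shape, np.uint8), H)
        bad.data[:] = 0
        with pytest.raises(MicrovalError):
            dvc.register(grey, grey, bad, grid)

    def test_shape_mismatch_rejected(self, phantom64, phantom64_mask, grid):
        grey, _, _ = phantom64
        smaller = GreyVolume(grey.data[:-1], H)
        with pytest.raises(ParameterError):
            dvc.register(grey, smaller, phantom64_mask, grid)


class TestInterpolateDisplacement:
    @pytest.fixture(scope="class")
    def affine_field(self, grid):
        A = np.array([[0.001, 0.0, 0.0002], [0.0, -0.002, 0.0], [0.0005, 0.0, -0.01]])
        b = np.array([3.0, -1.0, 7.0])
        u = truth_at_nodes(lambda p: p @ A.T + b, grid)
        return dvc.DisplacementGrid(grid, u, H), A, b

    def test_node_value_reproduced_exactly(self, affine_field):
        field, A, b = affine_field
        pos = field.node_positions_um().reshape(-1, 3)
        out = dvc.interpolate_displacement(field, pos[5:6])
        np.testing.assert_allclose(out, field.u.reshape(-1, 3)[5:6], atol=1e-12)

    def test_affine_nodal_field_reproduced_at_interior_points(self, affine_field, rng):
        field, A, b = affine_field
        pts = rng.uniform(100, 2000, (50, 3))
        out = dvc.interpolate_displacement(field, pts)
        np.testing.assert_allclose(out, pts @ A.T + b, atol=1e-9)

    def test_point_outside_grid_rejected(self, affine_field):
        field, _, _ = affine_field
        with pytest.raises(OutOfDomainError):
            dvc.interpolate_displacement(field, np.array([[-500.0, 0.0, 0.0]]))


class TestGridStrain:
    def test_rigid_translation_gives_zero_strain(self, grid):
        u = np.broadcast_to([5.0, -2.0, 1.0], tuple(grid.node_counts) + (3,)).copy()
        strains = dvc.grid_strain(dvc.DisplacementGrid(grid, u, H))
        assert np.abs(strains.eps6).max() < 1e-15

    def test_affine_field_gives_uniform_symmetric_strain(self, grid):
        A = np.array([[0.001, 0.002, 0.0], [0.0, -0.003, 0.001], [0.0, 0.0, -0.01]])
        u = truth_at_nodes(lambda p: p @ A.T, grid)
        strains = dvc.grid_strain(dvc.DisplacementGrid(grid, u, H))
        sym = 0.5 * (A + A.T)
        expected = [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]]
        np.testing.assert_allclose(
            strains.eps6.reshape(-1, 6), np.tile(expected, (strains.eps6.size // 6, 1)), atol=1e-12
        )
        # trace preserved by the principal decomposition
        np.testing.assert_allclose(
            strains.principal.sum(axis=-1), np.trace(sym) * np.ones(strains.principal.shape[:-1]), atol=1e-9
        )

    def test_sinusoidal_strain_error_shrinks_with_nodal_spacing(self):
        # cell-centre strain converges to the analytic derivative as NS halves;
        # the period is chosen incommensurate with the node positions so the
        # sampled field never degenerates to zero
        period = 40 * H
        amp = 2 * H
        w = 2 * np.pi / period

        def field(p):
            u = np.zeros_like(p)
            u[:, 2] = amp * np.sin(w * p[:, 2])
            return u

        errors = []
        for ns in (16, 8, 4):
            grid = dvc.GridSpec.cover((64, 64, 64), ns)
            u = truth_at_nodes(field, grid)
            strains = dvc.grid_strain(dvc.DisplacementGrid(grid, u, H))
            pz = np.asarray(grid.node_positions_vox()[0]) * H
            zc = 0.5 * (pz[:-1] + pz[1:])
            analytic = amp * w * np.cos(w * zc)
            measured = strains.eps6[..., 2]
            err = np.abs(measured - analytic[:, None, None]).max()
            errors.append(err)
        assert errors[0] > errors[1] > errors[2]
        # O(NS^2): halving NS should shrink the error by ~4; demand > 2.5
        assert errors[0] / errors[1] > 2.5


class TestZeroStrainCheck:
    def test_identical_images_have_zero_error(self, phantom64, phantom64_mask, grid):
        grey, _, _ = phantom64
        report = dvc.zero_strain_check(grey, grey, phantom64_mask, grid)
        assert report.displacement_random_error_um == 0.0
        assert report.strain_random_error_ue == 0.0

    def test_repeat_noise_renderings_have_small_random_error(self, phantom64, phantom64_mask, grid):
        grey, _, _ = phantom64
        a = noisy(grey, 0.02 * 130, 31)
        b = noisy(grey, 0.02 * 130, 32)
        report = dvc.zero_strain_check(a, b, phantom64_mask, grid)
        assert report.displacement_random_error_um / H < 0.1

    def test_random_error_decreases_as_spacing_doubles(self, phantom64, phantom64_mask):
        grey, _, _ = phantom64
        a = noisy(grey, 0.02 * 130, 41)
        b = noisy(grey, 0.02 * 130, 42)
        errors = []
        for ns in (8, 16, 32):
            grid = dvc.GridSpec.cover(grey.shape, ns)
            report = dvc.zero_strain_check(a, b, phantom64_mask, grid)
            errors.append(report.displacement_random_error_um)
        assert errors[0] > errors[1] > errors[2]


class TestGridSpec:
    def test_cover_spans_the_volume(self):
        grid = dvc.GridSpec.cover((64, 48, 50), 16)
        for a, n in zip(range(3), (64, 48, 50)):
            top = grid.origin[a] + (grid.node_counts[a] - 1) * grid.nodal_spacing
            assert top >= n

    def test_minimum_spacing_enforced(self):
        with pytest.raises(ParameterError):
            dvc.GridSpec(2, (3, 3, 3))
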