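"""Displacement gradients, strain tensors, principal strains, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import binary_erosion
from scipy.stats import special_ortho_group

import musclestrain4d as m
from musclestrain4d.strain import StrainField, sign_normalize


def random_symmetric(rng, n=1, scale=0.2):
    a = rng.normal(0, scale, (n, 3, 3))
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def tensor_field(tensors):
    """Wrap (n, 3, 3) tensors as a 1x1xn StrainField-compatible grid."""
    return StrainField(tensor=tensors.reshape(1, 1, -1, 3, 3))


class TestDisplacementGradient:
    spacing = (1.875, 1.875, 5.0)

    def coords(self, shape):
        axes = [np.arange(n) * d for n, d in zip(shape, self.spacing)]
        return np.meshgrid(*axes, indexing="ij")

    def test_linear_field_single_entry(self):
        shape = (6, 6, 6)
        x, _, _ = self.coords(shape)
        disp = np.zeros((3,) + shape)
        disp[0] = 0.1 * x
        grad = m.displacement_gradient(disp, self.spacing)
        expected = np.zeros((3, 3))
        expected[0, 0] = 0.1
        assert np.allclose(grad[2:-2, 2:-2, 2:-2], expected, atol=1e-12)

    def test_rigid_translation_gives_zero(self):
        disp = np.full((3, 5, 5, 5), 2.5)
        grad = m.displacement_gradient(disp, self.spacing)
        assert np.abs(grad).max() < 1e-14

    def test_quadratic_exact_at_interior(self):
        """Central differences differentiate quadratics exactly."""
        shape = (7, 5, 5)
        x, _, _ = self.coords(shape)
        disp = np.zeros((3,) + shape)
        disp[0] = x**2
        grad = m.displacement_gradient(disp, self.spacing)
        interior = grad[1:-1, :, :, 0, 0]
        assert np.allclose(interior, 2.0 * x[1:-1], atol=1e-10)

    def test_thin_volume_rejected(self):
        with pytest.raises(ValueError, match="3 voxels"):
            m.displacement_gradient(np.zeros((3, 2, 5, 5)), self.spacing)


class TestStrainTensor:
    def test_symmetric_input_fixed_point(self, rng):
        s = random_symmetric(rng, 5)
        out = m.strain_tensor(s.reshape(1, 1, 5, 3, 3))
        assert np.allclose(out.tensor, s.reshape(1, 1, 5, 3, 3))

    def test_antisymmetric_input_annihilated(self, rng):
        a = rng.normal(0, 1, (3, 3))
        a = a - a.T
        out = m.strain_tensor(a.reshape(1, 1, 1, 3, 3))
        assert np.abs(out.tensor).max() < 1e-15

    def test_off_diagonal_halved(self):
        f = np.zeros((1, 1, 1, 3, 3))
        f[..., 0, 1] = 0.2
        out = m.strain_tensor(f)
        assert out.tensor[0, 0, 0, 0, 1] == pytest.approx(0.1)
        assert out.tensor[0, 0, 0, 1, 0] == pytest.approx(0.1)

    def test_finite_strain_variant(self):
        f = np.zeros((1, 1, 1, 3, 3))
        f[..., 0, 0] = 0.1
        out = m.strain_tensor(f, finite=True)
        # E_xx = F_xx + 0.5 F_xx^2 for a uniaxial displacement gradient
        assert out.tensor[0, 0, 0, 0, 0] == pytest.approx(0.1 + 0.005)


class TestPrincipalStrains:
    def test_diagonal_sorted_ascending(self):
        t = np.diag([0.2, -0.2, 0.01]).reshape(1, 1, 1, 3, 3)
        f = m.principal_strains(StrainField(tensor=t))
        assert np.allclose(f.eigenvalues[0, 0, 0], [-0.2, 0.01, 0.2])

    def test_rotation_preserves_eigenvalues(self, rng):
        lam = np.diag([-0.2, 0.0, 0.2])
        rot = special_ortho_group.rvs(3, size=20, random_state=42)
        tensors = np.einsum("nij,jk,nlk->nil", rot, lam, rot)
        f = m.principal_strains(tensor_field(tensors))
        assert np.allclose(
            f.eigenvalues.reshape(-1, 3), [-0.2, 0.0, 0.2], atol=1e-12
        )

    def test_compression_eigenvector_along_z(self):
        t = np.diag([0.1, 0.1, -0.2]).reshape(1, 1, 1, 3, 3)
        f = m.principal_strains(StrainField(tensor=t))
        v1 = f.eigenvectors[0, 0, 0][:, 0]
        assert np.allclose(np.abs(v1), [0, 0, 1], atol=1e-12)

    def test_eigenvectors_orthonormal(self, rng):
        f = m.principal_strains(tensor_field(random_symmetric(rng, 50)))
        v = f.eigenvectors.reshape(-1, 3, 3)
        gram = np.einsum("nij,nik->njk", v, v)
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_sign_convention_largest_component_nonnegative(self, rng):
        v = rng.normal(0, 1, (100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        fixed = sign_normalize(v)
        largest = np.take_along_axis(
            fixed, np.argmax(np.abs(fixed), axis=1, keepdims=True), axis=1
        )
        assert np.all(largest >= 0)
        assert np.allclose(np.abs(fixed), np.abs(v))


class TestInvariants:
    @pytest.mark.parametrize(
        "diag,expected",
        [
            ((0.05, 0.05, 0.05), 0.0),
            ((-0.2, 0.0, 0.2), (2.0 / 3.0) * np.sqrt(0.24)),
        ],
    )
    def test_max_shear_diagonal_cases(self, diag, expected):
        t = np.diag(diag).reshape(1, 1, 1, 3, 3)
        f = StrainField(tensor=t)
        assert m.max_shear(f)[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_max_shear_pure_shear(self):
        t = np.zeros((1, 1, 1, 3, 3))
        t[..., 0, 1] = t[..., 1, 0] = 0.1
        f = StrainField(tensor=t)
        assert m.max_shear(f)[0, 0, 0] == pytest.approx(
            (2.0 / 3.0) * np.sqrt(0.06), abs=1e-12
        )

    def test_volumetric_strain_is_trace(self):
        t = np.diag([0.01, 0.02, 0.03]).reshape(1, 1, 1, 3, 3)
        f = StrainField(tensor=t)
        assert m.volumetric_strain(f)[0, 0, 0] == pytest.approx(0.06)

    def test_trace_equals_eigenvalue_sum(self, rng):
        f = m.principal_strains(tensor_field(random_symmetric(rng, 200)))
        m.volumetric_strain(f)
        assert np.allclose(
            f.l_vol, f.eigenvalues.sum(axis=-1), atol=1e-12
        )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_max_shear_matches_eigenvalue_form(self, seed):
        """Component formula equals (2/3) sqrt(sum (li - lj)^2) — the
        rotationally invariant eigenvalue form."""
        rng = np.random.default_rng(seed)
        f = m.principal_strains(tensor_field(random_symmetric(rng, 10)))
        m.max_shear(f)
        lam = f.eigenvalues
        eig_form = (2.0 / 3.0) * np.sqrt(
            (lam[..., 0] - lam[..., 1]) ** 2
            + (lam[..., 0] - lam[..., 2]) ** 2
            + (lam[..., 1] - lam[..., 2]) ** 2
        )
        assert np.allclose(f.l_max, eig_form, atol=1e-10)


class TestStrainSeries:
    def test_phantom_recovery_in_agonist_core(self, noiseless_run):
        run = noiseless_run
        f = run["fields"][run["force"].peak_frame]
        core = binary_erosion(run["gt"].labels == 1, iterations=3)
        core &= f.valid_mask
        lam = f.eigenvalues[core]
        assert np.abs(lam[:, 0].mean() + 0.2) < 0.01
        assert np.abs(lam[:, 1]).max() <= 0.02
        assert np.abs(f.l_vol[core]).max() <= 0.02

    def test_rigid_translation_series_strain_free(self):
        from musclestrain4d.kinematics import DisplacementSeries

        disp = np.zeros((4, 3, 6, 6, 6))
        disp[2] = 1.5  # uniform shift
        series = DisplacementSeries(
            displacement=disp, spacing=(1.0, 1.0, 1.0), frame_dt=0.1,
            ref_frame=0, out_of_field=np.zeros((4, 6, 6, 6), bool),
        )
        fields = m.compute_strain_series(series)
        for f in fields:
            assert np.abs(f.tensor).max() < 1e-14

    def test_valid_mask_excludes_border_and_out_of_field(self, noiseless_run):
        f = noiseless_run["fields"][5]
        assert not f.valid_mask[0].any()
        assert not f.valid_mask[:, :, -1].any()
        assert f.valid_mask[5:-5, 5:-5, 5:-5].all()

    def test_recovery_error_monotone_in_phase_noise(self):
        """Same seed, growing noise sigma: the VOI compressive-strain error
        grows monotonically (the noise realization scales with sigma)."""
        import musclestrain4d.voi_stats as vs
        from musclestrain4d.pipeline import phantom_vois

        errors = []
        for sigma in (0.0, 0.05, 0.15):
            spec = m.small_grid_spec(noise_sigma_phase=sigma,
                                     shading_coeffs=(0.0,), seed=11)
            force = m.make_force_trace()
            series, gt = m.synthesize_velocity_series(spec, force)
            fields = m.compute_strain_series(m.track_voxels(series))
            voi = phantom_vois(spec)[0]
            row = vs.extract_voi_indices(fields, voi, force.peak_frame)
            errors.append(abs(row["lambda1"] - 0.2))
        assert errors[0] <= errors[1] <= errors[2]
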