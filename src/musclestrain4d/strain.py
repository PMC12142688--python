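"""Strain tensor fields, principal strains and invariants.

From the tracked displacement field u = (Dx, Dy, Dz) on the reference grid,
the displacement-gradient matrix F_ab = d(Da)/d(b) is computed by central
differences in physical units.  The (small-strain) Lagrangian tensor is its
symmetric part, L = (F + F') / 2, which is diagonalized per voxel; the
eigenvalues are sorted ascending so L_l1 (most negative) is the compression
along the fiber at peak contraction and L_l3 (most positive) the transverse
lengthening.  Two invariants are computed from the tensor components prior to
diagonalization:

    L_max = 2/3 * sqrt((Lxx-Lyy)^2 + (Lxx-Lzz)^2 + (Lyy-Lzz)^2
                       + 6 (Lxy^2 + Lxz^2 + Lyz^2))        (maximum shear)
    L_vol = Lxx + Lyy + Lzz                                (volumetric strain)

L_vol is the fractional volume change and is ~0 for incompressible muscle.
A finite-strain (Green-Lagrange) variant E = (F + F' + F'F) / 2 is available
behind a flag for comparison; the small-strain form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .kinematics import DisplacementSeries

__all__ = [
    "StrainField",
    "displacement_gradient",
    "strain_tensor",
    "principal_strains",
    "max_shear",
    "volumetric_strain",
    "compute_strain_series",
    "sign_normalize",
]


@dataclass
class StrainField:
    """Per-voxel symmetric strain tensor with eigen-structure and invariants.

    ``tensor``: (nx, ny, nz, 3, 3); ``eigenvalues``: (..., 3) ascending;
    ``eigenvectors``: (..., 3, 3) with eigenvector i in [..., :, i], matched
    to eigenvalue i and sign-fixed so the largest-magnitude component is
    non-negative; ``l_max``/``l_vol``: scalar volumes; ``valid_mask``: False
    where the gradient stencil touched the volume border or an out-of-field
    trajectory.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    l_max: np.ndarray | None = None
    l_vol: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.tensor.shape[:3])


def displacement_gradient(
    displacement: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """F_ab = d(displacement_a)/d(b), central differences, (nx, ny, nz, 3, 3).

    ``displacement`` is (3, nx, ny, nz) in mm on the reference grid; entries
    are dimensionless (mm/mm).  One-sided differences are used at volume
    edges; volumes must be at least 3 voxels along each axis.
    """
    displacement = np.asarray(displacement, float)
    if displacement.ndim != 4 or displacement.shape[0] != 3:
        raise ValueError("displacement must be (3, nx, ny, nz)")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")
    if any(n < 3 for n in displacement.shape[1:]):
        raise ValueError("volume must span at least 3 voxels along each axis")
    grad = np.empty(displacement.shape[1:] + (3, 3))
    for a in range(3):
        derivs = np.gradient(displacement[a], *spacing)
        for b in range(3):
            grad[..., a, b] = derivs[b]
    return grad


def strain_tensor(gradient: np.ndarray, finite: bool = False) -> StrainField:
    """Symmetrize the displacement gradient: L = (F + F')/2 per voxel.

    With ``finite=True`` the Green-Lagrange tensor (F + F' + F'F)/2 of the
    displacement gradient is returned instead.
    """
    gradient = np.asarray(gradient, float)
    tensor = 0.5 * (gradient + np.swapaxes(gradient, -1, -2))
    if finite:
        tensor = tensor + 0.5 * np.swapaxes(gradient, -1, -2) @ gradient
    return StrainField(tensor=tensor)


def sign_normalize(vectors: np.ndarray) -> np.ndarray:
    """Flip vector signs so each one's largest-magnitude component is >= 0.

    ``vectors``: (..., 3); eigenvectors are direction lines, so v and -v are
    equivalent and a deterministic representative is chosen.
    """
    v = np.asarray(vectors, float)
    comp = np.take_along_axis(
        v, np.argmax(np.abs(v), axis=-1, keepdims=True), axis=-1
    )[..., 0]
    return v * np.where(comp < 0, -1.0, 1.0)[..., None]


def principal_strains(field: StrainField) -> StrainField:
    """Fill eigenvalues (ascending) and sign-fixed eigenvectors per voxel."""
    w, v = np.linalg.eigh(field.tensor)
    # eigenvector i lives in v[..., :, i]; sign convention per vector
    v = np.swapaxes(sign_normalize(np.swapaxes(v, -1, -2)), -1, -2)
    field.eigenvalues = w
    field.eigenvectors = v
    return field


def max_shear(field: StrainField) -> np.ndarray:
    """Maximum (octahedral-type) shear invariant from the tensor components."""
    t = field.tensor
    xx, yy, zz = t[..., 0, 0], t[..., 1, 1], t[..., 2, 2]
    xy, xz, yz = t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]
    field.l_max = (2.0 / 3.0) * np.sqrt(
        (xx - yy) ** 2 + (xx - zz) ** 2 + (yy - zz) ** 2
        + 6.0 * (xy**2 + xz**2 + yz**2)
    )
    return field.l_max


def volumetric_strain(field: StrainField) -> np.ndarray:
    """Volumetric strain dV/V = Lxx + Lyy + Lzz (trace of the tensor)."""
    field.l_vol = np.trace(field.tensor, axis1=-2, axis2=-1)
    return field.l_vol


def compute_strain_series(
    displacement: DisplacementSeries,
    spacing: tuple[float, float, float] | None = None,
    finite: bool = False,
) -> list[StrainField]:
    """Full strain pipeline per frame: gradient -> tensor -> eigen -> invariants.

    ``valid_mask`` excludes the one-voxel volume border (incomplete central
    stencil) and any voxel whose stencil neighbourhood contains an
    out-of-field trajectory.
    """
    if spacing is None:
        spacing = displacement.spacing
    fields: list[StrainField] = []
    border = np.zeros(displacement.grid_shape, dtype=bool)
    border[1:-1, 1:-1, 1:-1] = True
    for t in range(displacement.n_frames):
        grad = displacement_gradient(displacement.displacement[t], spacing)
        f = strain_tensor(grad, finite=finite)
        principal_strains(f)
        max_shear(f)
        volumetric_strain(f)
        bad = binary_dilation(displacement.out_of_field[t])
        f.valid_mask = border & ~bad
        fields.append(f)
    return fields
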