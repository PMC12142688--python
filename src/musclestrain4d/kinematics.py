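"""Lagrangian voxel tracking through the contraction cycle.

Every reference-grid voxel is advected through the per-frame velocity fields
to obtain its displacement and position in subsequent temporal frames.  The
integrator is explicit forward Euler at the frame period (93.75 ms for a 3 s
cycle of 32 frames); muscle velocities are below a few cm/s, so each step
moves well under a voxel and Euler is adequate — a midpoint (RK2) option is
provided for validation.  Velocity frame t is treated as the mean velocity
over the interval (t-1, t].

Velocities are sampled at the current tracked position by trilinear
interpolation in physical (mm) coordinates, honouring anisotropic voxel
spacing.  Trajectories that leave the volume are clamped to the boundary and
flagged; the flag is sticky (once out, always flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .preproc import VelocitySeries

__all__ = ["DisplacementSeries", "interpolate_velocity", "track_voxels"]

#: velocities are stored in cm/s, positions in mm
CM_PER_S_TO_MM_PER_S = 10.0


@dataclass
class DisplacementSeries:
    """Per-frame displacement of every reference voxel (Lagrangian).

    ``displacement``: (n_frames, 3, nx, ny, nz) in mm on the reference grid;
    ``out_of_field``: (n_frames, nx, ny, nz) sticky flags of trajectories that
    left the volume by that frame.
    """

    displacement: np.ndarray
    spacing: tuple[float, float, float]
    frame_dt: float
    ref_frame: int
    out_of_field: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.displacement.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.displacement.shape[2:])

    def positions(self, frame: int) -> np.ndarray:
        """Tracked coordinates (3, nx, ny, nz) in mm at ``frame``."""
        ref = reference_positions(self.grid_shape, self.spacing)
        return ref + self.displacement[frame]


def reference_positions(
    grid_shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> np.ndarray:
    """Voxel-center coordinates (3, nx, ny, nz) in mm."""
    axes = [np.arange(n) * d for n, d in zip(grid_shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def interpolate_velocity(
    velocity_field: np.ndarray,
    spacing: tuple[float, float, float],
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear sampling of a (3, nx, ny, nz) field at (N, 3) mm coordinates.

    Returns (values (N, 3) in the field's units, outside (N,) bool).  Points
    beyond the volume's bounding box are clamped to the edge for sampling and
    flagged rather than extrapolated.
    """
    points = np.atleast_2d(np.asarray(points, float))
    idx = points / np.asarray(spacing, float)
    shape = np.asarray(velocity_field.shape[1:], float)
    outside = np.any((idx < -1e-9) | (idx > shape - 1 + 1e-9), axis=1)
    coords = np.clip(idx, 0.0, shape - 1).T
    values = np.stack(
        [map_coordinates(velocity_field[c], coords, order=1, mode="nearest")
         for c in range(3)],
        axis=1,
    )
    return values, outside


def track_voxels(
    series: VelocitySeries, ref_frame: int = 0, scheme: str = "euler"
) -> DisplacementSeries:
    """Track every voxel of the reference frame through all temporal frames.

    Forward Euler (or midpoint RK2) through the stored velocity fields;
    displacement(t) = p(t) - p(ref_frame).  Unit bookkeeping (velocity cm/s,
    positions mm, frame_dt s) happens here.
    """
    if not 0 <= ref_frame < series.n_frames:
        raise ValueError("ref_frame out of range")
    if series.frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    if scheme not in ("euler", "rk2"):
        raise ValueError("scheme must be 'euler' or 'rk2'")
    vel = series.velocity
    grid_shape = series.grid_shape
    ref = reference_positions(grid_shape, series.spacing).reshape(3, -1).T
    n_vox = ref.shape[0]
    step_mm = series.frame_dt * CM_PER_S_TO_MM_PER_S

    positions = np.empty((series.n_frames, n_vox, 3))
    out = np.zeros((series.n_frames, n_vox), dtype=bool)
    positions[ref_frame] = ref

    extent = (np.asarray(grid_shape, float) - 1) * np.asarray(series.spacing)

    def advance(p: np.ndarray, field: np.ndarray, sign: float):
        v, flag = interpolate_velocity(field, series.spacing, p)
        if scheme == "rk2":
            mid = p + sign * 0.5 * step_mm * v
            v, flag2 = interpolate_velocity(field, series.spacing, mid)
            flag = flag | flag2
        new = p + sign * step_mm * v
        flag = flag | np.any((new < 0) | (new > extent), axis=1)
        return np.clip(new, 0.0, extent), flag

    for t in range(ref_frame + 1, series.n_frames):
        p, flag = advance(positions[t - 1], vel[t], +1.0)
        positions[t] = p
        out[t] = out[t - 1] | flag
    for t in range(ref_frame, 0, -1):
        # backward pass for a nonzero reference frame: invert the step using
        # the velocity sampled at the later position (first-order accurate)
        p, flag = advance(positions[t], vel[t], -1.0)
        positions[t - 1] = p
        out[t - 1] = out[t] | flag

    displacement = (positions - ref).transpose(0, 2, 1)
    displacement = displacement.reshape((series.n_frames, 3) + grid_shape)
    out_of_field = out.reshape((series.n_frames,) + grid_shape)
    return DisplacementSeries(
        displacement=displacement,
        spacing=series.spacing,
        frame_dt=series.frame_dt,
        ref_frame=ref_frame,
        out_of_field=out_of_field,
    )
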