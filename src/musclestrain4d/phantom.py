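"""Synthetic contracting-muscle phantom with analytic ground truth.

The phantom emulates a velocity-encoded cine acquisition of a thigh during an
isometric contraction cycle: an *agonist* region (quadriceps-like, anterior)
shortens along the fiber axis (z, superior-inferior) while an *antagonist*
region (hamstring-like, posterior) lengthens — the coactivation pattern.  Both
regions deform by a region-wise affine map about their centroid, so the
ground-truth strain tensor is spatially constant inside each region and the
whole pipeline can be validated against a closed form.

Geometry and timing follow a 4D-flow protocol: 3-directional velocity encoding
at VENC 15 cm/s, 32 temporal frames over a 3 s cycle, 1.875 x 1.875 x 5 mm
voxels.  Velocities are encoded into phase (pi <-> VENC) with optional Gaussian
phase noise and a smooth polynomial phase-shading bias; a matched
diffusion-weighted stack with fibers along z is generated for the DTI arm.

Units: coordinates and displacements in mm, velocities in cm/s, time in s,
phase in radians, diffusivities in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import VelocitySeries, shading_basis
from .fiber_dti import DtiVolume

__all__ = [
    "PhantomSpec",
    "ForceTrace",
    "GroundTruth",
    "small_grid_spec",
    "make_force_trace",
    "region_labels",
    "analytic_displacement",
    "synthesize_velocity_series",
    "synthesize_dwi",
    "fibonacci_hemisphere",
]

#: label codes of the two muscle regions
AGONIST, ANTAGONIST = 1, 2


@dataclass
class PhantomSpec:
    """Parameters of the two-region contracting phantom.

    ``peak_strain_agonist`` is the magnitude of the compressive principal
    strain along the fiber axis at peak force; ``transverse_split`` is the
    asymmetry alpha of the transverse expansion (alpha*eps and (1-alpha)*eps),
    which makes the prescribed strain exactly traceless (linearized
    incompressibility).  The default alpha = 0.95 concentrates the expansion
    in one transverse direction, reproducing the in-vivo pattern of a
    compressive and a tensile principal strain of nearly equal magnitude with
    the intermediate one close to zero.  ``coactivation_factor`` scales the
    antagonist's compressive principal-strain magnitude relative to the
    agonist's.
    """

    grid_shape: tuple[int, int, int] = (80, 160, 28)
    spacing: tuple[float, float, float] = (1.875, 1.875, 5.0)
    n_frames: int = 32
    period: float = 3.0
    venc: float = 15.0
    peak_strain_agonist: float = 0.20
    coactivation_factor: float = 0.5
    transverse_split: float = 0.95
    noise_sigma_phase: float = 0.05
    shading_coeffs: tuple[float, ...] = (
        0.0, 0.08, 0.05, -0.06, 0.04, 0.03, 0.02, 0.03, -0.02, 0.02,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.shading_coeffs = tuple(float(c) for c in self.shading_coeffs)
        if len(self.grid_shape) != 3 or any(int(n) < 4 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers >= 4")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.peak_strain_agonist < 0:
            raise ValueError("peak_strain_agonist must be >= 0")
        if not 0.0 < self.transverse_split < 1.0:
            raise ValueError("transverse_split must be in (0, 1)")
        if self.noise_sigma_phase < 0:
            raise ValueError("noise_sigma_phase must be >= 0")

    @property
    def frame_dt(self) -> float:
        return self.period / self.n_frames

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * np.asarray(self.spacing, float)

    def region_center(self, label: int) -> np.ndarray:
        """Centroid of a region in mm (voxel-center coordinates)."""
        ext = self.extent_mm
        y_frac = 0.30 if label == AGONIST else 0.70
        return np.array([0.5 * ext[0], y_frac * ext[1], 0.5 * ext[2]])

    def region_matrix(self, label: int) -> np.ndarray:
        """Displacement-gradient matrix A of a region at peak force.

        Agonist: diag(alpha*eps, (1-alpha)*eps, -eps) — fiber shortening with
        asymmetric transverse expansion, trace exactly zero.  Antagonist:
        -(c/alpha) * A_agonist — fiber lengthening, transverse compression,
        also traceless, with compressive principal strain magnitude c*eps so
        the antagonist/agonist compressive-strain ratio equals c.
        """
        eps = self.peak_strain_agonist
        a = self.transverse_split
        ag = np.diag([a * eps, (1.0 - a) * eps, -eps])
        if label == AGONIST:
            return ag
        if label == ANTAGONIST:
            return -(self.coactivation_factor / a) * ag
        raise ValueError(f"unknown region label {label}")


def small_grid_spec(**overrides) -> PhantomSpec:
    """Fast preset (32 x 64 x 12 voxels) with the full-size voxel spacing."""
    params = dict(grid_shape=(32, 64, 12))
    params.update(overrides)
    return PhantomSpec(**params)


@dataclass
class ForceTrace:
    """Per-frame relative force (fraction of MVC) over one contraction cycle."""

    values: np.ndarray
    pct_mvc: float
    peak_frame: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values[self.peak_frame] != self.values.max():
            raise ValueError("values[peak_frame] must be the maximum")

    @property
    def n_frames(self) -> int:
        return self.values.size

    def activation(self) -> np.ndarray:
        """Force normalized to [0, 1] of the target level."""
        return self.values / self.pct_mvc


def make_force_trace(
    n_frames: int = 32,
    period: float = 3.0,
    pct_mvc: float = 0.30,
    ramp_fraction: float = 0.25,
    peak_frame: int = 20,
    hold_droop: float = 0.02,
) -> ForceTrace:
    """Ramp-hold-release force profile with raised-cosine ramps.

    The hold is given a shallow raised-cosine droop (``hold_droop`` of the
    target, 2% by default) with its unique maximum exactly at ``peak_frame``,
    mimicking a subject tracking a visual force target imperfectly; the trace
    is zero at the first and last frame and attains ``pct_mvc`` at
    ``peak_frame``.
    """
    if not 0.0 < pct_mvc <= 1.0:
        raise ValueError("pct_mvc must be in (0, 1]")
    if not 0.0 < ramp_fraction < 0.5:
        raise ValueError("ramp_fraction must be in (0, 0.5)")
    if not 0.0 <= hold_droop < 1.0:
        raise ValueError("hold_droop must be in [0, 1)")
    n_ramp = int(round(ramp_fraction * n_frames))
    lo, hi = n_ramp, n_frames - 1 - n_ramp
    if not lo <= peak_frame <= hi:
        raise ValueError(
            f"peak_frame {peak_frame} outside the hold plateau [{lo}, {hi}] "
            f"implied by ramp_fraction {ramp_fraction}"
        )
    f = np.arange(n_frames, dtype=float)
    env = np.ones(n_frames)
    up = f < n_ramp
    env[up] = 0.5 * (1.0 - np.cos(np.pi * f[up] / n_ramp))
    down = f > n_frames - 1 - n_ramp
    env[down] = 0.5 * (1.0 - np.cos(np.pi * (n_frames - 1 - f[down]) / n_ramp))
    # shallow tent over the hold, unique max at peak_frame
    half = max(peak_frame - lo, hi - peak_frame, 1)
    s = np.clip((f - peak_frame) / half, -1.0, 1.0)
    droop = (1.0 - hold_droop) + hold_droop * np.cos(0.5 * np.pi * s) ** 2
    values = pct_mvc * env * droop
    values[0] = 0.0
    values[-1] = 0.0
    return ForceTrace(values=values, pct_mvc=pct_mvc, peak_frame=peak_frame)


def region_labels(spec: PhantomSpec) -> np.ndarray:
    """Label volume: 0 background, 1 agonist (anterior), 2 antagonist (posterior).

    Regions are axis-aligned elliptic cylinders along z spanning the central
    80% of the z extent, with in-plane semi-axes 0.30*X and 0.15*Y.
    """
    ext = spec.extent_mm
    x, y, z = coordinate_grids(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    semi = np.array([0.30 * ext[0], 0.15 * ext[1]])
    z_ok = np.abs(z - 0.5 * ext[2]) <= 0.40 * ext[2]
    for label in (AGONIST, ANTAGONIST):
        c = spec.region_center(label)
        r2 = ((x - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2
        labels[(r2 <= 1.0) & z_ok] = label
    return labels


def coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates in mm, one 3D array per axis."""
    axes = [np.arange(n) * d for n, d in zip(spec.grid_shape, spec.spacing)]
    return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass
class GroundTruth:
    """Analytic sidecar of the phantom: labels, displacement and strain."""

    spec: PhantomSpec
    force: ForceTrace
    labels: np.ndarray

    def displacement_field(self, frame: int) -> np.ndarray:
        """Lagrangian displacement (3, nx, ny, nz) in mm at ``frame``."""
        return analytic_displacement(self.spec, self.force, frame, self.labels)

    def strain_tensor(self, label: int, frame: int) -> np.ndarray:
        """Prescribed (constant) strain tensor of a region at ``frame``."""
        g = self.force.activation()[frame]
        a_mat = self.spec.region_matrix(label)
        return g * 0.5 * (a_mat + a_mat.T)

    def fiber_direction(self) -> np.ndarray:
        """Unit fiber-direction field (3, nx, ny, nz); z inside muscle."""
        out = np.zeros((3,) + self.labels.shape)
        out[2][self.labels > 0] = 1.0
        return out


def analytic_displacement(
    spec: PhantomSpec,
    force: ForceTrace,
    frame: int,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Ground-truth Lagrangian displacement u(x) = g(t) A (x - c), mm.

    ``x`` is the reference (frame-0) voxel position; zero in the background.
    """
    if frame >= spec.n_frames:
        raise ValueError("frame out of range")
    if labels is None:
        labels = region_labels(spec)
    g = force.activation()[frame]
    x, y, z = coordinate_grids(spec)
    u = np.zeros((3,) + spec.grid_shape)
    for label in (AGONIST, ANTAGONIST):
        m = labels == label
        c = spec.region_center(label)
        a_mat = spec.region_matrix(label)
        dx = np.stack([x[m] - c[0], y[m] - c[1], z[m] - c[2]])
        um = g * (a_mat @ dx)
        for i in range(3):
            u[i][m] = um[i]
    return u


def _eulerian_velocity(spec: PhantomSpec, force: ForceTrace, frame: int,
                       labels: np.ndarray) -> np.ndarray:
    """Velocity volume (3, nx, ny, nz) in cm/s for the interval (frame-1, frame].

    Phase-contrast MRI measures velocity at the *spatial* position, so the
    emitted field is the incremental Eulerian velocity of the particle
    currently at each voxel: v(y) = dg * A (I + g_prev A)^-1 (y - c) / dt.
    The field is linear in y inside each region, which makes trilinear
    sampling along tracked trajectories exact.
    """
    v = np.zeros((3,) + spec.grid_shape)
    if frame == 0:
        return v
    g = force.activation()
    dg = g[frame] - g[frame - 1]
    x, y, z = coordinate_grids(spec)
    for label in (AGONIST, ANTAGONIST):
        m = labels == label
        c = spec.region_center(label)
        a_mat = spec.region_matrix(label)
        mat = dg * a_mat @ np.linalg.inv(np.eye(3) + g[frame - 1] * a_mat)
        dx = np.stack([x[m] - c[0], y[m] - c[1], z[m] - c[2]])
        vm = (mat @ dx) / spec.frame_dt  # mm/s
        for i in range(3):
            v[i][m] = vm[i] / 10.0  # cm/s
    return v


def synthesize_velocity_series(
    spec: PhantomSpec, force: ForceTrace, rng: np.random.Generator | None = None
) -> tuple[VelocitySeries, GroundTruth]:
    """Forward-model a velocity-encoded cine series of the phantom.

    Velocity maps to phase as phi = pi * v / VENC; Gaussian noise
    (``noise_sigma_phase`` rad) and the polynomial shading bias are added to
    the phase, and the magnitude channel is a labels-derived intensity with
    noise.  Raises if any noiseless velocity reaches VENC (phase wrap would
    corrupt the ground truth).
    """
    if force.n_frames != spec.n_frames:
        raise ValueError("force trace length does not match spec.n_frames")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = region_labels(spec)
    shape = (spec.n_frames, 3) + tuple(spec.grid_shape)
    phase = np.empty(shape)
    for t in range(spec.n_frames):
        v = _eulerian_velocity(spec, force, t, labels)
        vmax = np.abs(v).max()
        if vmax >= spec.venc:
            raise ValueError(
                f"noiseless velocity {vmax:.2f} cm/s reaches VENC {spec.venc}"
            )
        phase[t] = np.pi * v / spec.venc
    basis = shading_basis(spec.grid_shape, order=2)
    coeffs = np.zeros(basis.shape[0])
    coeffs[: len(spec.shading_coeffs)] = spec.shading_coeffs
    shading = np.tensordot(coeffs, basis, axes=1)
    phase += shading  # same bias on each encoding direction
    if spec.noise_sigma_phase > 0:
        phase += rng.normal(0.0, spec.noise_sigma_phase, size=shape)
    base = np.choose(labels, [0.1, 1.0, 0.85])
    magnitude = base[None] + rng.normal(0.0, 0.02, (spec.n_frames,) + base.shape)
    series = VelocitySeries(
        phase=phase,
        magnitude=magnitude,
        venc=spec.venc,
        spacing=tuple(spec.spacing),
        frame_dt=spec.frame_dt,
    )
    return series, GroundTruth(spec=spec, force=force, labels=labels)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the upper hemisphere (fixed table)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = i / n
    r = np.sqrt(1.0 - z**2)
    g = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def synthesize_dwi(
    spec: PhantomSpec,
    b_value: float = 400.0,
    n_directions: int = 30,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    eigenvalues: tuple[float, float, float] = (2.1e-3, 1.6e-3, 1.4e-3),
    directions: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DtiVolume:
    """Diffusion-weighted stack of the phantom (b0 + ``n_directions`` volumes).

    The diffusion tensor is prolate about the fiber axis (z) inside muscle:
    D = diag(lperp2, lperp1, lpar) with ``eigenvalues`` = (lpar, lperp1,
    lperp2) in mm^2/s (design values for muscle, configurable).  Signals
    follow S_i = S0 exp(-b g_i' D g_i) with optional Gaussian noise; SNR is
    ``s0 / noise_sigma``.
    """
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions")
    if directions is None:
        directions = fibonacci_hemisphere(n_directions)
    directions = np.asarray(directions, float)
    if directions.shape != (n_directions, 3):
        raise ValueError("directions must be (n_directions, 3)")
    norms = np.linalg.norm(directions, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("gradient directions must be unit norm")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    labels = region_labels(spec)
    mask = labels > 0
    lpar, lp1, lp2 = eigenvalues
    d_tensor = np.diag([lp2, lp1, lpar])  # fiber along z
    bg = b_value * np.einsum("ij,jk,ik->i", directions, d_tensor, directions)
    signals = np.zeros((n_directions + 1,) + tuple(spec.grid_shape))
    signals[0][mask] = s0
    for i in range(n_directions):
        signals[i + 1][mask] = s0 * np.exp(-bg[i])
    if noise_sigma > 0:
        signals += rng.normal(0.0, noise_sigma, size=signals.shape)
    b_values = np.concatenate([[0.0], np.full(n_directions, b_value)])
    b_vectors = np.concatenate([np.zeros((1, 3)), directions])
    return DtiVolume(signals=signals, b_values=b_values, b_vectors=b_vectors,
                     mask=mask)
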