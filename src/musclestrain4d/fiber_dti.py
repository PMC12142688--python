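"""Diffusion-tensor fitting and muscle-fiber direction extraction.

The diffusion tensor D is fitted per voxel to the log-linearized signal model
log(S_i / S0) = -b_i g_i' D g_i by weighted least squares with weights S_i^2,
S_i predicted from a first-pass ordinary fit (one iteration) — the standard
WLS for the log-transformed model, which restores the correct error
weighting after the log.  Eigenvalues are sorted
DESCENDING (diffusion convention — opposite to the strain module): the lead
eigenvector, associated with the largest diffusivity, is the muscle fiber
direction.  Fractional anisotropy follows the usual normalized eigenvalue
spread.

Signals are clamped at a small positive floor before the log; voxels that
needed clamping are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strain import sign_normalize

__all__ = [
    "DtiVolume",
    "TensorField",
    "fit_dti_wls",
    "fiber_direction_map",
    "mean_dyadic_direction",
    "fractional_anisotropy",
]

#: relative signal floor applied before the log transform
SIGNAL_FLOOR = 1e-6


@dataclass
class DtiVolume:
    """DWI stack: (n_volumes, nx, ny, nz) signals with b-values/b-vectors."""

    signals: np.ndarray
    b_values: np.ndarray
    b_vectors: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, float)
        self.b_values = np.asarray(self.b_values, float)
        self.b_vectors = np.asarray(self.b_vectors, float)
        n = self.signals.shape[0]
        if self.b_values.shape != (n,) or self.b_vectors.shape != (n, 3):
            raise ValueError("b-scheme lengths must match the signal stack")
        dw = self.b_values > 0
        norms = np.linalg.norm(self.b_vectors[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("b-vectors must be unit norm where b > 0")

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[0]


@dataclass
class TensorField:
    """Fitted diffusion tensors with eigen-structure.

    ``d_tensor``: (nx, ny, nz, 3, 3) in mm^2/s; ``eigenvalues``: (..., 3)
    DESCENDING; ``lead_eigenvector``: (..., 3) unit, sign-normalized;
    ``fa``: fractional anisotropy in [0, 1]; ``mask``: fitted voxels;
    ``clamped``: voxels where non-positive signals were floored.
    """

    d_tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lead_eigenvector: np.ndarray
    fa: np.ndarray
    mask: np.ndarray
    clamped: np.ndarray


def _design_matrix(b_values: np.ndarray, b_vectors: np.ndarray) -> np.ndarray:
    """(n, 7) design: [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    g = b_vectors
    cols = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )
    return np.concatenate([np.ones((g.shape[0], 1)), -b_values[:, None] * cols],
                          axis=1)


def _tensor_from_coeffs(d: np.ndarray) -> np.ndarray:
    """(N, 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (N, 3, 3) symmetric."""
    out = np.empty(d.shape[:-1] + (3, 3))
    out[..., 0, 0] = d[..., 0]
    out[..., 1, 1] = d[..., 1]
    out[..., 2, 2] = d[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
    return out


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from (..., 3) eigenvalues, clipped to [0, 1]."""
    lam = np.asarray(eigenvalues, float)
    md = lam.mean(axis=-1, keepdims=True)
    num = ((lam - md) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.clip(np.nan_to_num(fa), 0.0, 1.0)


def fit_dti_wls(dwi: DtiVolume) -> TensorField:
    """Weighted least-squares tensor fit per masked voxel.

    Requires at least 6 non-collinear diffusion directions plus one b=0
    volume; a singular design matrix raises.  Weights are the squared
    (floored) signals.
    """
    if (dwi.b_values == 0).sum() < 1:
        raise ValueError("at least one b=0 volume is required")
    if (dwi.b_values > 0).sum() < 6:
        raise ValueError("at least 6 diffusion-weighted volumes are required")
    design = _design_matrix(dwi.b_values, dwi.b_vectors)
    if np.linalg.matrix_rank(design) < 7:
        raise np.linalg.LinAlgError(
            "singular design matrix: diffusion directions are collinear"
        )
    grid_shape = dwi.signals.shape[1:]
    mask = np.asarray(dwi.mask, bool)
    sig = dwi.signals[:, mask].T  # (N, n_volumes)
    s0 = sig[:, dwi.b_values == 0].mean(axis=1, keepdims=True)
    s0 = np.maximum(s0, np.finfo(float).tiny)
    floor = SIGNAL_FLOOR * s0
    clamped_vox = (sig <= floor).any(axis=1)
    sig = np.maximum(sig, floor)
    y = np.log(sig)
    # first pass: OLS on the log signals to predict noise-free signals
    beta_ols = np.linalg.lstsq(design, y.T, rcond=None)[0].T
    s_pred = np.exp(beta_ols @ design.T)
    w = s_pred**2  # predicted-signal weights, one iteration
    # batched WLS: solve (X' W X) beta = X' W y per voxel
    xtw = design.T[None] * w[:, None, :]  # (N, 7, n)
    lhs = xtw @ design  # (N, 7, 7)
    rhs = np.einsum("npk,nk->np", xtw, y)
    beta = np.linalg.solve(lhs, rhs[..., None])[..., 0]
    tensors = _tensor_from_coeffs(beta[:, 1:])

    w_eig, v_eig = np.linalg.eigh(tensors)
    w_eig = w_eig[:, ::-1]  # descending
    v_eig = v_eig[:, :, ::-1]
    lead = sign_normalize(v_eig[:, :, 0])

    def scatter(values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(grid_shape + values.shape[1:], fill)
        out[mask] = values
        return out

    return TensorField(
        d_tensor=scatter(tensors),
        eigenvalues=scatter(w_eig),
        eigenvectors=scatter(v_eig),
        lead_eigenvector=scatter(lead),
        fa=scatter(fractional_anisotropy(w_eig)),
        mask=mask,
        clamped=scatter(clamped_vox.astype(bool), fill=False).astype(bool),
    )


def fiber_direction_map(tensors: TensorField,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Sign-normalized lead eigenvector per masked voxel, zero elsewhere.

    Voxels flagged as clamped during fitting are excluded from the map.
    """
    if mask is None:
        mask = tensors.mask
    good = np.asarray(mask, bool) & tensors.mask & ~tensors.clamped
    out = np.zeros(tensors.lead_eigenvector.shape)
    out[good] = sign_normalize(tensors.lead_eigenvector[good])
    return out


def mean_dyadic_direction(vectors: np.ndarray,
                          mask: np.ndarray) -> np.ndarray:
    """Mean fiber orientation of a region via the mean dyadic tensor.

    Eigenvector fields are sign-ambiguous, so orientations are averaged as
    <v v'> over the masked voxels; the lead eigenvector of that mean dyadic
    is the region's mean direction.
    """
    v = np.asarray(vectors, float)[np.asarray(mask, bool)]
    if v.size == 0:
        raise ValueError("mask selects no voxels")
    dyad = np.einsum("ni,nj->ij", v, v) / v.shape[0]
    w, vec = np.linalg.eigh(dyad)
    return sign_normalize(vec[:, -1])
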