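"""Directionally-encoded colormaps and strain overlays.

Eigenvector fields (strain compression direction, DTI fiber direction) are
rendered with the directionally-encoded color (DEC) convention standard in
diffusion imaging: red = |x| (medial-lateral), green = |y|
(anterior-posterior), blue = |z| (superior-inferior).  Eigenvectors are
direction lines, so absolute components make v and -v render identically.
The same convention is used for strain and DTI maps so the two are visually
comparable.

Scalar strain maps are alpha-blended over the grayscale magnitude image with
a diverging scale (negative blue, positive red).  Rendering is pure: fixed
inputs give byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

__all__ = ["RgbMap", "eigenvector_colormap", "overlay_on_magnitude"]


@dataclass
class RgbMap:
    """Per-voxel RGB triple in [0, 1]; zero outside ``mask``."""

    rgb: np.ndarray
    source: str
    mask: np.ndarray


def eigenvector_colormap(
    vectors: np.ndarray,
    mask: np.ndarray,
    weight: np.ndarray | None = None,
    source: str = "eigenvector",
) -> RgbMap:
    """DEC colormap (R, G, B) = (|vx|, |vy|, |vz|) inside ``mask``.

    ``vectors`` is (nx, ny, nz, 3) and must be unit norm inside the mask;
    deviations above 1e-6 are renormalized with a warning.  ``weight`` (e.g.
    FA for DTI maps) modulates the brightness and must lie in [0, 1].
    """
    v = np.asarray(vectors, float)
    m = np.asarray(mask, bool)
    if v.shape[-1] != 3 or v.shape[:-1] != m.shape:
        raise ValueError("vectors must be (nx, ny, nz, 3) matching mask")
    norms = np.linalg.norm(v[m], axis=-1)
    if norms.size and np.abs(norms - 1.0).max() > 1e-6:
        warnings.warn("non-unit eigenvectors renormalized", stacklevel=2)
    rgb = np.zeros(v.shape)
    safe = np.where(norms > 0, norms, 1.0)
    rgb[m] = np.abs(v[m]) / safe[:, None]
    if weight is not None:
        w = np.asarray(weight, float)
        if w.shape != m.shape:
            raise ValueError("weight must match the mask geometry")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weight must lie in [0, 1]")
        rgb *= w[..., None]
    rgb[~m] = 0.0
    return RgbMap(rgb=np.clip(rgb, 0.0, 1.0), source=source, mask=m)


def overlay_on_magnitude(
    scalar: np.ndarray,
    magnitude: np.ndarray,
    value_range: tuple[float, float],
    colormap_name: str = "RdBu_r",
    mask: np.ndarray | None = None,
    alpha: float = 0.6,
) -> np.ndarray:
    """Diverging-colormap overlay of a scalar slice on a magnitude slice.

    ``scalar`` and ``magnitude`` are 2D arrays of identical shape; the
    default 'RdBu_r' maps negative values to blue hues and positive to red.
    Values at the neutral midpoint are fully transparent, ramping to
    ``alpha`` at the range ends, so a zero map leaves pure grayscale.
    Returns an (H, W, 3) float image in [0, 1].
    """
    scalar = np.asarray(scalar, float)
    magnitude = np.asarray(magnitude, float)
    if scalar.shape != magnitude.shape:
        raise ValueError("scalar and magnitude geometry mismatch")
    lo, hi = value_range
    if not hi > lo:
        raise ValueError("value_range must be increasing")
    span = magnitude.max() - magnitude.min()
    gray = (magnitude - magnitude.min()) / (span if span > 0 else 1.0)
    base = np.repeat(gray[..., None], 3, axis=-1)
    cmap = colormaps[colormap_name]
    t = np.clip((scalar - lo) / (hi - lo), 0.0, 1.0)
    color = np.asarray(cmap(t))[..., :3]
    # transparency proportional to distance from the neutral midpoint
    a = alpha * np.abs(2.0 * t - 1.0)
    if mask is not None:
        a = a * np.asarray(mask, bool)
    return base * (1.0 - a[..., None]) + color * a[..., None]
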