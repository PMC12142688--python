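"""Shared fixtures: phantom pipeline runs on the fast small-grid preset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import musclestrain4d as m
from musclestrain4d import preproc, voi_stats
from musclestrain4d.pipeline import phantom_vois, preproc_static_mask


@pytest.fixture(scope="session")
def noiseless_run():
    """Noise- and shading-free phantom tracked and strained end to end."""
    spec = m.small_grid_spec(noise_sigma_phase=0.0, shading_coeffs=(0.0,))
    force = m.make_force_trace(n_frames=spec.n_frames, period=spec.period)
    series, gt = m.synthesize_velocity_series(spec, force)
    disp = m.track_voxels(series)
    fields = m.compute_strain_series(disp)
    vois = phantom_vois(spec)
    rows = [
        voi_stats.extract_voi_indices(fields, v, force.peak_frame,
                                      pct_mvc=force.pct_mvc)
        for v in vois
    ]
    return {
        "spec": spec, "force": force, "series": series, "gt": gt,
        "disp": disp, "fields": fields, "vois": vois,
        "table": pd.DataFrame(rows),
    }


@pytest.fixture(scope="session")
def noisy_run():
    """Phantom with phase noise (0.05 rad) and shading, with and without
    denoising, for the noise-robustness checks."""
    spec = m.small_grid_spec()  # default noise 0.05 rad + shading bias
    force = m.make_force_trace(n_frames=spec.n_frames, period=spec.period)
    series, gt = m.synthesize_velocity_series(spec, force)
    static = preproc_static_mask(gt.labels)
    corrected = preproc.correct_series_shading(series, static)
    denoised = preproc.denoise_series(corrected)
    vois = phantom_vois(spec)

    def table_for(s):
        disp = m.track_voxels(s)
        fields = m.compute_strain_series(disp)
        rows = [
            voi_stats.extract_voi_indices(fields, v, force.peak_frame,
                                          pct_mvc=force.pct_mvc)
            for v in vois
        ]
        return fields, pd.DataFrame(rows)

    fields_raw, table_raw = table_for(corrected)
    fields_dn, table_dn = table_for(denoised)
    return {
        "spec": spec, "force": force, "gt": gt, "series": series,
        "corrected": corrected, "denoised": denoised, "vois": vois,
        "fields_raw": fields_raw, "table_raw": table_raw,
        "fields_denoised": fields_dn, "table_denoised": table_dn,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
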