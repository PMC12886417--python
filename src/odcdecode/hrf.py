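"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF: response peak 6 s, undershoot peak 16 s,
    dispersions 1 s, undershoot ratio 1/6, 32 s support."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


def canonical_hrf(dt_s: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sample the canonical HRF on a grid of spacing ``dt_s``.

    The kernel is normalized to unit integral so that convolution with a long
    boxcar plateaus at the boxcar's amplitude (amplitudes keep their units).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, params.duration_s + dt_s / 2, dt_s)
    h = stats.gamma.pdf(t, params.peak_delay_s / params.peak_disp_s,
                        scale=params.peak_disp_s)
    h = h - params.undershoot_ratio * stats.gamma.pdf(
        t, params.undershoot_delay_s / params.undershoot_disp_s,
        scale=params.undershoot_disp_s)
    area = h.sum() * dt_s
    if area <= 0:
        raise ValueError("degenerate HRF parameters")
    return h / area


def convolve_boxcar(boxcar: np.ndarray, dt_s: float,
                    params: HrfParams = HrfParams()) -> np.ndarray:
    """Convolve a condition boxcar (sampled at dt_s) with the canonical HRF,
    truncated to the boxcar's length."""
    h = canonical_hrf(dt_s, params)
    return np.convolve(boxcar, h * dt_s)[: len(boxcar)]
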