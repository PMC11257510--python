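"""Canonical double-gamma hemodynamic response function.

The kernel is the difference of two gamma densities: a positive lobe peaking
~5 s after stimulus onset and a smaller, later undershoot, mixed 6:1. It is
sampled on a fine "microtime" grid (default TR/20 = 0.0625 s) and normalized
to unit integral so that convolving a unit-height boxcar yields a plateau of
height ~1 — amplitudes then read directly in units of the neural signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["HRFKernel", "canonical_hrf", "MICROTIME_DT_S"]

#: default microtime resolution: TR (1.25 s) / 20
MICROTIME_DT_S = 0.0625


@dataclass
class HRFKernel:
    """Sampled HRF kernel with its generating parameters."""

    dt_s: float
    values: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.dt_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt_s


def canonical_hrf(
    dt_s: float = MICROTIME_DT_S,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
    length_s: float = 32.0,
) -> HRFKernel:
    """Canonical double-gamma HRF sampled at ``dt_s``.

    Parameters follow the usual convention: a gamma density with shape
    ``delay/dispersion`` and scale ``dispersion`` for each lobe, the
    undershoot scaled down by ``peak_undershoot_ratio``. The kernel is
    normalized to unit integral.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    for name, v in [
        ("peak_delay", peak_delay),
        ("undershoot_delay", undershoot_delay),
        ("peak_disp", peak_disp),
        ("undershoot_disp", undershoot_disp),
        ("peak_undershoot_ratio", peak_undershoot_ratio),
        ("length_s", length_s),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    t = np.arange(int(round(length_s / dt_s))) * dt_s
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - under / peak_undershoot_ratio
    h = h / (h.sum() * dt_s)
    return HRFKernel(
        dt_s=dt_s,
        values=h,
        params=dict(
            peak_delay=peak_delay,
            undershoot_delay=undershoot_delay,
            peak_disp=peak_disp,
            undershoot_disp=undershoot_disp,
            peak_undershoot_ratio=peak_undershoot_ratio,
            length_s=length_s,
        ),
    )
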