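"""Mode detection in Ks distributions.

Ks distributions from whole-genome homology searches are mixtures of
divergence layers (orthologue split, WGD paralogues, older duplications)
whose components are roughly log-normal, so the kernel density is
estimated on log(Ks) by default; detected modes are reported back on the
Ks scale, ascending.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde


def ks_peak_detect(
    ks_values,
    bandwidth: float | None = None,
    *,
    log_scale: bool = True,
    prominence: float = 0.05,
    grid_size: int = 512,
) -> list[float]:
    """Detect modes of a Ks distribution by kernel density estimation.

    ``bandwidth`` is the KDE factor (Silverman's rule when None);
    ``prominence`` is relative to the highest density value.  Requires at
    least 20 finite positive values.
    """
    x = np.asarray(ks_values, dtype=float)
    x = x[np.isfinite(x)]
    if log_scale:
        x = x[x > 0]
    if x.size < 20:
        raise ValueError(f"need >= 20 finite Ks values, got {x.size}")
    y = np.log(x) if log_scale else x
    if np.ptp(y) == 0:
        return [float(np.exp(y[0])) if log_scale else float(y[0])]
    kde = gaussian_kde(y, bw_method=bandwidth)
    grid = np.linspace(y.min() - 0.5, y.max() + 0.5, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence * dens.max())
    modes = grid[peaks]
    if log_scale:
        modes = np.exp(modes)
    return [float(m) for m in np.sort(modes)]
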