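"""FDR / average-power tradeoff over a grid of p-value thresholds.

For a fixed sample size and effect profile, tabulates the operational FDR
and the average power as a function of the common p-value threshold alpha.
The FDR column uses the Benjamini–Hochberg operational estimate (numerator
pi0 set to 1):

    fdr(alpha) = alpha / (pi0 * alpha + (1 - pi0) * avepow(alpha))

so every row satisfies fdr * (pi0 * alpha + (1 - pi0) * avepow) = alpha
exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import EffectProfile

__all__ = ["default_alpha_grid", "fdr_avepow"]


def default_alpha_grid() -> np.ndarray:
    """Thresholds 0.001, 0.002, ..., 0.100."""
    return np.round(np.arange(1, 101) * 0.001, 10)


def fdr_avepow(n, profile: EffectProfile, alpha_grid=None) -> pd.DataFrame:
    """Tabulate (alpha, fdr, avepow) rows for sample size ``n``.

    Parameters
    ----------
    n : int
        Sample size in the profile family's unit (per group, pairs, events).
    profile : EffectProfile
        Per-feature effects; its null fraction supplies pi0.
    alpha_grid : array-like, optional
        Strictly increasing thresholds in (0, 1); defaults to
        0.001..0.1 in steps of 0.001.

    Returns
    -------
    pandas.DataFrame with columns ``alpha``, ``fdr``, ``avepow``.
    """
    grid = default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("alpha_grid must be a non-empty 1-D array")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("alpha_grid values must lie strictly in (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("alpha_grid must be strictly increasing")

    pi0 = profile.pi0
    avepow = np.array([profile.average_power(n, a) for a in grid])
    fdr = grid / (pi0 * grid + (1.0 - pi0) * avepow)
    return pd.DataFrame({"alpha": grid, "fdr": fdr, "avepow": avepow})
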