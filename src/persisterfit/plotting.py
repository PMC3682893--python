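"""Simple per-curve survival plots (log-scale CFU/ml over time)."""

from __future__ import annotations

import numpy as np

from .inference import FitResult, KillCurve
from .model import total_cfu


def plot_kill_curve(curve: KillCurve, fit: FitResult | None = None, ax=None):
    """Scatter observed concentrations (x/delta) and overlay the fitted model.

    Zero counts are drawn at the per-sample detection floor 1/delta with an
    open marker.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t, x, d = curve.times, curve.counts, curve.deltas
    pos = x > 0
    ax.semilogy(t[pos], x[pos] / d[pos], "o", label="observed")
    if np.any(~pos):
        ax.semilogy(t[~pos], 1.0 / d[~pos], "v", mfc="none", label="below detection")
    if fit is not None and fit.obs_hat is not None:
        tt = np.linspace(0, float(t.max()), 200)
        ax.semilogy(tt, np.maximum(total_cfu(fit.obs_hat, tt), 1e-3), "-", label="fit")
    ax.set_xlabel("time after drug addition (h)")
    ax.set_ylabel("CFU/ml")
    ax.set_title(f"{curve.strain} / {curve.treatment} / {curve.replicate}")
    ax.legend(frameon=False, fontsize=8)
    return ax
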