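"""Plotting helpers: spectrum / signal / heart-rate overlay panels."""

from __future__ import annotations

import numpy as np

from .rpeak import HRSeries
from .tfa import SignalSegment, TFSpectrum


def plot_tf_summary(T: TFSpectrum, signal: SignalSegment,
                    hr_peaks: HRSeries | None = None,
                    hr_ridge: HRSeries | None = None,
                    ax=None, figsize=(10, 8)):
    """Three stacked panels: SSWT spectrum, the signal, overlaid HR series.

    Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=figsize, sharex=True)
    t = signal.times
    extent = [t[0], t[-1], T.bin_centers[0], T.bin_centers[-1]]
    axes[0].imshow(np.abs(T.coeffs), aspect="auto", origin="lower",
                   extent=extent, cmap="magma")
    axes[0].set_ylabel("frequency (Hz)")
    axes[0].set_title("synchrosqueezed spectrum")
    axes[1].plot(t, signal.samples, lw=0.5, color="k")
    axes[1].set_ylabel(signal.label or "signal")
    if hr_ridge is not None:
        axes[2].plot(hr_ridge.times, hr_ridge.values, label="SSWT ridge")
    if hr_peaks is not None:
        axes[2].plot(hr_peaks.times, hr_peaks.values, label="R peaks", alpha=0.8)
    axes[2].set_ylabel("heart rate (Hz)")
    axes[2].set_xlabel("time (s)")
    if hr_ridge is not None or hr_peaks is not None:
        axes[2].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    return fig
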