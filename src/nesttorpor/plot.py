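"""Basic night-trace plotting (unstyled; for inspection, not publication)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import GasTrace, TemperatureTrace
from .solar import SunTimes


def plot_night(
    gas: GasTrace | None = None,
    nest: TemperatureTrace | None = None,
    ambient: TemperatureTrace | None = None,
    sun: SunTimes | None = None,
    path: str | None = None,
):
    """Plot one night's VO2 and temperature traces; shade the night window."""
    n_rows = (gas is not None) + (nest is not None or ambient is not None)
    fig, axes = plt.subplots(max(n_rows, 1), 1, sharex=True, figsize=(9, 3 * max(n_rows, 1)))
    if n_rows <= 1:
        axes = [axes]
    row = 0
    if gas is not None:
        axes[row].plot(gas.frame.index, gas.vo2, lw=0.8, color="k")
        axes[row].set_ylabel("VO2 (ml/min)")
        row += 1
    if nest is not None or ambient is not None:
        if nest is not None:
            axes[row].plot(nest.series.index, nest.series, lw=0.8, label="T_nest")
        if ambient is not None:
            axes[row].plot(ambient.series.index, ambient.series, lw=0.8, label="T_a")
        axes[row].set_ylabel("temperature (degC)")
        axes[row].legend(frameon=False)
    if sun is not None:
        for ax in axes:
            ax.axvspan(sun.sunset, sun.next_sunrise, color="0.85", zorder=0)
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
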