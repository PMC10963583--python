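"""Minimal plotting helpers for the climatology products."""

from __future__ import annotations

import numpy as np


def plot_hour_doy_field(field, ax=None, cmap="RdBu_r", label=""):
    """Heat map of a (24, 365) hour × day-of-year statistic."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    vmax = np.nanmax(np.abs(field))
    im = ax.pcolormesh(np.arange(365), np.arange(24), field,
                       cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xlabel("day of year")
    ax.set_ylabel("hour of day")
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax


def plot_stress_hours(table, ax=None, **bar_kw):
    """Bar chart of annual mean stress hours by month."""
    import matplotlib.pyplot as plt

    from .climatology import MONTH_NAMES

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(MONTH_NAMES, table.by_month, **bar_kw)
    ax.set_ylabel("annual mean stress hours")
    return ax
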