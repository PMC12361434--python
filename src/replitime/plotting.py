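"""Simple RT profile plots."""

from __future__ import annotations

from .genome import Region
from .track import BinnedTrack

__all__ = ["plot_rt_profiles"]


def plot_rt_profiles(
    profiles: dict[str, BinnedTrack],
    region: Region,
    ax=None,
    colors: dict[str, str] | None = None,
):
    """Plot smoothed RT profiles over a region (one line per label).

    Convention follows allele-specific RT figures: deletion allele in
    red, control in black.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    colors = colors or {}
    for label, track in profiles.items():
        sl = track.genome.midpoint_bins(region, track.bin_size)
        y = track.data[region.chrom][sl]
        x = (np.arange(sl.start, sl.stop) + 0.5) * track.bin_size / 1e6
        ax.plot(x, y, label=label, color=colors.get(label))
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.set_xlabel(f"{region.chrom} position (Mb)")
    ax.set_ylabel("RT  log2(E/L)")
    ax.legend(frameon=False)
    return ax
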