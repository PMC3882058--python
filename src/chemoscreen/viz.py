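"""Optional plotting helpers (requires matplotlib)."""

from __future__ import annotations

from typing import Sequence

from .tracking import realign_tracks
from .tracks import Track


def plot_realigned_tracks(tracks: Sequence[Track], ax=None, **kwargs):
    """Overlay all tracks starting from the origin — the conventional
    "rose" plot of chemotaxis assays (+y is the gradient direction)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for t in realign_tracks(tracks):
        ax.plot(t.x, t.y, lw=0.8, **kwargs)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y toward gradient (μm)")
    ax.set_aspect("equal")
    return ax
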