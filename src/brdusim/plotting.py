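"""Thin optional plotting helpers (requires matplotlib)."""

from __future__ import annotations

from .assembly import OverallDistribution


def plot_distribution(dist: OverallDistribution, ax=None, **kwargs):
    """Plot m(x|t): continuous part as a line, atoms as stems."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(dist.grid_x, dist.density, label=f"t = {dist.time:g} d", **kwargs)
    if len(dist.atom_w):
        ax.stem(dist.atom_x, dist.atom_w, linefmt="C1-", markerfmt="C1^", basefmt=" ")
    ax.set_xlabel("label content x")
    ax.set_ylabel("cells per unit label content")
    return ax
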