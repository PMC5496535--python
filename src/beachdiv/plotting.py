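"""Simple species–area curve figures (richness vs cumulative area with CI)."""

from __future__ import annotations

from .change import HistoricalPoint
from .estimation import RarefactionCurve


def plot_curve(
    curve: RarefactionCurve,
    historical: HistoricalPoint | None = None,
    ax=None,
    title: str | None = None,
):
    """Plot one species–area curve with its confidence band.

    The optional historical point is drawn as a marker; its position
    relative to the band is the visual form of the significance rule.
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    df = curve.to_frame()
    for mode, style in (("interpolated", "-"), ("extrapolated", "--")):
        sub = df[df["mode"] == mode]
        if len(sub):
            ax.plot(sub["area_m2"], sub["S"], style, color="C0")
    ax.fill_between(df["area_m2"], df["ci_low"], df["ci_high"],
                    alpha=0.25, color="C0", linewidth=0)
    obs = df[df["mode"] == "observed"]
    if len(obs):
        ax.plot(obs["area_m2"], obs["S"], "o", color="C0")
    if historical is not None:
        ax.plot(historical.A_hist, historical.S_hist, "s", color="C3",
                label="historical")
        ax.legend(frameon=False)
    ax.set_xlabel("cumulative sampled area (m²)")
    ax.set_ylabel("species richness")
    if title:
        ax.set_title(title)
    return ax
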