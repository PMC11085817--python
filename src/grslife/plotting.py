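"""Plotting helpers (optional; matplotlib Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .grs import QUARTILE_LABELS


def plot_bmi_by_quartile(results, ax=None):
    """Boxplot of BMI across GRS quartiles with mean markers.

    ``results`` is a fitted :class:`~grslife.model.GRSLifestyleResults`.
    Returns the matplotlib Axes.
    """
    from .association import build_analysis_frame

    frame = build_analysis_frame(results.scores, results.model.phenotypes)
    data = [frame.loc[frame["quartile"] == q, "bmi"].to_numpy() for q in QUARTILE_LABELS]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=list(QUARTILE_LABELS), showmeans=True)
    ax.set_xlabel("GRS quartile")
    ax.set_ylabel("BMI (kg/m$^2$)")
    ax.set_title("BMI by weighted genetic risk score quartile")
    return ax
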