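"""Radar ("therapeutic fingerprint") plot rendering.

The tested surface is the radar *data* export in :mod:`cdti.composite`; this
module only renders it. One polygon per product over the four axes, safety
shown inverted so larger is better everywhere.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .composite import RADAR_AXES, CdtiScorecard, radar_data

__all__ = ["plot_radar"]

_AXIS_TITLES = {
    "efficacy": "Adjusted efficacy",
    "engagement": "Engagement",
    "evidence_quality": "Evidence quality",
    "inverted_safety": "Safety (1 − penalty)",
}


def plot_radar(scorecards: Iterable[CdtiScorecard], path: str | Path) -> None:
    """Render an overlaid radar plot of one or more scorecards to ``path``."""
    cards = list(scorecards)
    if not cards:
        raise ValueError("at least one scorecard is required")
    n = len(RADAR_AXES)
    angles = [2 * math.pi * i / n for i in range(n)]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    rmax = max(1.0, max(max(radar_data(c)) for c in cards))
    for card in cards:
        values = list(radar_data(card))
        ax.plot(angles + angles[:1], values + values[:1], label=card.product_name)
        ax.fill(angles + angles[:1], values + values[:1], alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels([_AXIS_TITLES[a] for a in RADAR_AXES])
    ax.set_ylim(0, rmax)
    ax.set_title("cDTI therapeutic fingerprint")
    ax.legend(loc="lower right", bbox_to_anchor=(1.2, -0.1))
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
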