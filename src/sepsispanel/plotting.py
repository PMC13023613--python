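"""Minimal plotting: composite score vs SOFA, colored by outcome."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .io import SampleRecord
from .panels import COMPOSITE, PanelScores
from .rules import NON_SURVIVOR, SURVIVOR


def plot_composite_vs_sofa(
    scores: PanelScores,
    records: Iterable[SampleRecord],
    path: str | Path,
    composite_threshold: float = 1.50,
    sofa_threshold: float = 8.0,
) -> None:
    """Scatter of SOFA vs composite with the rule thresholds drawn."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {SURVIVOR: "tab:blue", NON_SURVIVOR: "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for r in records:
        if r.sofa is None or r.sample_id not in scores.values.index:
            continue
        comp = scores.values.at[r.sample_id, COMPOSITE]
        ax.scatter(comp, r.sofa, s=18, color=colors.get(r.outcome, "0.6"),
                   label=r.outcome)
    ax.axvline(composite_threshold, ls="--", lw=0.8, color="k")
    ax.axhline(sofa_threshold, ls="--", lw=0.8, color="k")
    ax.set_xlabel("composite score (NDrG − HLAd)")
    ax.set_ylabel("SOFA score")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
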