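"""Metric-curve plots with data-quality threshold annotations.

Reliability figures conventionally mark .60 (acceptable, red dotted),
.80 (good, black solid) and .90 (excellent, black dotted); effect-size
curves carry no thresholds by default.  The overall estimate is drawn as a
separate annotated point to the right of the trial-count grid.

Determinism contract: the rendered image may differ byte-wise across
matplotlib versions, so each plot writes a JSON sidecar (<path>.json) whose
content is byte-stable for identical inputs and records every plotted
number and threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["Threshold", "RELIABILITY_THRESHOLDS", "plot_metric_curve"]


@dataclass(frozen=True)
class Threshold:
    value: float
    style: str  # matplotlib linestyle/color shorthand, e.g. "r:" or "k-"
    label: str


RELIABILITY_THRESHOLDS = (
    Threshold(0.60, "r:", "acceptable (.60)"),
    Threshold(0.80, "k-", "good (.80)"),
    Threshold(0.90, "k:", "excellent (.90)"),
)


def plot_metric_curve(
    results: Sequence,
    path: str | Path,
    thresholds: Sequence[Threshold] = (),
    ylabel: str = "estimate",
    title: str | None = None,
) -> Path:
    """Plot estimates with CI error bars against trial count.

    ``results`` are ReliabilityResult/EffectSizeResult objects; subsample
    rows form the curve (x = n), the overall row (if any) appears as a
    separate annotated point.  Returns the image path; a ``.json`` sidecar
    records the plotted data.
    """
    rows = [r for res in results for r in res.to_rows()]
    if not rows:
        raise ValueError("nothing to plot: no available results")
    path = Path(path)
    curve = [r for r in rows if r["scope"] == "subsample"]
    overall = [r for r in rows if r["scope"] == "overall"]

    fig, ax = plt.subplots(figsize=(7, 4.5))
    if curve:
        xs = [r["n_trials"] for r in curve]
        ys = [r["estimate"] for r in curve]
        lo = [r["estimate"] - r["ci_low"] for r in curve]
        hi = [r["ci_high"] - r["estimate"] for r in curve]
        ax.errorbar(xs, ys, yerr=[lo, hi], fmt="o-", capsize=3, label="subsample")
    x_over = (max(r["n_trials"] for r in curve) * 1.15 + 1) if curve else 1.0
    for r in overall:
        ax.errorbar(
            [x_over], [r["estimate"]],
            yerr=[[r["estimate"] - r["ci_low"]], [r["ci_high"] - r["estimate"]]],
            fmt="s", capsize=3, color="tab:orange",
        )
        ax.annotate("overall", (x_over, r["estimate"]),
                    textcoords="offset points", xytext=(5, 5))
    for th in thresholds:
        color = {"r": "red", "k": "black"}.get(th.style[:1], th.style[:1])
        ls = {":": ":", "-": "-", "--": "--"}.get(th.style[1:], "--")
        ax.axhline(th.value, color=color, linestyle=ls, linewidth=1, label=th.label)
    ax.set_xlabel("number of trials")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    if thresholds or curve:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    sidecar = {
        "curve": [
            {k: r[k] for k in ("n_trials", "estimate", "ci_low", "ci_high")}
            for r in curve
        ],
        "overall": [
            {k: r[k] for k in ("estimate", "ci_low", "ci_high")} for r in overall
        ],
        "thresholds": [
            {"value": th.value, "style": th.style, "label": th.label}
            for th in thresholds
        ],
    }
    Path(str(path) + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path
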