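"""Publication-style scatter and Bland-Altman figures for paired FFR data."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import bland_altman


def agreement_plots(paired: pd.DataFrame, out_dir: str | Path,
                    threshold: float = 0.80) -> list[Path]:
    """Write a correlation scatter and per-phase Bland-Altman plots.

    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for phase, marker in (("pre", "o"), ("post", "s")):
        sub = paired[paired["phase"] == phase]
        if len(sub):
            ax.scatter(sub["ffr_invasive"], sub["ffr_sim"], s=18,
                       marker=marker, label=f"{phase}-stent")
    ax.axhline(threshold, ls="--", c="grey", lw=0.8)
    ax.axvline(threshold, ls="--", c="grey", lw=0.8)
    ax.plot([0, 1], [0, 1], c="k", lw=0.8)
    ax.set_xlabel("invasive FFR")
    ax.set_ylabel("simulated FFR")
    ax.set_xlim(0.3, 1.02)
    ax.set_ylim(0.3, 1.02)
    ax.legend(frameon=False)
    path = out / "correlation.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    for phase in dict.fromkeys(paired["phase"]):
        sub = paired[paired["phase"] == phase]
        if len(sub) < 2:
            continue
        ba = bland_altman(sub["ffr_invasive"].to_numpy(),
                          sub["ffr_sim"].to_numpy())
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.scatter(ba.means, ba.diffs, s=18)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, ls=style, c="grey", lw=0.9)
        ax.set_xlabel("mean of invasive and simulated FFR")
        ax.set_ylabel("invasive - simulated FFR")
        ax.set_title(f"{phase}-stent: bias {ba.bias:+.3f}, "
                     f"LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]", fontsize=9)
        path = out / f"bland_altman_{phase}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
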