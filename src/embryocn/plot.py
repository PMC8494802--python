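"""Relative haplotype copy-number scatter plots, one panel per blastomere."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_haplotype_cn(
    hap_track: pd.DataFrame,
    path: str | Path,
    chrom: str | None = None,
    samples: list[str] | None = None,
    ylim: tuple[float, float] = (-0.2, 3.2),
) -> None:
    """Per-blastomere scatter of cn_129 (dark) and cn_b6 (light) along the
    genome (or one chromosome)."""
    df = hap_track if chrom is None else hap_track[hap_track["chrom"] == chrom]
    samples = samples or sorted(df["sample"].unique())
    fig, axes = plt.subplots(
        len(samples), 1, figsize=(10, 1.4 * len(samples)), sharex=True, squeeze=False
    )
    for ax, sample in zip(axes[:, 0], samples):
        sub = df[df["sample"] == sample]
        x = (sub["start"] + sub["end"]) / 2e6
        ax.scatter(x, sub["cn_129"], s=4, c="0.25", label="129/SvJae")
        ax.scatter(x, sub["cn_b6"], s=4, c="0.65", label="C57BL/6J")
        ax.set_ylim(*ylim)
        ax.set_ylabel(sample, rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("position (Mb)" + (f" on {chrom}" if chrom else ""))
    axes[0, 0].legend(loc="upper right", fontsize=7, frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
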