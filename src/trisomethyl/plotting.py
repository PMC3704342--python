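"""Figure helpers for the two headline views.

Both functions draw on a provided or fresh matplotlib Axes and return it;
callers save or show.  Kept deliberately small — the tabular outputs are
the primary interface.
"""

from __future__ import annotations

import pandas as pd


def plot_chromosome_profile(profile: pd.DataFrame, ax=None, chrom: str = "chr8"):
    """Median-centered per-group expression along a chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for col, style in (
        ("mean_trisomy8", "-"),
        ("mean_disomy8", "--"),
        ("mean_reference", ":"),
    ):
        ax.plot(profile["position"], profile[col], style, label=col.removeprefix("mean_"))
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel("median-centered log2 expression")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_gene_density(bin_table: pd.DataFrame, chrom: str, ax=None):
    """Per-group mean log2 methylation vs gene count, with the clone-proportion curve."""
    import matplotlib.pyplot as plt

    sub = bin_table[bin_table["chrom"] == chrom].sort_values("gene_count")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for col in [c for c in sub.columns if c.startswith("mean_")]:
        ax.plot(sub["gene_count"], sub[col], marker="o", ms=3,
                label=col.removeprefix("mean_"))
    ax.set_xlabel("genes per BAC clone")
    ax.set_ylabel("mean log2 ratio")
    ax2 = ax.twinx()
    ax2.plot(sub["gene_count"], sub["fraction_of_chrom"], color="black", lw=1,
             label="clone proportion")
    ax2.set_ylabel("proportion of clones")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(chrom)
    return ax
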