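"""Rank-comparison outputs: E-rank vs P-rank scatter and E−P difference bars.

Two views of how the evolutionary adjustment reorders a study's SNPs:

* a scatter with the evolutionarily adjusted rank on x and the raw
  significance rank on y — points below the identity line are SNPs the
  adjustment promoted;
* a bar series of E-rank − P-rank per SNP — negative bars are the SNPs
  whose relative significance the adjustment most enhanced.  Over a
  complete ranked set the series sums to zero (both rankings are
  permutations of 1..N).

The contract is the plot-ready TSV (byte-stable for identical input);
rendered PNG/SVG images are a convenience on top.  Tabulated/plotted views
are capped (default 1000 SNPs) to stay interpretable, preserving the
caller's sort order; bulk export is never capped.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .erank import RankedSNP, rankings_frame

DISPLAY_CAP = 1000

SCATTER_COLUMNS = ["rsid", "e_rank_ordinal", "p_rank", "e_score", "p_value"]
DIFF_COLUMNS = ["rsid", "p_rank", "e_rank_ordinal", "rank_diff", "e_score"]


def erank_vs_prank(ranked: Sequence[RankedSNP]) -> pd.DataFrame:
    """Scatter data: x = E-rank ordinal, y = P-rank, one point per SNP.

    The extra columns replicate the hover payload (rsid plus plotted
    values).  The identity line x = y is the no-adjustment reference; it is
    recorded in ``DataFrame.attrs["identity_line"]``.
    """
    if not ranked:
        raise ValueError("empty ranked set")
    df = rankings_frame(ranked)[SCATTER_COLUMNS].copy()
    df.attrs["identity_line"] = True
    df.attrs["x"] = "e_rank_ordinal"
    df.attrs["y"] = "p_rank"
    return df


def erank_minus_prank(
    ranked: Sequence[RankedSNP], order: str = "by_p_rank"
) -> pd.DataFrame:
    """Bar series of rank_diff per SNP.

    ``order`` is ``by_p_rank`` (bars in raw-significance order) or
    ``by_rank_diff`` (most-promoted SNPs first).
    """
    if not ranked:
        raise ValueError("empty ranked set")
    df = rankings_frame(ranked)[DIFF_COLUMNS].copy()
    if order == "by_p_rank":
        df = df.sort_values("p_rank", kind="stable")
    elif order == "by_rank_diff":
        df = df.sort_values(["rank_diff", "rsid"], kind="stable")
    else:
        raise ValueError(f"order must be by_p_rank or by_rank_diff, got {order!r}")
    return df.reset_index(drop=True)


def cap_for_display(
    table: pd.DataFrame, limit: int = DISPLAY_CAP
) -> tuple[pd.DataFrame, bool]:
    """First *limit* rows in the current order, plus a truncation flag.

    Sort first to choose what survives the cap; use the full table for bulk
    CSV export.
    """
    if limit < 1:
        raise ValueError(f"display cap must be ≥ 1, got {limit}")
    truncated = len(table) > limit
    return table.head(limit).reset_index(drop=True), truncated


def to_plot_tsv(df: pd.DataFrame) -> str:
    """Byte-stable TSV of plot data (floats at 10 significant digits)."""
    return df.to_csv(sep="\t", index=False, float_format="%.10g")


def render_scatter(df: pd.DataFrame, path: str) -> None:
    """Render the E-rank vs P-rank scatter to *path* (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df["e_rank_ordinal"], df["p_rank"], s=12, alpha=0.7)
    n = max(df["e_rank_ordinal"].max(), df["p_rank"].max())
    ax.plot([1, n], [1, n], color="grey", lw=0.8, ls="--", label="identity")
    ax.set_xlabel("E-rank (evolutionarily adjusted)")
    ax.set_ylabel("P-rank (raw significance)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_bars(df: pd.DataFrame, path: str) -> None:
    """Render the E-rank − P-rank bar series to *path* (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(5, len(df) * 0.12), 4))
    colors = ["#2166ac" if d < 0 else "#b2182b" for d in df["rank_diff"]]
    ax.bar(range(len(df)), df["rank_diff"], color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["rsid"], rotation=90, fontsize=6)
    ax.set_ylabel("E-rank − P-rank")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
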