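"""Advisory figures summarising a study run (CSVs are the tested surface)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

MORPH_COLOURS = {"orange": "#e06a10", "pink": "#e8a0c0"}


def make_figures(summary: pd.DataFrame, out_dir) -> None:
    out = Path(out_dir) / "figures"
    out.mkdir(exist_ok=True)
    _counts_figure(summary, out / "counts.png")
    _pd_figure(summary, out / "gof_pd.png")
    _dispersal_figure(summary, out / "dispersal.png")


def _counts_figure(summary: pd.DataFrame, path) -> None:
    pivot = summary.pivot_table(
        index="site_id", columns="morph", values="count", aggfunc="sum", fill_value=0
    )
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(pivot)), 3))
    bottom = None
    for morph in pivot.columns:
        ax.bar(pivot.index, pivot[morph], bottom=bottom,
               color=MORPH_COLOURS.get(morph, "grey"), label=morph)
        bottom = pivot[morph] if bottom is None else bottom + pivot[morph]
    ax.set_ylabel("corals per site")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _pd_figure(summary: pd.DataFrame, path) -> None:
    cols = [c for c in ("pd_csr", "pd_hp", "pd_tc_10", "pd_htc") if c in summary]
    fig, ax = plt.subplots(figsize=(5, 3))
    data = [summary[c].dropna() for c in cols]
    data = [d for d in data if len(d)]
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(data) + 1))
        ax.set_xticklabels([c.replace("pd_", "").upper() for c in cols][: len(data)])
    ax.set_ylabel(r"Diggle $p_d$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _dispersal_figure(summary: pd.DataFrame, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    for ax, col, label in (
        (axes[0], "offspring_nonempty", "offspring per parent (non-empty cluster)"),
        (axes[1], "nn_median_cm", "site median NN distance (cm)"),
    ):
        if col not in summary:
            continue
        for i, group in enumerate(("O", "P", "M")):
            for morph in ("orange", "pink"):
                vals = summary.query("group == @group and morph == @morph")[col].dropna()
                if len(vals):
                    x = [i + (-0.12 if morph == "orange" else 0.12)] * len(vals)
                    ax.plot(x, vals, "o", ms=4, alpha=0.7, color=MORPH_COLOURS[morph])
        ax.set_xticks(range(3))
        ax.set_xticklabels(["O", "P", "M"])
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
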