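"""Static summary plots (matplotlib, Agg backend).

One PNG per summary, mirroring the usual cohort-overview panels: totals
bar chart, replicate-overlap region counts, substitution-spectrum bars,
indel-length histogram, feature stacked bars, driver-gene bars and
signature profiles. Replicate overlap is drawn as a labelled region-count
bar chart rather than a proportional Venn layout.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def _save(fig, path: str | Path) -> None:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_totals(df: pd.DataFrame, path: str | Path) -> None:
    sub = df[df["category"] == "total"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(sub["sample"], sub["count"], color="steelblue")
    ax.set_ylabel("variants")
    ax.set_title("Total variants per sample")
    ax.tick_params(axis="x", rotation=45)
    _save(fig, path)


def plot_overlap(df: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(df["subset"], df["count"], color="darkseagreen")
    ax.set_ylabel("exclusive variant keys")
    ax.set_title(f"Replicate overlap regions ({df['group'].iloc[0]})")
    ax.tick_params(axis="x", rotation=60)
    _save(fig, path)


def plot_spectrum(df: pd.DataFrame, path: str | Path) -> None:
    wide = df.pivot(index="category", columns="sample", values="frequency")
    fig, ax = plt.subplots(figsize=(7, 4))
    wide.plot.bar(ax=ax)
    ax.set_ylabel("frequency of SNVs")
    ax.set_title("Base substitution spectrum")
    ax.legend(fontsize=6, ncol=2)
    _save(fig, path)


def plot_indels(df: pd.DataFrame, path: str | Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, itype in zip(axes, ("INSERTION", "DELETION")):
        sub = df[df["indel_type"] == itype]
        wide = sub.pivot(index="category", columns="sample", values="frequency")
        wide.plot.bar(ax=ax, legend=False)
        ax.set_title(itype.lower() + "s")
        ax.set_xlabel("length (bp)")
    axes[0].set_ylabel("frequency")
    _save(fig, path)


def plot_features(df: pd.DataFrame, path: str | Path) -> None:
    wide = df.pivot(index="sample", columns="category", values="frequency")
    fig, ax = plt.subplots(figsize=(7, 4))
    wide.plot.bar(stacked=True, ax=ax, colormap="tab20")
    ax.set_ylabel("fraction of variants")
    ax.set_title("Genomic feature distribution")
    ax.legend(fontsize=6, ncol=2)
    _save(fig, path)


def plot_drivers(totals: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(totals["sample"], totals["count"], color="indianred")
    ax.set_ylabel("variants in driver genes")
    ax.set_title("Driver-gene variant load")
    ax.tick_params(axis="x", rotation=45)
    _save(fig, path)


def plot_signatures(sigs: pd.DataFrame, path: str | Path) -> None:
    k = sigs.shape[1]
    fig, axes = plt.subplots(k, 1, figsize=(10, 1.8 * k), sharex=True, squeeze=False)
    for ax, name in zip(axes[:, 0], sigs.columns):
        ax.bar(range(96), sigs[name], width=0.8)
        ax.set_ylabel(name, fontsize=7)
        ax.tick_params(labelsize=5)
    axes[-1, 0].set_xticks(range(0, 96, 16))
    axes[-1, 0].set_xticklabels([sigs.index[i] for i in range(0, 96, 16)], fontsize=5)
    _save(fig, path)
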