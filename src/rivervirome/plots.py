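"""Optional figures: family heatmap, rarefaction curves, PCoA, top species."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def family_heatmap(profile, path) -> None:
    """log10(1+count) heatmap of the family profile."""
    counts = profile.drop_reserved().counts
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * len(counts.columns))))
    im = ax.imshow(np.log10(1 + counts.values.T), aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(len(counts.index)), counts.index, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(counts.columns)), counts.columns, fontsize=7)
    fig.colorbar(im, ax=ax, label="log10(1 + reads)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rarefaction_plot(curves: dict[str, list[tuple[int, float]]], path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, curve in sorted(curves.items()):
        xs = [d for d, _ in curve]
        ys = [s for _, s in curve]
        ax.plot(xs, ys, label=lab)
    ax.set_xlabel("reads sampled")
    ax.set_ylabel("expected species")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pcoa_plot(pcoa_result, path) -> None:
    coords = pcoa_result.coordinates
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = coords.iloc[:, 0]
    ys = coords.iloc[:, 1] if coords.shape[1] > 1 else 0 * xs
    ax.scatter(xs, ys)
    for lab, x, y in zip(coords.index, xs, ys):
        ax.annotate(lab, (x, y), fontsize=8)
    pe = pcoa_result.proportion_explained
    ax.set_xlabel(f"PCo1 ({100 * pe[0]:.1f}%)" if len(pe) else "PCo1")
    if len(pe) > 1:
        ax.set_ylabel(f"PCo2 ({100 * pe[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def top_species_bars(top10: dict, path) -> None:
    n = len(top10)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    for ax, (lab, df) in zip(axes.ravel(), sorted(top10.items())):
        if len(df):
            ax.barh(df["species"][::-1], df["relative_abundance"][::-1])
        ax.set_title(lab, fontsize=9)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
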