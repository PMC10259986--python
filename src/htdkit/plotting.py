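"""Minimal plots: PCA biplot, isotherm, simulated spectrum."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_biplot", "plot_isotherm", "plot_spectrum"]


def plot_biplot(pca, panel, path, scale: float = 2.5):
    """2D biplot of PC1/PC2 scores (colored by class) and variable loadings."""
    fig, ax = plt.subplots(figsize=(6, 6))
    scores = pca.scores[["PC1", "PC2"]]
    if panel.class_labels is not None:
        for cls, sub in scores.groupby(panel.class_labels):
            ax.scatter(sub["PC1"], sub["PC2"], label=cls, s=40)
        ax.legend(fontsize=8)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=40)
    for var, row in pca.loadings[["PC1", "PC2"]].iterrows():
        ax.annotate(
            "", xy=(scale * row.PC1, scale * row.PC2), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="steelblue", lw=1.2),
        )
        ax.text(scale * row.PC1 * 1.08, scale * row.PC2 * 1.08, var,
                fontsize=7, color="steelblue", ha="center")
    vf = pca.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}%)")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_isotherm(isotherm, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(isotherm.molar_ratio, isotherm.normalized_heats, "o-", ms=4)
    ax.set_xlabel("molar ratio")
    ax.set_ylabel("kcal/mol of injectant")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_spectrum(spectrum, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(spectrum.frequency_grid, spectrum.intensity, lw=1)
    ax.set_xlabel("offset (Hz)")
    ax.set_ylabel("intensity (a.u.)")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
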