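"""Matplotlib renderings of the standard outputs: score plot with Hotelling
ellipses, correlation-coded loading pseudo-spectrum, S-plot, permutation
histogram and the pathway bubble plot. All functions save to a file and
return the path; axes follow NMR convention (ppm decreasing left to right)
where relevant."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .chemo import PlsdaModel, hotelling_ellipse


def score_plot(model: PlsdaModel, labels, path: str, alpha: float = 0.05) -> str:
    fig, ax = plt.subplots(figsize=(5, 4))
    T = model.scores
    if T.shape[1] < 2:
        T = np.column_stack([T[:, 0], np.zeros(T.shape[0])])
    labels = np.asarray(labels)
    for g in pd.unique(labels):
        sub = T[labels == g]
        ax.scatter(sub[:, 0], sub[:, 1], label=str(g))
        if sub.shape[0] > 3 and np.ptp(sub[:, 1]) > 0:
            ex, ey = hotelling_ellipse(sub[:, :2], alpha=alpha)
            ax.plot(ex, ey, lw=0.8)
    ax.set_xlabel("t[1]")
    ax.set_ylabel("t[2]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def loading_pseudospectrum(df: pd.DataFrame, path: str) -> str:
    """``df`` from :func:`wormetab.chemo.correlation_loading_plot`."""
    fig, ax = plt.subplots(figsize=(8, 3))
    sc = ax.scatter(df.ppm, df.covariance, c=df.abs_correlation,
                    cmap="coolwarm", s=6, vmin=0, vmax=1)
    fig.colorbar(sc, label="|r|")
    ax.invert_xaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("covariance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def s_plot(df: pd.DataFrame, path: str) -> str:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(df.covariance, df.correlation, s=8)
    ax.set_xlabel("cov(t1, X)")
    ax.set_ylabel("corr(t1, X)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def permutation_histogram(null_stats, observed: float, path: str) -> str:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(null_stats), bins=40, color="0.7")
    ax.axvline(observed, color="red")
    ax.annotate("observed", (observed, ax.get_ylim()[1] * 0.9), color="red",
                ha="right")
    ax.set_xlabel("permutation Q2Y")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def pathway_bubble_plot(pw: pd.DataFrame, path: str) -> str:
    """``pw`` from :func:`wormetab.pathway.metpa`: x = impact,
    y = -log10 raw p, area proportional to impact, color by p."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(pw.impact, pw.neg_log10_p, s=100 + 900 * pw.impact,
               c=pw.raw_p, cmap="Reds_r", edgecolors="k", alpha=0.85)
    for _, r in pw.iterrows():
        ax.annotate(r.pathway, (r.impact, r.neg_log10_p), fontsize=6,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("pathway impact")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
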