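"""Rendering helpers: morphospace scatter, allometry scatter, and
visual-field diagrams, written as deterministic SVG."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .allometry import AllometryFit
from .morphospace import OccupancyReport, PCAResult
from .vision import HeadLayout, ScenarioResult, stylet_zone

_GROUP_COLORS = {"extant": "tab:blue", "fossil": "tab:orange", "new": "tab:red"}

# deterministic SVG ids so repeated runs are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "stemmorph"
_SVG_META = {"Date": None}


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, metadata=_SVG_META)
    plt.close(fig)


def plot_morphospace(pca: PCAResult, report: OccupancyReport,
                     path: str | Path, axes: tuple[int, int] = (0, 1)) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    pts = pca.scores[:, list(axes)]
    for g in dict.fromkeys(pca.groups):
        idx = [i for i, gi in enumerate(pca.groups) if gi == g]
        ax.scatter(pts[idx, 0], pts[idx, 1], s=18,
                   color=_GROUP_COLORS.get(g, "gray"), label=g)
        hull = report.hulls.get(g)
        if hull is not None and not hull.degenerate:
            closed = np.vstack([hull.vertices, hull.vertices[:1]])
            ax.plot(closed[:, 0], closed[:, 1], "-",
                    color=_GROUP_COLORS.get(g, "gray"), alpha=0.6)
    i, j = axes
    vf = pca.variance_fraction
    ax.set_xlabel(f"PC{i + 1} ({100 * vf[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * vf[j]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    _save(fig, path)


def plot_allometry(fit: AllometryFit, head_lengths, lens_diameters, groups,
                   path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    head_lengths = np.asarray(head_lengths, float)
    for g in dict.fromkeys(groups):
        idx = [i for i, gi in enumerate(groups) if gi == g]
        ax.scatter(head_lengths[idx], np.asarray(lens_diameters, float)[idx],
                   s=18, color=_GROUP_COLORS.get(g, "gray"), label=g)
    grid = np.geomspace(head_lengths.min(), head_lengths.max(), 50)
    ax.plot(grid, 10.0 ** (fit.intercept + fit.slope * np.log10(grid)),
            "k-", lw=1, label=f"slope {fit.slope:.2f}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("head length")
    ax.set_ylabel("largest lens diameter")
    ax.legend()
    fig.tight_layout()
    _save(fig, path)


def plot_scenario(layout: HeadLayout, result: ScenarioResult,
                  path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 6))
    head = np.asarray(layout.head_polygon + (layout.head_polygon[0],))
    ax.plot(head[:, 0], head[:, 1], "k-", lw=1.5)
    zone = stylet_zone(layout)
    zx, zy = zone.exterior.xy
    ax.fill(zx, zy, alpha=0.15, color="tab:green", label="stylet zone")
    for field, color in ((result.left, "tab:blue"), (result.right, "tab:orange")):
        if not field.polygon.is_empty:
            fx, fy = field.polygon.exterior.xy
            ax.fill(fx, fy, alpha=0.15, color=color)
    if not result.binocular.region.is_empty:
        bx, by = result.binocular.region.exterior.xy
        ax.fill(bx, by, alpha=0.35, color="tab:red", label="binocular")
    ax.set_aspect("equal")
    lim = 3.0 * layout.head_length
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-1.5 * layout.head_length, 2 * lim)
    ax.set_title(f"{result.scenario} / {result.mode}: {result.relation}"
                 f"{'' if result.feasible else ' (infeasible)'}")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    _save(fig, path)
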