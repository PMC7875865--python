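"""Per-state 2D density maps and fixation heatmaps.

Densities are Gaussian-kernel sums evaluated on a regular pixel grid using the
separable-kernel factorisation (grid = Ey^T Ex with per-axis kernel matrices),
normalised to sum to one whenever any fixation contributes. Rendering draws
contour/alpha overlays of the per-state maps with AOI outlines; it never
mutates the numeric grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import AOISet, FixationSequence

DEFAULT_BANDWIDTH = 30.0  # px
DEFAULT_GRID_STEP = 4.0   # px


@dataclass
class DensityGrid:
    """A normalised kernel-density map on the canvas for one state (or pooled)."""

    state: int | str
    grid: np.ndarray  # (H, W), rows = y
    bandwidth: float
    grid_step: float
    empty: bool = False

    @property
    def extent(self) -> tuple[float, float, float, float]:
        h, w = self.grid.shape
        return (0.0, w * self.grid_step, h * self.grid_step, 0.0)


def _grid_axes(canvas: tuple[float, float], step: float) -> tuple[np.ndarray, np.ndarray]:
    w, h = canvas
    gx = np.arange(0.0, w + step / 2, step)
    gy = np.arange(0.0, h + step / 2, step)
    return gx, gy


def _kernel_grid(
    xy: np.ndarray,
    canvas: tuple[float, float],
    bandwidth: float,
    step: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    gx, gy = _grid_axes(canvas, step)
    if len(xy) == 0:
        return np.zeros((len(gy), len(gx)))
    ex = np.exp(-0.5 * ((gx[None, :] - xy[:, 0][:, None]) / bandwidth) ** 2)
    ey = np.exp(-0.5 * ((gy[None, :] - xy[:, 1][:, None]) / bandwidth) ** 2)
    if weights is not None:
        ey = ey * np.asarray(weights, dtype=float)[:, None]
    grid = ey.T @ ex
    total = grid.sum()
    return grid / total if total > 0 else grid


def state_density_map(
    assignment: pd.DataFrame,
    canvas: tuple[float, float],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: float = DEFAULT_GRID_STEP,
    n_states: int | None = None,
) -> dict[int, DensityGrid]:
    """One normalised density per hidden state from that state's fixations.

    States with no fixations yield an all-zero grid flagged empty.
    """
    n = int(n_states if n_states is not None else assignment["state"].max() + 1)
    out = {}
    for s in range(n):
        block = assignment[assignment["state"] == s]
        xy = block[["x", "y"]].to_numpy(dtype=float)
        grid = _kernel_grid(xy, canvas, bandwidth, grid_step)
        out[s] = DensityGrid(
            state=s, grid=grid, bandwidth=bandwidth, grid_step=grid_step, empty=len(xy) == 0
        )
    return out


def fixation_heatmap(
    sequences: list[FixationSequence],
    canvas: tuple[float, float],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: float = DEFAULT_GRID_STEP,
    weight_by_duration: bool = False,
) -> DensityGrid:
    """Pooled density over all fixations, optionally duration-weighted."""
    xy = np.concatenate([s.xy for s in sequences], axis=0)
    weights = (
        np.concatenate([s.durations for s in sequences]) if weight_by_duration else None
    )
    grid = _kernel_grid(xy, canvas, bandwidth, grid_step, weights=weights)
    return DensityGrid(
        state="all", grid=grid, bandwidth=bandwidth, grid_step=grid_step, empty=len(xy) == 0
    )


def relative_onset_by_state(
    assignment: pd.DataFrame, sequences: list[FixationSequence]
) -> dict[int, float]:
    """Mean normalised fixation onset per state (onset / subject task duration).

    An approximation of coloring states by their relative time of attendance.
    """
    rel = []
    for seq in sequences:
        total = seq.onsets[-1] + seq.durations[-1]
        for r, onset in zip(seq.records, seq.onsets):
            rel.append(
                {"subject_id": seq.subject_id, "image_id": seq.image_id,
                 "fixation_index": r.fixation_index, "rel_onset": onset / total}
            )
    merged = assignment.merge(pd.DataFrame(rel), on=["subject_id", "image_id", "fixation_index"])
    return merged.groupby("state")["rel_onset"].mean().to_dict()


def render_overlays(
    grids: dict[int, DensityGrid] | list[DensityGrid],
    aoiset: AOISet,
    output_path,
    cmap: str = "viridis",
    dpi: int = 100,
) -> str:
    """Render per-state density contours with AOI outlines to a PNG.

    Output is deterministic: identical inputs produce byte-identical files.
    """
    if isinstance(grids, dict):
        grids = [grids[k] for k in sorted(grids)]
    fig, ax = plt.subplots(figsize=(9.6, 6.0))
    colors = plt.get_cmap("tab10")
    handles, labels = [], []
    for i, g in enumerate(grids):
        color = colors(i % 10)
        name = f"state {g.state}"
        if g.empty:
            labels.append(f"{name} (empty)")
            handles.append(plt.Line2D([], [], color=color, linestyle=":"))
            continue
        gx, gy = _grid_axes((aoiset.canvas_width, aoiset.canvas_height), g.grid_step)
        levels = np.quantile(g.grid[g.grid > 0], [0.85, 0.95, 0.99])
        levels = np.unique(levels)
        if len(levels) >= 2:
            ax.contour(gx, gy, g.grid, levels=levels, colors=[color], linewidths=1.0)
        labels.append(name)
        handles.append(plt.Line2D([], [], color=color))
    for region in aoiset.regions:
        poly = np.vstack([region.polygon, region.polygon[:1]])
        ax.plot(poly[:, 0], poly[:, 1], color="black", linewidth=0.8)
        ax.annotate(region.label, region.center, fontsize=8, ha="center")
    ax.set_xlim(0, aoiset.canvas_width)
    ax.set_ylim(aoiset.canvas_height, 0)  # screen convention: y down
    ax.set_aspect("equal")
    ax.legend(handles, labels, fontsize=7, loc="upper left", framealpha=0.8)
    ax.set_title(f"hidden-state densities — {aoiset.image_id}")
    fig.savefig(output_path, dpi=dpi, metadata={"Software": "gazehmm"})
    plt.close(fig)
    return str(output_path)


def grid_to_csv(grid: DensityGrid, path) -> None:
    np.savetxt(path, grid.grid, delimiter=",")
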