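"""Render per-chain scalar profiles into smoothed 2D surface maps.

The surface matrix doubles the grafting lattice: chain values sit at
even-even cells; the cell between each 2x2 chain neighborhood (odd-odd) is
the arithmetic mean of its four surrounding chains, wrapping periodically at
grid edges; odd-even / even-odd cells average their two flanking chains.
The matrix is then refined by bilinear interpolation (``pixels_per_cell``
steps per node interval) and smoothed by repeated 5-point moving averages
with shrinking edge windows, which preserves constants and affine interiors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_metrics import ChainProfile
from .core import GraftingGrid

WINDOW_TAGS = ("avg_last100ns", "first_converged", "final")


@dataclass
class SurfaceMatrix:
    """Expanded (2*n_x, 2*n_y) matrix over the grafting lattice."""

    values: np.ndarray
    grid: GraftingGrid

    @property
    def extent(self) -> tuple[float, float]:
        return (self.grid.box_x, self.grid.box_y)

    def chain_cell(self, i: int, j: int) -> float:
        return float(self.values[2 * i, 2 * j])

    def cavity_cell(self, i: int, j: int) -> float:
        """Cavity between chains (i, j), (i+1, j), (i, j+1), (i+1, j+1)."""
        return float(self.values[2 * i + 1, 2 * j + 1])


@dataclass
class SurfaceMap:
    """Interpolated and smoothed field over the matrix extent."""

    values: np.ndarray
    extent: tuple[float, float]
    pixels_per_cell: int
    smoothing_passes: int
    metric: str = ""
    window_tag: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("surface map contains non-finite values")


def build_matrix(profile: ChainProfile, grid: GraftingGrid) -> SurfaceMatrix:
    """Place chain values on the doubled lattice and fill cavities with the
    periodic-wrapped mean of the surrounding chains."""
    if len(profile.values) != grid.n_chains:
        raise ValueError(
            f"profile has {len(profile.values)} values but grid has "
            f"{grid.n_chains} chains"
        )
    chain_vals = np.empty((grid.n_x, grid.n_y), dtype=float)
    for cid, i, j in grid.lattice_coords():
        chain_vals[i, j] = profile.value_for(cid)

    m = np.empty((2 * grid.n_x, 2 * grid.n_y), dtype=float)
    for i in range(grid.n_x):
        ip = (i + 1) % grid.n_x
        for j in range(grid.n_y):
            jp = (j + 1) % grid.n_y
            m[2 * i, 2 * j] = chain_vals[i, j]
            m[2 * i + 1, 2 * j] = 0.5 * (chain_vals[i, j] + chain_vals[ip, j])
            m[2 * i, 2 * j + 1] = 0.5 * (chain_vals[i, j] + chain_vals[i, jp])
            m[2 * i + 1, 2 * j + 1] = 0.25 * (
                chain_vals[i, j]
                + chain_vals[ip, j]
                + chain_vals[i, jp]
                + chain_vals[ip, jp]
            )
    return SurfaceMatrix(values=m, grid=grid)


# ---------------------------------------------------------------------------
# Interpolation + smoothing
# ---------------------------------------------------------------------------


def _bilinear_refine(values: np.ndarray, pixels_per_cell: int) -> np.ndarray:
    """Refine each node interval into ``pixels_per_cell`` steps, bilinear."""
    nx, ny = values.shape
    out_x = (nx - 1) * pixels_per_cell + 1
    out_y = (ny - 1) * pixels_per_cell + 1
    xi = np.arange(out_x) / pixels_per_cell
    yi = np.arange(out_y) / pixels_per_cell
    # separable linear interpolation along each axis
    tmp = np.empty((out_x, ny), dtype=float)
    for j in range(ny):
        tmp[:, j] = np.interp(xi, np.arange(nx), values[:, j])
    out = np.empty((out_x, out_y), dtype=float)
    for i in range(out_x):
        out[i, :] = np.interp(yi, np.arange(ny), tmp[i, :])
    return out


def moving_average_smooth(y: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving average with shrinking symmetric windows at the edges
    (first value untouched, second averages 3 points, and so on)."""
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be a positive odd integer, got {span}")
    n = len(y)
    half = span // 2
    out = np.empty(n, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (csum[i + k + 1] - csum[i - k]) / (2 * k + 1)
    return out


def _smooth_2d(values: np.ndarray, span: int = 5) -> np.ndarray:
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = moving_average_smooth(values[:, j], span)
    for i in range(values.shape[0]):
        out[i, :] = moving_average_smooth(out[i, :], span)
    return out


def interpolate_and_smooth(
    matrix: SurfaceMatrix,
    pixels_per_cell: int = 5,
    passes: int = 5,
    metric: str = "",
    window_tag: str = "",
) -> SurfaceMap:
    """Bilinear refinement followed by repeated 5-point smoothing."""
    if pixels_per_cell < 1:
        raise ValueError(f"pixels_per_cell must be >= 1, got {pixels_per_cell}")
    if passes < 0:
        raise ValueError(f"passes must be >= 0, got {passes}")
    if matrix.values.shape[0] < 2 or matrix.values.shape[1] < 2:
        raise ValueError("surface matrix must be at least 2x2")
    field = _bilinear_refine(matrix.values, pixels_per_cell)
    for _ in range(passes):
        field = _smooth_2d(field, span=5)
    return SurfaceMap(
        values=field,
        extent=matrix.extent,
        pixels_per_cell=pixels_per_cell,
        smoothing_passes=passes,
        metric=metric,
        window_tag=window_tag,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render(
    surface_map: SurfaceMap,
    output_prefix: str,
    window_tag: str | None = None,
) -> tuple[str, str]:
    """Write the map as a delimited matrix file and a raster image.

    Returns (matrix_path, image_path).  Deterministic for fixed input.
    """
    tag = window_tag or surface_map.window_tag or "map"
    if window_tag is not None and window_tag not in WINDOW_TAGS:
        raise ValueError(
            f"unknown window tag {window_tag!r}; expected one of {WINDOW_TAGS}"
        )
    matrix_path = f"{output_prefix}_{tag}.tsv"
    image_path = f"{output_prefix}_{tag}.png"

    header = (
        f"# surface map\tmetric={surface_map.metric or 'unknown'}"
        f"\twindow={tag}"
        f"\textent_A={surface_map.extent[0]:g}x{surface_map.extent[1]:g}"
        f"\tpixels_per_cell={surface_map.pixels_per_cell}"
        f"\tpasses={surface_map.smoothing_passes}\n"
    )
    with open(matrix_path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, surface_map.values, fmt="%.6f", delimiter="\t")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        surface_map.values.T,
        origin="lower",
        extent=(0, surface_map.extent[0], 0, surface_map.extent[1]),
        aspect="equal",
        cmap="viridis",
    )
    ax.set_xlabel("x (Å)")
    ax.set_ylabel("y (Å)")
    label = surface_map.metric or "value"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(f"{label} ({tag})")
    fig.savefig(image_path, dpi=120)
    plt.close(fig)
    return matrix_path, image_path
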