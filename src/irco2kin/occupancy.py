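"""CO2 occupancy analysis of centroid trajectories in a periodic box.

Counts ligand centroids inside a defined active-site volume, converts the
time-averaged counts to local and bulk concentrations, and reports the
binding free energy

    dG = -ln(c_site / c_bulk)   [kBT]

with a block-averaged standard error.  Negative dG means binding to the
site volume is favourable.  A simple density-grid peak finder locates the
most probable binding sites.

Coordinates are wrapped into the primary box image; region membership uses
half-open bounds (min <= x < max per axis) so boundary counts are
deterministic.  Trajectories are plain tables (columns frame, mol_id,
x_nm, y_nm, z_nm) — real MD formats are deliberately out of scope, the CSV
schema is the seam for format adapters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Trajectory",
    "RegionBox",
    "OccupancyResult",
    "BindingSite",
    "count_in_region",
    "binding_free_energy",
    "find_binding_sites",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


@dataclass
class Trajectory:
    """Per-frame CO2 centroid coordinates (nm) in an orthorhombic box."""

    frames: list[np.ndarray]
    box_edges: np.ndarray

    def __post_init__(self) -> None:
        self.box_edges = np.asarray(self.box_edges, dtype=float).reshape(3)
        if np.any(self.box_edges <= 0):
            raise ValueError("box edges must be positive")
        frames = []
        for i, f in enumerate(self.frames):
            arr = np.asarray(f, dtype=float).reshape(-1, 3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"frame {i}: non-finite coordinates")
            frames.append(arr)
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def wrapped(self) -> list[np.ndarray]:
        """Frames with coordinates wrapped into the primary box image."""
        return [np.mod(f, self.box_edges) for f in self.frames]


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned region (nm), half-open per axis: min <= x < max."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float).reshape(3)
        hi = np.asarray(self.max_corner, dtype=float).reshape(3)
        if np.any(lo >= hi):
            raise ValueError("region min corner must be < max corner on every axis")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def volume(self) -> float:
        return float(np.prod(self.max_corner - self.min_corner))


@dataclass(frozen=True)
class OccupancyResult:
    mean_count: float
    c_site: float       # molecules / nm^3
    c_bulk: float
    ratio: float
    dG: float           # kBT; negative = favourable
    dG_err: float       # block-averaged SE, kBT
    n_frames: int


@dataclass(frozen=True)
class BindingSite:
    center: np.ndarray          # nm
    density: float              # smoothed counts at the peak cell
    occupancy_fraction: float   # fraction of all samples near the peak


def _validate_region(region: RegionBox, box_edges: np.ndarray) -> None:
    box = np.asarray(box_edges, dtype=float).reshape(3)
    if np.any(region.min_corner < 0) or np.any(region.max_corner > box):
        raise ValueError("region must lie inside the periodic box")
    if region.volume >= float(np.prod(box)):
        raise ValueError("region volume must be smaller than the box volume")


def count_in_region(
    frame: np.ndarray, region: RegionBox, box_edges: Sequence[float]
) -> int:
    """Count centroids inside the region after wrapping into the box."""
    box = np.asarray(box_edges, dtype=float).reshape(3)
    _validate_region(region, box)
    coords = np.mod(np.asarray(frame, dtype=float).reshape(-1, 3), box)
    inside = np.all(
        (coords >= region.min_corner) & (coords < region.max_corner), axis=1
    )
    return int(inside.sum())


def binding_free_energy(
    trajectory: Trajectory, region: RegionBox, n_blocks: int = 5
) -> OccupancyResult:
    """Binding free energy of the region from time-averaged occupancy.

    c_site and c_bulk are the mean in-region and out-of-region counts per
    unit volume; dG = -ln(c_site / c_bulk) in kBT.  The error is the
    standard error of per-block dG over ``n_blocks`` contiguous blocks.
    """
    if trajectory.n_frames < 100:
        raise ValueError("need at least 100 frames for occupancy statistics")
    _validate_region(region, trajectory.box_edges)
    n_mol = sum(f.shape[0] for f in trajectory.frames)
    if n_mol == 0:
        raise ValueError("trajectory contains no molecules; dG undefined")

    v_site = region.volume
    v_box = float(np.prod(trajectory.box_edges))
    v_bulk = v_box - v_site
    lo, hi = region.min_corner, region.max_corner

    counts_in = np.empty(trajectory.n_frames)
    counts_tot = np.empty(trajectory.n_frames)
    for i, f in enumerate(trajectory.wrapped()):
        inside = np.all((f >= lo) & (f < hi), axis=1)
        counts_in[i] = inside.sum()
        counts_tot[i] = f.shape[0]

    if counts_in.sum() == 0:
        raise ValueError("unsampled region: no molecule ever inside the site volume")

    c_site = counts_in.mean() / v_site
    c_bulk = (counts_tot - counts_in).mean() / v_bulk
    if c_bulk <= 0:
        raise ValueError("unsampled bulk: every molecule inside the site volume")
    ratio = c_site / c_bulk
    dg = -np.log(ratio)

    block_dgs = []
    for block in np.array_split(np.arange(trajectory.n_frames), n_blocks):
        bi = counts_in[block].mean() / v_site
        bo = (counts_tot[block] - counts_in[block]).mean() / v_bulk
        if bi > 0 and bo > 0:
            block_dgs.append(-np.log(bi / bo))
    if len(block_dgs) >= 2:
        err = float(np.std(block_dgs, ddof=1) / np.sqrt(len(block_dgs)))
    else:
        err = float("nan")

    return OccupancyResult(
        mean_count=float(counts_in.mean()),
        c_site=float(c_site),
        c_bulk=float(c_bulk),
        ratio=float(ratio),
        dG=float(dg),
        dG_err=err,
        n_frames=trajectory.n_frames,
    )


def find_binding_sites(
    trajectory: Trajectory,
    grid_spacing: float = 0.1,
    smooth_sigma_cells: float = 1.0,
    threshold_sd: float = 3.0,
) -> list[BindingSite]:
    """Locate density peaks: the most probable binding sites.

    All samples are histogrammed on a 3-D grid (``grid_spacing`` nm cells,
    periodic), the histogram is Gaussian-smoothed (sigma in cells), and
    peaks are local maxima of the smoothed density exceeding
    mean + ``threshold_sd`` * SD of the raw cell counts.  Smoothing
    suppresses Poisson cell noise, so a uniform trajectory yields no peaks
    while a genuine well stands far above the raw-count threshold.  Peaks
    are ranked by density; occupancy_fraction is the fraction of all
    samples within one cell (Chebyshev) of the peak.
    """
    if trajectory.n_frames < 100:
        raise ValueError("need at least 100 frames for a density map")
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    box = trajectory.box_edges
    nbins = np.maximum(np.round(box / grid_spacing).astype(int), 1)
    coords = np.vstack(trajectory.wrapped())
    if coords.shape[0] == 0:
        raise ValueError("trajectory contains no molecules")
    edges = [np.linspace(0.0, box[d], nbins[d] + 1) for d in range(3)]
    counts, _ = np.histogramdd(coords, bins=edges)

    smoothed = ndimage.gaussian_filter(counts, sigma=smooth_sigma_cells, mode="wrap")
    threshold = counts.mean() + threshold_sd * counts.std()
    local_max = smoothed == ndimage.maximum_filter(smoothed, size=3, mode="wrap")
    peak_mask = local_max & (smoothed > threshold)
    idx = np.argwhere(peak_mask)
    if idx.size == 0:
        return []

    total = coords.shape[0]
    sites = []
    for i, j, k in idx:
        center = (np.array([i, j, k]) + 0.5) * (box / nbins)
        # occupancy: raw counts in the 3x3x3 periodic neighbourhood
        occ = 0.0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    occ += counts[(i + di) % nbins[0], (j + dj) % nbins[1], (k + dk) % nbins[2]]
        sites.append(
            BindingSite(
                center=center,
                density=float(smoothed[i, j, k]),
                occupancy_fraction=float(occ / total),
            )
        )
    sites.sort(key=lambda s: s.density, reverse=True)
    return sites


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write the plain-table trajectory schema (frame, mol_id, x/y/z nm)."""
    rows = []
    for i, f in enumerate(trajectory.frames):
        for j, (x, y, z) in enumerate(f):
            rows.append((i, j, x, y, z))
    df = pd.DataFrame(rows, columns=["frame", "mol_id", "x_nm", "y_nm", "z_nm"])
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, box_edges: Sequence[float]) -> Trajectory:
    """Read a trajectory table written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    required = {"frame", "x_nm", "y_nm", "z_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    frames = []
    for _, group in df.groupby("frame", sort=True):
        frames.append(group[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float))
    return Trajectory(frames=frames, box_edges=np.asarray(box_edges, dtype=float))
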