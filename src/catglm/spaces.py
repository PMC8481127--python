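"""Two-dimensional orientation x spatial-frequency category spaces.

A category space is a grid of grating stimuli, each defined by an
orientation, a spatial frequency and a drift direction, bisected by a
linear category boundary. Stimuli on one side of the boundary belong to
the "left" category, stimuli on the other side to the "right" category,
and stimuli falling exactly on the boundary line are excluded from the
task.

Geometry is computed in integer grid coordinates (orientation index on
the x axis, spatial-frequency index on the y axis): orientations are
spaced linearly but spatial frequencies roughly logarithmically, so the
behaviorally meaningful "distance to the category boundary" is counted
in grid steps, not in physical units. The boundary angle convention is:
0 deg = boundary parallel to the spatial-frequency axis (a pure
orientation rule), measured counter-clockwise, so a 45 deg boundary
weighs both dimensions equally (information integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CategorySpace", "build_category_space", "reduce_to_category_stimuli"]

#: stimuli closer than this (grid units) to the boundary line count as on it
ON_BOUNDARY_TOL = 1e-9


@dataclass
class CategorySpace:
    """A labeled grid of grating stimuli split by a linear boundary.

    Attributes
    ----------
    orientations : ndarray
        Orientation of each grid column, degrees.
    spatial_frequencies : ndarray
        Spatial frequency of each grid row, cycles/degree, strictly
        increasing.
    directions : int
        Number of drift directions per (orientation, SF) combination.
    boundary_angle_deg : float
        Boundary angle in grid units (see module docstring).
    boundary_offset : float
        Signed offset of the boundary from the grid center, in grid
        units along the boundary normal.
    stimulus_grid : DataFrame
        One row per stimulus with columns ``ori_index``, ``sf_index``,
        ``direction``, ``orientation_deg``, ``spatial_frequency``,
        ``signed_distance`` (grid units, positive on the "right" side)
        and ``category`` in {"left", "right", "excluded"}, plus an
        ``active`` flag used to restrict the task to a stimulus subset.
    """

    orientations: np.ndarray
    spatial_frequencies: np.ndarray
    directions: int
    boundary_angle_deg: float
    boundary_offset: float
    stimulus_grid: pd.DataFrame = field(repr=False)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)

    @property
    def n_spatial_frequencies(self) -> int:
        return len(self.spatial_frequencies)

    @property
    def grid_center(self) -> tuple[float, float]:
        return (self.n_orientations - 1) / 2.0, (self.n_spatial_frequencies - 1) / 2.0

    def active_stimuli(self) -> pd.DataFrame:
        """Labeled, non-excluded stimuli currently in the task."""
        g = self.stimulus_grid
        return g[(g["category"] != "excluded") & g["active"]].reset_index(drop=True)

    def labeled_stimuli(self) -> pd.DataFrame:
        """All stimuli carrying a left/right label (excluded dropped)."""
        g = self.stimulus_grid
        return g[g["category"] != "excluded"].reset_index(drop=True)

    def category_counts(self) -> dict[str, int]:
        return self.stimulus_grid["category"].value_counts().to_dict()

    def signed_distance(self, ori_index, sf_index) -> np.ndarray:
        """Signed grid distance of (ori_index, sf_index) to the boundary."""
        return signed_boundary_distance(
            np.asarray(ori_index, dtype=float),
            np.asarray(sf_index, dtype=float),
            self.boundary_angle_deg,
            self.boundary_offset,
            self.grid_center,
        )


def signed_boundary_distance(x, y, angle_deg, offset, center):
    """Distance of grid points to the boundary line, positive -> 'right'.

    The boundary passes at ``offset`` grid units from ``center`` along
    its unit normal ``(cos a, sin a)`` with ``a`` the boundary angle.
    """
    a = np.deg2rad(angle_deg)
    cx, cy = center
    return np.cos(a) * (np.asarray(x) - cx) + np.sin(a) * (np.asarray(y) - cy) - offset


def build_category_space(
    n_orientations: int,
    orientation_spacing_deg: float,
    spatial_frequencies,
    boundary_angle_deg: float = 45.0,
    boundary_offset: float = 0.0,
    directions: int = 1,
    orientation_start_deg: float = 0.0,
) -> CategorySpace:
    """Construct a labeled orientation x spatial-frequency category space.

    Parameters
    ----------
    n_orientations : int
        Number of orientation levels (grid columns), >= 2.
    orientation_spacing_deg : float
        Spacing between neighboring orientations, degrees.
    spatial_frequencies : sequence of float
        Strictly increasing spatial frequencies, cycles/degree.
    boundary_angle_deg, boundary_offset : float
        Boundary placement in grid units; see :mod:`catglm.spaces`.
    directions : int
        1 or 2 drift directions per grid node.

    Returns
    -------
    CategorySpace
        With every (orientation, SF, direction) combination appearing
        exactly once, stimuli on the boundary labeled ``excluded`` and
        the remainder split into equally-defined left/right categories
        by the signed boundary distance.
    """
    if n_orientations < 2:
        raise ValueError("need at least 2 orientations")
    sfs = np.asarray(list(spatial_frequencies), dtype=float)
    if len(sfs) < 1 or np.any(np.diff(sfs) <= 0):
        raise ValueError("spatial_frequencies must be strictly increasing")
    if directions not in (1, 2):
        raise ValueError("directions must be 1 or 2")
    if not np.isfinite(boundary_angle_deg):
        raise ValueError("degenerate boundary: angle undefined")

    oris = orientation_start_deg + orientation_spacing_deg * np.arange(n_orientations)
    center = ((n_orientations - 1) / 2.0, (len(sfs) - 1) / 2.0)

    ori_idx, sf_idx, dirs = np.meshgrid(
        np.arange(n_orientations), np.arange(len(sfs)), np.arange(directions),
        indexing="ij",
    )
    ori_idx, sf_idx, dirs = ori_idx.ravel(), sf_idx.ravel(), dirs.ravel()
    dist = signed_boundary_distance(
        ori_idx.astype(float), sf_idx.astype(float),
        boundary_angle_deg, boundary_offset, center,
    )
    category = np.where(
        np.abs(dist) <= ON_BOUNDARY_TOL, "excluded",
        np.where(dist > 0, "right", "left"),
    )
    if np.all(category == "excluded"):
        raise ValueError("boundary excludes every stimulus")

    grid = pd.DataFrame(
        {
            "ori_index": ori_idx,
            "sf_index": sf_idx,
            "direction": dirs,
            "orientation_deg": oris[ori_idx],
            "spatial_frequency": sfs[sf_idx],
            "signed_distance": dist,
            "category": category,
            "active": True,
        }
    )
    return CategorySpace(
        orientations=oris,
        spatial_frequencies=sfs,
        directions=directions,
        boundary_angle_deg=float(boundary_angle_deg),
        boundary_offset=float(boundary_offset),
        stimulus_grid=grid,
    )


def reduce_to_category_stimuli(space: CategorySpace, n_per_side: int = 5) -> CategorySpace:
    """Restrict the task to the ``n_per_side`` stimuli nearest the boundary.

    Mirrors the reduced category space of the chronic-imaging task, in
    which only the stimuli hugging the boundary ("category stimuli")
    are shown so that each collects many trials. Returns a new space
    whose grid is identical but with ``active`` set only on the
    ``n_per_side`` labeled stimuli closest to the boundary on each
    side (ties broken by grid position, deterministically).
    """
    grid = space.stimulus_grid.copy()
    grid["active"] = False
    for side in ("left", "right"):
        rows = grid[grid["category"] == side].copy()
        if len(rows) < n_per_side:
            raise ValueError(f"fewer than {n_per_side} stimuli in {side} category")
        rows["absd"] = rows["signed_distance"].abs()
        chosen = rows.sort_values(
            ["absd", "ori_index", "sf_index", "direction"], kind="mergesort"
        ).head(n_per_side)
        grid.loc[chosen.index, "active"] = True
    return CategorySpace(
        orientations=space.orientations,
        spatial_frequencies=space.spatial_frequencies,
        directions=space.directions,
        boundary_angle_deg=space.boundary_angle_deg,
        boundary_offset=space.boundary_offset,
        stimulus_grid=grid,
    )
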