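"""Tissue domain: a thin 2-D sheet carrying the tissue-point grid.

The tissue is a closed polygon of given thickness (default 20 µm) with a
square array of tissue points (default spacing 50 µm) that act as the
discrete oxygen sinks and VEGF sources. Fields solved on the grid are stored
point-wise; `(i, j)` indexing into the bounding-box lattice is kept so that
finite-difference operators and bilinear interpolation are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import sparse
from shapely.geometry import Point, Polygon


@dataclass
class TissueDomain:
    boundary: Polygon                 # µm coordinates
    thickness: float = 20.0           # µm
    spacing: float = 50.0             # µm, tissue-point grid spacing
    points: np.ndarray = field(init=False)        # (N, 2) µm
    index: np.ndarray = field(init=False)         # (N, 2) lattice (i, j)
    shape: Tuple[int, int] = field(init=False)    # lattice extent (ni, nj)
    origin: np.ndarray = field(init=False)        # lattice origin (µm)
    grid_id: np.ndarray = field(init=False)       # (ni, nj) -> point index or -1

    def __post_init__(self) -> None:
        minx, miny, maxx, maxy = self.boundary.bounds
        h = self.spacing
        # center the lattice in the bounding box
        nx = int(np.floor((maxx - minx) / h + 1e-9)) + 1
        ny = int(np.floor((maxy - miny) / h + 1e-9)) + 1
        x0 = minx + ((maxx - minx) - (nx - 1) * h) / 2
        y0 = miny + ((maxy - miny) - (ny - 1) * h) / 2
        self.origin = np.array([x0, y0])
        xs = x0 + h * np.arange(nx)
        ys = y0 + h * np.arange(ny)
        pts = []
        idx = []
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                if self.boundary.buffer(1e-6).contains(Point(x, y)):
                    pts.append((x, y))
                    idx.append((i, j))
        self.points = np.array(pts) if pts else np.empty((0, 2))
        self.index = np.array(idx, dtype=int) if idx else np.empty((0, 2), dtype=int)
        self.shape = (nx, ny)
        self.grid_id = -np.ones((nx, ny), dtype=int)
        for k, (i, j) in enumerate(self.index):
            self.grid_id[i, j] = k

    # ------------------------------------------------------------------ api
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Polygon area in mm^2."""
        return self.boundary.area / 1e6

    @property
    def point_volume(self) -> float:
        """Tissue volume per grid point in cm^3."""
        return (self.spacing * 1e-4) ** 2 * (self.thickness * 1e-4)

    def contains(self, p: np.ndarray) -> bool:
        return self.boundary.buffer(1e-6).contains(Point(float(p[0]), float(p[1])))

    def crosses_boundary(self, a: np.ndarray, b: np.ndarray) -> bool:
        from shapely.geometry import LineString

        return not self.boundary.buffer(1e-6).contains(
            LineString([tuple(map(float, a)), tuple(map(float, b))])
        )

    def neumann_laplacian(self) -> sparse.csr_matrix:
        """Graph Laplacian of the tissue-point lattice with no-flux boundaries.

        Entry units: dimensionless (per link); multiply by a conductance and
        it discretizes -∇·(k∇) integrated over cells of a 2-D sheet, where
        the cell size cancels.
        """
        n = self.n_points
        rows, cols, vals = [], [], []
        for k, (i, j) in enumerate(self.index):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < self.shape[0] and 0 <= jj < self.shape[1]:
                    m = self.grid_id[ii, jj]
                    if m >= 0:
                        rows.append(k)
                        cols.append(k)
                        vals.append(1.0)
                        rows.append(k)
                        cols.append(int(m))
                        vals.append(-1.0)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def interpolate(self, values: np.ndarray, position: np.ndarray) -> float:
        """Bilinear interpolation of a point-wise field at an arbitrary position.

        Cells with missing corners (outside the polygon) fall back to the
        nearest available tissue point.
        """
        h = self.spacing
        fx = (float(position[0]) - self.origin[0]) / h
        fy = (float(position[1]) - self.origin[1]) / h
        i0 = int(np.floor(fx))
        j0 = int(np.floor(fy))
        tx = fx - i0
        ty = fy - j0
        corners = []
        weights = []
        for (di, dj, w) in (
            (0, 0, (1 - tx) * (1 - ty)),
            (1, 0, tx * (1 - ty)),
            (0, 1, (1 - tx) * ty),
            (1, 1, tx * ty),
        ):
            i, j = i0 + di, j0 + dj
            if 0 <= i < self.shape[0] and 0 <= j < self.shape[1] and self.grid_id[i, j] >= 0:
                corners.append(self.grid_id[i, j])
                weights.append(w)
        if not corners:
            d = np.hypot(*(self.points - np.asarray(position, float)).T)
            return float(values[int(np.argmin(d))])
        weights = np.array(weights)
        if weights.sum() <= 0:
            d = np.hypot(*(self.points - np.asarray(position, float)).T)
            return float(values[int(np.argmin(d))])
        weights = weights / weights.sum()
        return float(np.dot(weights, values[np.array(corners, dtype=int)]))


def rectangle_domain(width: float, height: float, thickness: float = 20.0, spacing: float = 50.0) -> TissueDomain:
    """Axis-aligned rectangular tissue sheet with corner at the origin (µm)."""
    poly = Polygon([(0, 0), (width, 0), (width, height), (0, height)])
    return TissueDomain(poly, thickness=thickness, spacing=spacing)
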