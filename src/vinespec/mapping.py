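"""Multilevel B-spline approximation (MBA) maps of block predictions.

Scattered per-block predictions are turned into smooth rasters with the
classic multilevel B-spline approximation: a coarse uniform cubic B-spline
control lattice is fitted to the points with the local weighted
least-squares control-point assignment of the BA algorithm, the residuals
are fitted on a lattice of twice the resolution, and so on; the surface is
the sum of the per-level spline surfaces plus a constant offset (the data
mean), so a constant field is reproduced exactly everywhere.  The result is
a C²-continuous surface whose misfit at the data points shrinks
geometrically with the number of levels.

Rasters are masked to the neighbourhood of the block centroids (no-data
beyond twice the row spacing by default) so maps never extrapolate far
outside the plot, and can be written as ESRI ASCII grids or GeoJSON cell
polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DEFAULT_LEVELS = 8
DEFAULT_INITIAL_LATTICE = 4


def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """The four uniform cubic B-spline basis values at local parameter t.

    Returns shape ``(n, 4)`` for input shape ``(n,)``; column ``k`` is
    ``B_k(t)`` for the control point ``k`` cells to the right of the
    anchor.
    """
    t = np.asarray(t, dtype=float)
    one = 1.0 - t
    return np.stack(
        [
            one**3 / 6.0,
            (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0,
            (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0,
            t**3 / 6.0,
        ],
        axis=-1,
    )


@dataclass
class _Lattice:
    """One level's control lattice: (m+3) × (n+3) coefficients."""

    phi: np.ndarray
    m: int  # cells along x
    n: int  # cells along y


@dataclass
class MBAModel:
    """A fitted multilevel B-spline surface over a bounding box."""

    bbox: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    offset: float
    lattices: list[_Lattice] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.lattices)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return evaluate(self, x, y)


def _locate(
    coords: np.ndarray, lo: float, hi: float, cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cell index and local parameter of each coordinate on a lattice axis."""
    u = (np.asarray(coords, dtype=float) - lo) / (hi - lo) * cells
    i = np.floor(u).astype(int)
    i = np.clip(i, 0, cells - 1)  # points on the upper boundary
    return i, u - i


def _fit_level(
    x: np.ndarray, y: np.ndarray, z: np.ndarray,
    bbox: tuple[float, float, float, float], m: int, n: int,
) -> _Lattice:
    """BA algorithm: one control lattice approximating scattered residuals.

    Each point distributes its value to the 4×4 control points whose basis
    functions cover it, with the per-point solution
    ``φ_c = w_c z / Σ w²``; overlapping claims are reconciled by the
    w²-weighted average.  Control points untouched by any point stay 0.
    """
    xmin, ymin, xmax, ymax = bbox
    ix, s = _locate(x, xmin, xmax, m)
    iy, t = _locate(y, ymin, ymax, n)
    bs = _bspline_basis(s)  # (npts, 4)
    bt = _bspline_basis(t)
    w = bs[:, :, None] * bt[:, None, :]  # (npts, 4, 4)
    wsum2 = np.sum(w**2, axis=(1, 2))  # (npts,)
    num = np.zeros((m + 3, n + 3))
    den = np.zeros((m + 3, n + 3))
    contrib = w**2 * (w * z[:, None, None] / wsum2[:, None, None])
    kk, ll = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
    for p in range(x.size):
        rows = ix[p] + kk
        cols = iy[p] + ll
        np.add.at(num, (rows, cols), contrib[p])
        np.add.at(den, (rows, cols), w[p] ** 2)
    phi = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return _Lattice(phi=phi, m=m, n=n)


def _eval_level(
    lat: _Lattice, x: np.ndarray, y: np.ndarray,
    bbox: tuple[float, float, float, float],
) -> np.ndarray:
    xmin, ymin, xmax, ymax = bbox
    ix, s = _locate(np.ravel(x), xmin, xmax, lat.m)
    iy, t = _locate(np.ravel(y), ymin, ymax, lat.n)
    bs = _bspline_basis(s)
    bt = _bspline_basis(t)
    out = np.zeros(ix.size)
    for k in range(4):
        for l_ in range(4):
            out += bs[:, k] * bt[:, l_] * lat.phi[ix + k, iy + l_]
    return out.reshape(np.shape(x))


def mba_fit(
    x: Sequence[float],
    y: Sequence[float],
    values: Sequence[float],
    n_levels: int = DEFAULT_LEVELS,
    initial_lattice: int = DEFAULT_INITIAL_LATTICE,
    bbox: tuple[float, float, float, float] | None = None,
) -> MBAModel:
    """Fit the multilevel B-spline surface to scattered points.

    ``initial_lattice`` is the cell count of the coarsest lattice along
    each axis (≥ 1; the classic choice 4 gives a 7×7 control grid); each
    level doubles it.  ``bbox`` defaults to the data bounding box padded by
    1% (degenerate spans are widened so the lattice always has area).  The
    data mean is carried as a constant offset level so the spline levels
    fit only departures from it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one point")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(z))):
        raise ValueError("points and values must be finite")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if bbox is None:
        span_x = max(x.max() - x.min(), 1e-6)
        span_y = max(y.max() - y.min(), 1e-6)
        bbox = (
            x.min() - 0.01 * span_x, y.min() - 0.01 * span_y,
            x.max() + 0.01 * span_x, y.max() + 0.01 * span_y,
        )
    if bbox[2] <= bbox[0] or bbox[3] <= bbox[1]:
        raise ValueError("bounding box has zero area")
    if np.any(x < bbox[0]) or np.any(x > bbox[2]) \
            or np.any(y < bbox[1]) or np.any(y > bbox[3]):
        raise ValueError("points fall outside the bounding box")
    offset = float(z.mean())
    model = MBAModel(bbox=bbox, offset=offset)
    resid = z - offset
    m = n = int(initial_lattice)
    for _ in range(n_levels):
        lat = _fit_level(x, y, resid, bbox, m, n)
        surf = _eval_level(lat, x, y, bbox)
        # Damped update: the BA assignment can overshoot in max norm on
        # coarse lattices over elongated point sets, so each level's
        # surface is scaled by the step length minimising the new max
        # residual.  max|r - g*s| is convex in g, so a grid-plus-refine
        # search is exact enough; g=0 is always admissible, which makes
        # the max residual non-increasing across levels by construction.
        gamma = _monotone_step(resid, surf)
        lat.phi *= gamma
        model.lattices.append(lat)
        resid = resid - gamma * surf
        m, n = m * 2, n * 2
    return model


def _monotone_step(resid: np.ndarray, surf: np.ndarray) -> float:
    """Step length in [0, 1] minimising ``max|resid - g * surf|``."""
    grid = np.linspace(0.0, 1.0, 41)
    costs = np.max(np.abs(resid[None, :] - grid[:, None] * surf[None, :]), axis=1)
    g0 = grid[int(np.argmin(costs))]
    lo, hi = max(0.0, g0 - 0.025), min(1.0, g0 + 0.025)
    fine = np.linspace(lo, hi, 41)
    costs = np.max(np.abs(resid[None, :] - fine[:, None] * surf[None, :]), axis=1)
    return float(fine[int(np.argmin(costs))])


def evaluate(model: MBAModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the summed spline hierarchy at arbitrary in-box positions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xmin, ymin, xmax, ymax = model.bbox
    if np.any(x < xmin) or np.any(x > xmax) or np.any(y < ymin) or np.any(y > ymax):
        raise ValueError("evaluation positions outside the model bounding box")
    out = np.full(np.shape(x), model.offset, dtype=float)
    for lat in model.lattices:
        out = out + _eval_level(lat, x, y, model.bbox)
    return out


@dataclass
class PredictionMap:
    """A raster of interpolated analyte values for one date."""

    origin: tuple[float, float]  # lower-left corner of the grid
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), row 0 = southernmost
    analyte: str = ""
    date_index: int = 0
    nodata: float = -9999.0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin
        xs = ox + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = oy + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def mba_evaluate(
    model: MBAModel,
    origin: tuple[float, float],
    cell_size: float,
    n_cols: int,
    n_rows: int,
    mask_centroids: np.ndarray | None = None,
    mask_distance: float | None = None,
    analyte: str = "",
    date_index: int = 0,
) -> PredictionMap:
    """Rasterise the surface on a regular grid of cell centers.

    Cells farther than ``mask_distance`` from every centroid in
    ``mask_centroids`` are set to NaN (no-data) so the map does not
    extrapolate beyond the plot.
    """
    pm = PredictionMap(
        origin=origin, cell_size=cell_size,
        values=np.zeros((n_rows, n_cols)),
        analyte=analyte, date_index=date_index,
    )
    gx, gy = pm.cell_centers()
    pm.values = evaluate(model, gx, gy)
    if mask_centroids is not None and mask_distance is not None:
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d = np.linalg.norm(
            pts[:, None, :] - np.asarray(mask_centroids)[None, :, :], axis=2
        ).min(axis=1)
        masked = pm.values.ravel()
        masked[d > mask_distance] = np.nan
        pm.values = masked.reshape(n_rows, n_cols)
    return pm


def render_series(
    per_date_points: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]],
    cell_size: float = 1.0,
    n_levels: int = DEFAULT_LEVELS,
    pad: float = 2.20,
    mask_distance: float | None = 4.40,
    analyte: str = "",
) -> tuple[dict[int, PredictionMap], tuple[float, float]]:
    """Build one map per date on a shared grid and shared colour scale.

    ``per_date_points`` maps date index to ``(x, y, values)``.  The grid
    covers the union bounding box of all dates padded by ``pad`` metres
    (one row spacing by default); the returned scale bounds are the min and
    max raster values across dates, so a figure series drawn from these
    maps is comparable over time.
    """
    if not per_date_points:
        raise ValueError("need at least one date")
    all_x = np.concatenate([p[0] for p in per_date_points.values()])
    all_y = np.concatenate([p[1] for p in per_date_points.values()])
    x0, y0 = all_x.min() - pad, all_y.min() - pad
    n_cols = max(1, int(np.ceil((all_x.max() + pad - x0) / cell_size)))
    n_rows = max(1, int(np.ceil((all_y.max() + pad - y0) / cell_size)))
    # the model bbox covers the whole grid so every cell center is in-box
    bbox = (x0, y0, x0 + n_cols * cell_size, y0 + n_rows * cell_size)
    maps: dict[int, PredictionMap] = {}
    for date, (x, y, z) in sorted(per_date_points.items()):
        model = mba_fit(x, y, z, n_levels=n_levels, bbox=bbox)
        maps[date] = mba_evaluate(
            model, (x0, y0), cell_size, n_cols, n_rows,
            mask_centroids=np.column_stack([x, y]),
            mask_distance=mask_distance,
            analyte=analyte, date_index=date,
        )
    lo = np.nanmin([np.nanmin(m.values) for m in maps.values()])
    hi = np.nanmax([np.nanmax(m.values) for m in maps.values()])
    return maps, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# raster writers


def write_esri_ascii(pm: PredictionMap, path: str | Path) -> None:
    """Write the raster as an ESRI ASCII grid (NaN → nodata)."""
    path = Path(path)
    vals = np.where(np.isnan(pm.values), pm.nodata, pm.values)
    lines = [
        f"ncols {pm.n_cols}",
        f"nrows {pm.n_rows}",
        f"xllcorner {pm.origin[0]:.6f}",
        f"yllcorner {pm.origin[1]:.6f}",
        f"cellsize {pm.cell_size:.6f}",
        f"NODATA_value {pm.nodata:g}",
    ]
    # ESRI grids store rows north to south
    for row in vals[::-1]:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_geojson_cells(pm: PredictionMap, path: str | Path) -> None:
    """Write raster cells as a GeoJSON FeatureCollection of square polygons."""
    ox, oy = pm.origin
    cs = pm.cell_size
    features = []
    for r in range(pm.n_rows):
        for c in range(pm.n_cols):
            v = pm.values[r, c]
            if np.isnan(v):
                continue
            x0, y0 = ox + c * cs, oy + r * cs
            ring = [
                [x0, y0], [x0 + cs, y0], [x0 + cs, y0 + cs], [x0, y0 + cs],
                [x0, y0],
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "value": float(v),
                        "analyte": pm.analyte,
                        "date_index": pm.date_index,
                    },
                }
            )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))
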