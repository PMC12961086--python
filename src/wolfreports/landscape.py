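"""Synthetic landscapes: footprint raster, recolonization zones, provinces.

The landscape emulates the structure of a wolf-recolonization study area:
a bounded region holding a human-footprint index surface (0-50, ~1 km
resolution), five ordered recolonization zones (1 = earliest colonized,
innermost; higher numbers are progressively more recent rings) and a set
of contiguous provinces.  Grids are plain numpy arrays in a north-up
planar (metre) georeference; the region boundary is a shapely polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box, mapping, shape


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    Parameters
    ----------
    width_m, height_m : extent in metres; must be positive multiples of
        ``cell_m``.
    cell_m : raster resolution in metres (default 1000, a 1-km footprint
        raster).
    n_zones : number of ordered recolonization zones (default 5).
    n_provinces : number of administrative provinces (default 10).
    footprint_range : closed range of the human-footprint index.
    smooth_sigma_cells : Gaussian smoothing radius (in cells) of the
        footprint noise field; controls spatial autocorrelation.
    zone_footprint_mix : weight in [0, 1) of the radial trend mixed into
        the footprint surface.  Because zones are concentric, the trend
        induces a mild positive correlation between zone index and
        footprint (recently colonized outer rings are more urbanized);
        the default yields a cell-level correlation near 0.45.
    seed : generator seed; identical configs produce identical landscapes.
    """

    width_m: float = 100_000.0
    height_m: float = 80_000.0
    cell_m: float = 1000.0
    n_zones: int = 5
    n_provinces: int = 10
    footprint_range: tuple[float, float] = (0.0, 50.0)
    smooth_sigma_cells: float = 3.0
    zone_footprint_mix: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.cell_m <= 0:
            raise ValueError("cell_m must be positive")
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("extent must be positive")
        for name, v in (("width_m", self.width_m), ("height_m", self.height_m)):
            if abs(v / self.cell_m - round(v / self.cell_m)) > 1e-9:
                raise ValueError(f"{name} must be a multiple of cell_m")
        if self.n_zones < 2:
            raise ValueError("n_zones must be >= 2")
        if self.n_provinces < 1:
            raise ValueError("n_provinces must be >= 1")
        if not 0 <= self.zone_footprint_mix < 1:
            raise ValueError("zone_footprint_mix must be in [0, 1)")


@dataclass
class Landscape:
    """Footprint grid + ordered zones + provinces + region boundary.

    Grids are (nrow, ncol), row 0 northernmost.  ``zone`` and ``province``
    are 0 outside the region boundary and 1-based inside.  The origin
    (x0, y0) is the lower-left corner of the grid.
    """

    footprint: np.ndarray
    zone: np.ndarray
    province: np.ndarray
    boundary: Polygon
    cell_m: float
    x0: float = 0.0
    y0: float = 0.0
    n_zones: int = 5
    config: LandscapeConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.footprint.shape == self.zone.shape == self.province.shape):
            raise ValueError("footprint, zone and province grids must share shape")

    # -- georeference helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.footprint.shape

    @property
    def extent(self) -> tuple[float, float]:
        nr, nc = self.shape
        return nc * self.cell_m, nr * self.cell_m

    def cell_index(self, x, y):
        """Row/col of the cell containing each point (half-open cells, north-up)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nr, nc = self.shape
        col = np.floor((x - self.x0) / self.cell_m).astype(int)
        row = np.floor((self.y0 + nr * self.cell_m - y) / self.cell_m).astype(int)
        # points exactly on the top/right edge belong to the outermost cell
        col = np.clip(col, 0, nc - 1)
        row = np.clip(row, 0, nr - 1)
        return row, col

    def cell_centers(self):
        """(x, y) coordinates of all cell centers as (nrow, ncol) arrays."""
        nr, nc = self.shape
        xs = self.x0 + (np.arange(nc) + 0.5) * self.cell_m
        ys = self.y0 + (nr - np.arange(nr) - 0.5) * self.cell_m
        return np.meshgrid(xs, ys)

    def inside_mask(self) -> np.ndarray:
        """Boolean grid of cells whose centers fall inside the boundary."""
        cx, cy = self.cell_centers()
        return shapely.contains_xy(self.boundary, cx.ravel(), cy.ravel()).reshape(self.shape)

    def contains(self, x, y) -> np.ndarray:
        return shapely.contains_xy(self.boundary, np.asarray(x, float), np.asarray(y, float))

    def covariates_at(self, x, y):
        """(H, S, province) of the cells containing the points.

        Cells on the rim can have their center outside the boundary and
        carry no zone/province label; points falling there are resolved
        to the nearest labelled cell (the count of such fallbacks is
        returned for logging by callers).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        r, c = self.cell_index(x, y)
        H = self.footprint[r, c].astype(float)
        S = self.zone[r, c].astype(int)
        prov = self.province[r, c].astype(int)
        n_fallback = 0
        bad = (S < 1) | ~np.isfinite(H)
        if bad.any():
            n_fallback = int(bad.sum())
            rows, cols = np.nonzero((self.zone > 0) & np.isfinite(self.footprint))
            cxs = self.x0 + (cols + 0.5) * self.cell_m
            cys = self.y0 + (self.shape[0] - rows - 0.5) * self.cell_m
            for i in np.nonzero(bad)[0]:
                j = np.argmin((cxs - x[i]) ** 2 + (cys - y[i]) ** 2)
                H[i] = self.footprint[rows[j], cols[j]]
                S[i] = self.zone[rows[j], cols[j]]
                prov[i] = self.province[rows[j], cols[j]]
        return H, S, prov, n_fallback

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write grids as ESRI ASCII rasters and vector layers as GeoJSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        _write_ascii_grid(directory / "footprint.asc", self.footprint, self.x0, self.y0, self.cell_m)
        _write_ascii_grid(directory / "zone.asc", self.zone, self.x0, self.y0, self.cell_m)
        _write_ascii_grid(directory / "province.asc", self.province, self.x0, self.y0, self.cell_m)
        (directory / "boundary.geojson").write_text(
            json.dumps({"type": "Feature", "properties": {}, "geometry": mapping(self.boundary)})
        )
        for name, grid in (("zones", self.zone), ("provinces", self.province)):
            feats = []
            for label in np.unique(grid[grid > 0]):
                geom = _dissolve_cells(grid == label, self.x0, self.y0, self.cell_m, self.shape[0])
                feats.append(
                    {"type": "Feature", "properties": {"label": int(label)}, "geometry": mapping(geom)}
                )
            (directory / f"{name}.geojson").write_text(
                json.dumps({"type": "FeatureCollection", "features": feats})
            )
        meta = {"cell_m": self.cell_m, "x0": self.x0, "y0": self.y0, "n_zones": self.n_zones}
        (directory / "landscape.json").write_text(json.dumps(meta))


def load_landscape(directory: str | Path) -> Landscape:
    """Read a landscape previously written by :meth:`Landscape.save`."""
    directory = Path(directory)
    meta = json.loads((directory / "landscape.json").read_text())
    footprint, hdr = _read_ascii_grid(directory / "footprint.asc")
    zone, _ = _read_ascii_grid(directory / "zone.asc")
    province, _ = _read_ascii_grid(directory / "province.asc")
    boundary = shape(json.loads((directory / "boundary.geojson").read_text())["geometry"])
    return Landscape(
        footprint=footprint,
        zone=zone.astype(int),
        province=province.astype(int),
        boundary=boundary,
        cell_m=float(meta["cell_m"]),
        x0=float(meta["x0"]),
        y0=float(meta["y0"]),
        n_zones=int(meta["n_zones"]),
    )


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a landscape with autocorrelated footprint and concentric zones.

    The footprint is white noise smoothed by an isotropic Gaussian kernel,
    mixed with a radial outward trend (see ``zone_footprint_mix``) and
    rescaled to the configured range.  Zones are concentric equal-area
    rings of in-boundary cells around the region centroid, zone 1
    innermost.  Provinces are angular sectors around the centroid.
    Deterministic for a given config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nc = int(round(config.width_m / config.cell_m))
    nr = int(round(config.height_m / config.cell_m))

    # region boundary: rectangle with clipped corners (a convex octagon)
    w, h = config.width_m, config.height_m
    cut = 0.12 * min(w, h)
    boundary = Polygon(
        [
            (cut, 0), (w - cut, 0), (w, cut), (w, h - cut),
            (w - cut, h), (cut, h), (0, h - cut), (0, cut),
        ]
    )

    noise = rng.standard_normal((nr, nc))
    smooth = gaussian_filter(noise, sigma=config.smooth_sigma_cells, mode="reflect")
    smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min() + 1e-12)

    land = Landscape(
        footprint=np.zeros((nr, nc)),
        zone=np.zeros((nr, nc), dtype=int),
        province=np.zeros((nr, nc), dtype=int),
        boundary=boundary,
        cell_m=config.cell_m,
        n_zones=config.n_zones,
        config=config,
    )
    cx, cy = land.cell_centers()
    gx, gy = boundary.centroid.x, boundary.centroid.y
    dist = np.hypot(cx - gx, cy - gy)
    radial = (dist - dist.min()) / (dist.max() - dist.min() + 1e-12)

    mix = config.zone_footprint_mix
    surf = (1.0 - mix) * smooth + mix * radial
    lo, hi = config.footprint_range
    surf = (surf - surf.min()) / (surf.max() - surf.min() + 1e-12)
    land.footprint = lo + surf * (hi - lo)

    inside = land.inside_mask()
    # concentric equal-area rings by distance quantiles over in-boundary cells
    d_in = dist[inside]
    qs = np.quantile(d_in, np.linspace(0, 1, config.n_zones + 1)[1:-1])
    zone_in = 1 + np.searchsorted(qs, d_in, side="right")
    zone = np.zeros((nr, nc), dtype=int)
    zone[inside] = zone_in
    land.zone = zone

    # angular sectors -> contiguous provinces
    ang = np.arctan2(cy - gy, cx - gx)  # (-pi, pi]
    sector = np.floor((ang + np.pi) / (2 * np.pi) * config.n_provinces).astype(int)
    sector = np.clip(sector, 0, config.n_provinces - 1)
    province = np.zeros((nr, nc), dtype=int)
    province[inside] = sector[inside] + 1
    land.province = province
    return land


# -- plain-text raster I/O (ESRI ASCII grid) ----------------------------------

def _write_ascii_grid(path: Path, grid: np.ndarray, x0: float, y0: float, cell: float) -> None:
    nr, nc = grid.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {x0}\nyllcorner {y0}\n"
        f"cellsize {cell}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.asarray(grid, dtype=float), fmt="%.6g")


def _read_ascii_grid(path: Path):
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    return grid, header


def _dissolve_cells(mask: np.ndarray, x0: float, y0: float, cell: float, nr: int):
    rows, cols = np.nonzero(mask)
    boxes = [
        box(
            x0 + c * cell,
            y0 + (nr - r - 1) * cell,
            x0 + (c + 1) * cell,
            y0 + (nr - r) * cell,
        )
        for r, c in zip(rows, cols)
    ]
    return shapely.unary_union(boxes)
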