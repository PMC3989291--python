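"""Idealized lagoon domain: bathymetry, sectors, and broodstock maps.

The model lagoon is a saucer-shaped deep basin enclosed by an atoll rim.
Exchange with the open ocean happens through a narrow, ~11 m deep pass
and through *hoa* — reef-flat spillways a few tens of centimetres deep.
The horizontal grid is regular (square cells); the vertical is resolved
with terrain-following sigma layers tightened near the surface and the
bottom, where velocity gradients are strongest.

Spawning/destination sectors partition the deep (>= 5 m) part of the
lagoon into ``k`` patches of similar area by planar k-means on cell
centroid coordinates; near-shore cells shallower than 5 m are kept apart
as a single "shallow" compartment used only as a destination.

Broodstock (larval production) maps come in two flavours: the *natural*
stock follows a density-by-depth table (bottom-dwelling wild oysters),
while the *reared* stock sits on farming concessions at a fixed density
per hectare, suspended on longlines between 5 and 10 m depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SHALLOW",
    "NONE",
    "BOTTOM",
    "Opening",
    "LagoonGrid",
    "SectorPartition",
    "BroodstockMap",
    "default_openings",
    "build_idealized_lagoon",
    "partition_sectors",
    "natural_stock",
    "reared_stock",
    "stock_by_sector",
    "synthetic_concessions",
    "grid_to_netcdf",
    "grid_from_netcdf",
]

#: Sector label for wet cells shallower than the sector depth cutoff.
SHALLOW = 0
#: Sector label for dry (land) cells.
NONE = -1
#: Release-band sentinel: larvae emitted from the bottom sigma layer.
BOTTOM = "bottom"

#: Depth (m) below which a wet cell belongs to the shallow compartment.
SHALLOW_DEPTH_M = 5.0


class ParameterError(ValueError):
    """Invalid physical or numerical parameter."""


class ConfigurationError(ValueError):
    """Inconsistent domain configuration (e.g. stock on land)."""


@dataclass(frozen=True)
class Opening:
    """A rim opening connecting lagoon and ocean.

    Parameters
    ----------
    kind : {"pass", "hoa"}
    azimuth_deg : float
        Compass azimuth of the opening on the rim (0 = north, 90 = east).
    width_cells : int
        Number of contiguous rim cells forming the opening.
    depth_m : float
        Sill depth of the opening cells (pass ~11 m, hoa ~0.3 m).
    """

    kind: str
    azimuth_deg: float
    width_cells: int = 1
    depth_m: float | None = None

    def __post_init__(self):
        if self.kind not in ("pass", "hoa"):
            raise ParameterError(f"unknown opening kind {self.kind!r}")
        if self.width_cells < 1:
            raise ParameterError("opening width must be >= 1 cell")


def default_openings() -> list[Opening]:
    """Default rim openings: one NW pass, southern and NW hoa fields.

    The pass sits on the north-west rim (sill depth 11 m); hoa spillways
    (0.3 m deep) occupy part of the southern rim and a short north-west
    stretch, mirroring the geomorphology of deep Tuamotu lagoons.
    """
    return [
        Opening("pass", azimuth_deg=315.0, width_cells=1, depth_m=11.0),
        Opening("hoa", azimuth_deg=170.0, width_cells=3, depth_m=0.3),
        Opening("hoa", azimuth_deg=195.0, width_cells=3, depth_m=0.3),
        Opening("hoa", azimuth_deg=300.0, width_cells=2, depth_m=0.3),
    ]


@dataclass
class LagoonGrid:
    """Regular horizontal grid with sigma-layer vertical geometry.

    Attributes
    ----------
    nx, ny : int
        Cell counts in x (east) and y (north).
    dx, dy : float
        Cell size in metres.
    depth : ndarray, shape (ny, nx)
        Bathymetry in metres, >= 0; 0 marks land.
    n_sigma : int
        Number of vertical sigma layers.
    sigma_edges : ndarray, shape (n_sigma + 1,)
        Layer interface fractions, strictly increasing from 0 (surface)
        to 1 (bottom), tightened near both ends.
    boundary_cells : dict[(int, int), str]
        Open rim cells, mapping (j, i) -> "pass" | "hoa".
    """

    nx: int
    ny: int
    dx: float
    dy: float
    depth: np.ndarray
    n_sigma: int
    sigma_edges: np.ndarray
    boundary_cells: dict = field(default_factory=dict)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (self.ny, self.nx):
            raise ParameterError("depth shape does not match (ny, nx)")
        if np.any(self.depth < 0):
            raise ParameterError("depth must be >= 0")
        e = np.asarray(self.sigma_edges, dtype=float)
        if e.shape != (self.n_sigma + 1,) or e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise ParameterError("sigma_edges must increase strictly from 0 to 1")
        self.sigma_edges = e
        for (j, i), kind in self.boundary_cells.items():
            if not self.wet[j, i]:
                raise ParameterError(f"boundary cell {(j, i)} is dry")
            if kind not in ("pass", "hoa"):
                raise ParameterError(f"unknown boundary kind {kind!r}")

    # -- derived geometry ------------------------------------------------
    @property
    def cell_area(self) -> float:
        """Horizontal cell area (m^2)."""
        return self.dx * self.dy

    @property
    def wet(self) -> np.ndarray:
        """Boolean mask of wet cells."""
        return self.depth > 0.0

    @property
    def layer_fraction(self) -> np.ndarray:
        """Sigma-layer thickness fractions, shape (n_sigma,)."""
        return np.diff(self.sigma_edges)

    @property
    def wet_area(self) -> float:
        """Total wet surface area (m^2)."""
        return float(self.wet.sum()) * self.cell_area

    @property
    def volume(self) -> float:
        """Total lagoon volume (m^3)."""
        return float(np.sum(self.depth[self.wet])) * self.cell_area

    @property
    def mean_depth(self) -> float:
        """Mean depth over wet cells (m)."""
        return float(np.mean(self.depth[self.wet]))

    def cell_centroids(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n, 2) array of (x, y) centroids of cells selected by ``mask``."""
        if mask is None:
            mask = np.ones((self.ny, self.nx), bool)
        jj, ii = np.nonzero(mask)
        return np.column_stack([(ii + 0.5) * self.dx, (jj + 0.5) * self.dy])

    def layer_depths(self, j: int, i: int) -> np.ndarray:
        """Depth (m) of layer interfaces at cell (j, i), surface first."""
        return self.depth[j, i] * self.sigma_edges

    def cell_volumes(self) -> np.ndarray:
        """Per-layer cell volumes, shape (n_sigma, ny, nx) in m^3."""
        return self.layer_fraction[:, None, None] * self.depth[None, :, :] * self.cell_area


def stretched_sigma_edges(n_sigma: int, tightening: float = 0.7) -> np.ndarray:
    """Sigma interfaces tightened near surface and bottom.

    Uses the monotone map ``s - c * sin(2 pi s) / (2 pi)`` of the uniform
    fractions ``s``; ``0 <= tightening < 1`` controls how much thinner the
    surface/bottom layers are than the mid-column ones.
    """
    if n_sigma < 1:
        raise ParameterError("n_sigma must be >= 1")
    if not 0.0 <= tightening < 1.0:
        raise ParameterError("tightening must be in [0, 1)")
    s = np.linspace(0.0, 1.0, n_sigma + 1)
    return s - tightening * np.sin(2.0 * np.pi * s) / (2.0 * np.pi)


def _rim_cells(wet: np.ndarray) -> list[tuple[int, int]]:
    """Wet cells with at least one dry or out-of-grid 4-neighbour."""
    ny, nx = wet.shape
    out = []
    for j, i in zip(*np.nonzero(wet)):
        for dj, di in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jj, ii = j + dj, i + di
            if not (0 <= jj < ny and 0 <= ii < nx) or not wet[jj, ii]:
                out.append((int(j), int(i)))
                break
    return out


def build_idealized_lagoon(
    area_km2: float = 142.0,
    mean_depth_m: float = 41.0,
    max_depth_m: float = 70.0,
    n_sigma: int = 23,
    openings: list[Opening] | None = None,
    dx_m: float = 400.0,
    n_pinnacles: int = 0,
    pinnacle_seed: int = 0,
    sigma_tightening: float = 0.7,
) -> LagoonGrid:
    """Build a radially symmetric saucer-shaped lagoon grid.

    The bathymetry is ``d(r) = max_depth * (1 - (r/R)^p)`` on a disc of
    radius ``R``; ``R`` is adjusted so that the rasterized wet area
    matches ``area_km2`` and the exponent ``p`` so that the discrete mean
    wet depth matches ``mean_depth_m`` (both to well within 2 %).
    Openings are carved into the rim at the requested azimuths; optional
    seeded pinnacle perturbations roughen the smooth saucer.
    """
    if area_km2 <= 0:
        raise ParameterError("area must be positive")
    if not 0 < mean_depth_m < max_depth_m:
        raise ParameterError("need 0 < mean depth < max depth")
    if n_sigma < 3:
        raise ParameterError("need at least 3 sigma layers")

    area_m2 = area_km2 * 1e6
    cell_area = dx_m * dx_m
    r0 = np.sqrt(area_m2 / np.pi)
    half = r0 * 1.15
    n = int(np.ceil(2 * half / dx_m))
    x = (np.arange(n) + 0.5) * dx_m - n * dx_m / 2.0
    xx, yy = np.meshgrid(x, x)
    rr = np.hypot(xx, yy)

    # radius such that the wet-cell count matches the requested area
    def area_err(R):
        return np.count_nonzero(rr < R) * cell_area - area_m2

    r_lo, r_hi = 0.5 * r0, 1.1 * half
    R = brentq(area_err, r_lo, r_hi, xtol=1e-3) if area_err(r_lo) * area_err(r_hi) < 0 else r0
    inside = rr < R

    # exponent such that the discrete mean wet depth matches the target
    rel = (rr[inside] / R)

    def mean_err(p):
        return np.mean(max_depth_m * (1.0 - rel**p)) - mean_depth_m

    if mean_err(1e-3) * mean_err(1e6) >= 0:
        raise ParameterError("infeasible depth profile for the requested mean/max")
    p = brentq(mean_err, 1e-3, 1e6, xtol=1e-10)

    depth = np.zeros((n, n))
    depth[inside] = max_depth_m * (1.0 - rel**p)
    # rasterized rim cells can get depth ~0; keep every inside cell wet
    depth[inside] = np.maximum(depth[inside], 0.5)

    if n_pinnacles > 0:
        rng = np.random.default_rng(pinnacle_seed)
        jj_w, ii_w = np.nonzero(inside)
        picks = rng.choice(len(jj_w), size=n_pinnacles, replace=False)
        for k in picks:
            j, i = jj_w[k], ii_w[k]
            # pinnacles rise toward the surface but never dry the cell
            depth[j, i] = min(depth[j, i], float(rng.uniform(1.0, 10.0)))

    edges = stretched_sigma_edges(n_sigma, sigma_tightening)
    grid = LagoonGrid(nx=n, ny=n, dx=dx_m, dy=dx_m, depth=depth,
                      n_sigma=n_sigma, sigma_edges=edges)

    # carve the openings into the rim
    if openings is None:
        openings = default_openings()
    rim = _rim_cells(grid.wet)
    if rim:
        cx = cy = n * dx_m / 2.0
        rim_xy = np.array([((i + 0.5) * dx_m - cx, (j + 0.5) * dx_m - cy) for j, i in rim])
        rim_az = np.degrees(np.arctan2(rim_xy[:, 0], rim_xy[:, 1])) % 360.0
        boundary: dict = {}
        for op in openings:
            d_az = np.abs((rim_az - op.azimuth_deg + 180.0) % 360.0 - 180.0)
            order = np.argsort(d_az)
            sill = op.depth_m if op.depth_m is not None else (11.0 if op.kind == "pass" else 0.3)
            taken = 0
            for idx in order:
                cell = rim[idx]
                if cell in boundary:
                    continue
                boundary[cell] = op.kind
                depth[cell] = sill
                taken += 1
                if taken == op.width_cells:
                    break
        grid = LagoonGrid(nx=n, ny=n, dx=dx_m, dy=dx_m, depth=depth,
                          n_sigma=n_sigma, sigma_edges=edges, boundary_cells=boundary)
    return grid


@dataclass
class SectorPartition:
    """Partition of the deep lagoon into numbered sectors.

    ``sector_id`` holds, per cell, an integer in ``1..k`` for numbered
    sectors, :data:`SHALLOW` (0) for wet cells shallower than 5 m, and
    :data:`NONE` (-1) for land.
    """

    sector_id: np.ndarray
    k: int
    cell_area: float

    @property
    def sector_labels(self) -> list[int]:
        return list(range(1, self.k + 1))

    def area(self, s: int) -> float:
        """Surface area (m^2) of sector ``s``."""
        return float(np.count_nonzero(self.sector_id == s)) * self.cell_area

    def areas(self) -> dict[int, float]:
        return {s: self.area(s) for s in self.sector_labels}

    def mask(self, s: int) -> np.ndarray:
        return self.sector_id == s


def partition_sectors(grid: LagoonGrid, k: int = 12, seed: int = 0) -> SectorPartition:
    """Cluster deep wet cells into ``k`` sectors by planar k-means.

    Cells with depth >= 5 m are clustered on their (x, y) centroids
    (k-means, 10 restarts, fixed seed), which on a convex basin yields
    contiguous, similar-area Voronoi-like patches; shallower wet cells
    are labelled :data:`SHALLOW` and land :data:`NONE`.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ParameterError("k must be >= 1")
    deep = grid.wet & (grid.depth >= SHALLOW_DEPTH_M)
    n_deep = int(deep.sum())
    if n_deep < k:
        raise ParameterError(f"k={k} exceeds the {n_deep} deep wet cells")
    xy = grid.cell_centroids(deep)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(xy)
    # renumber clusters west->east by centroid x so sector ids are stable
    order = np.argsort([xy[labels == c, 0].mean() for c in range(k)])
    remap = np.empty(k, int)
    remap[order] = np.arange(1, k + 1)
    sector_id = np.full((grid.ny, grid.nx), NONE, dtype=int)
    sector_id[grid.wet] = SHALLOW
    sector_id[deep] = remap[labels]
    return SectorPartition(sector_id=sector_id, k=k, cell_area=grid.cell_area)


@dataclass
class BroodstockMap:
    """Per-cell spawner counts with the release depth band.

    ``release_band`` is either a ``(top_m, bottom_m)`` depth interval
    (reared stock on longlines) or :data:`BOTTOM` (wild bottom-dwelling
    stock emitting from the deepest sigma layer).
    """

    counts: np.ndarray
    kind: str
    release_band: tuple | str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ParameterError("spawner counts must be >= 0")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


#: Wild oyster density (oysters per 100 m^2) by depth level, from the
#: Takapoto atoll stock survey of Zanini & Salvat (2000); depth bins are
#: left-closed right-open, the last one unbounded above.
TAKAPOTO_DENSITY_TABLE: tuple[tuple[float, float, float], ...] = (
    (0.0, 10.0, 1.0),
    (10.0, 20.0, 3.6),
    (20.0, 30.0, 5.2),
    (30.0, 40.0, 8.2),
    (40.0, np.inf, 2.5),
)

#: Legal stocking ceiling on Polynesian rearing concessions (oysters/ha).
REARED_DENSITY_PER_HA = 12_000.0


def natural_stock(
    grid: LagoonGrid,
    density_table: tuple[tuple[float, float, float], ...] = TAKAPOTO_DENSITY_TABLE,
) -> BroodstockMap:
    """Wild broodstock map from a density-by-depth table.

    Per-cell count = density(depth bin, oysters / 100 m^2) x cell area.
    The wild stock is bottom-dwelling, so the release band is the bottom
    sigma layer.
    """
    counts = np.zeros((grid.ny, grid.nx))
    wet = grid.wet
    covered = np.zeros_like(wet)
    for lo, hi, dens in density_table:
        if dens < 0:
            raise ConfigurationError("densities must be >= 0")
        sel = wet & (grid.depth >= lo) & (grid.depth < hi)
        counts[sel] = dens / 100.0 * grid.cell_area
        covered |= sel
    if np.any(wet & ~covered):
        bad = float(grid.depth[wet & ~covered][0])
        raise ConfigurationError(f"depth {bad} m not covered by the density table")
    return BroodstockMap(counts=counts, kind="natural", release_band=BOTTOM)


def reared_stock(
    grid: LagoonGrid,
    concessions: np.ndarray,
    density_per_ha: float = REARED_DENSITY_PER_HA,
) -> BroodstockMap:
    """Reared broodstock on concession cells, on 5-10 m longlines."""
    if density_per_ha < 0:
        raise ParameterError("density must be >= 0")
    concessions = np.asarray(concessions, dtype=bool)
    if concessions.shape != (grid.ny, grid.nx):
        raise ConfigurationError("concession mask shape does not match the grid")
    if np.any(concessions & ~grid.wet):
        raise ConfigurationError("concession cell on land")
    counts = np.where(concessions, density_per_ha * grid.cell_area / 1e4, 0.0)
    return BroodstockMap(counts=counts, kind="reared", release_band=(5.0, 10.0))


def synthetic_concessions(
    grid: LagoonGrid,
    sectors: SectorPartition | None = None,
    n_patches: int = 8,
    patch_cells: int = 4,
    west_bias: float = 0.75,
    seed: int = 0,
) -> np.ndarray:
    """Seeded rectangular concession patches, biased to the western half.

    Mimics the clustering of rearing concessions on the sheltered western
    side of Tuamotu lagoons. Returns a boolean mask on the grid.
    """
    rng = np.random.default_rng(seed)
    deep = grid.wet & (grid.depth >= SHALLOW_DEPTH_M)
    mask = np.zeros_like(deep)
    jj, ii = np.nonzero(deep)
    west = ii < grid.nx // 2
    for _ in range(n_patches):
        pool = np.nonzero(west)[0] if rng.random() < west_bias and west.any() else np.arange(len(jj))
        c = int(rng.choice(pool))
        j0, i0 = int(jj[c]), int(ii[c])
        h = int(rng.integers(1, patch_cells + 1))
        w = int(rng.integers(1, patch_cells + 1))
        sl = (slice(max(j0 - h // 2, 0), j0 + (h + 1) // 2),
              slice(max(i0 - w // 2, 0), i0 + (w + 1) // 2))
        mask[sl] |= deep[sl]
    return mask


def stock_by_sector(stock: BroodstockMap, sectors: SectorPartition):
    """Per-sector spawner totals W_s (pandas Series indexed by sector)."""
    import pandas as pd

    if stock.counts.shape != sectors.sector_id.shape:
        raise ConfigurationError("stock map and sector partition use different grids")
    totals = {s: float(stock.counts[sectors.sector_id == s].sum()) for s in sectors.sector_labels}
    out = pd.Series(totals, name=f"W_s ({stock.kind})")
    out.index.name = "sector"
    return out


# -- NetCDF persistence ---------------------------------------------------

def grid_to_netcdf(grid: LagoonGrid, path, sectors: SectorPartition | None = None) -> None:
    """Write the grid (and optionally the sector map) to a NetCDF file."""
    import xarray as xr

    bmask = np.zeros((grid.ny, grid.nx), dtype=np.int32)
    for (j, i), kind in grid.boundary_cells.items():
        bmask[j, i] = 1 if kind == "pass" else 2
    ds = xr.Dataset(
        {
            "depth": (("y", "x"), grid.depth, {"units": "m", "long_name": "bathymetry"}),
            "boundary": (("y", "x"), bmask, {"flag_values": "0 1 2", "flag_meanings": "closed pass hoa"}),
            "sigma_edges": (("sigma_edge",), grid.sigma_edges),
        },
        coords={
            "x": ("x", (np.arange(grid.nx) + 0.5) * grid.dx, {"units": "m"}),
            "y": ("y", (np.arange(grid.ny) + 0.5) * grid.dy, {"units": "m"}),
        },
        attrs={"dx": grid.dx, "dy": grid.dy, "n_sigma": grid.n_sigma},
    )
    if sectors is not None:
        ds["sector_id"] = (("y", "x"), sectors.sector_id.astype(np.int32))
        ds.attrs["n_sectors"] = sectors.k
    ds.to_netcdf(path, engine="scipy")


def grid_from_netcdf(path) -> tuple[LagoonGrid, SectorPartition | None]:
    """Read a grid (and sector map, if present) written by :func:`grid_to_netcdf`."""
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    depth = ds["depth"].values
    bmask = ds["boundary"].values
    boundary = {}
    for j, i in zip(*np.nonzero(bmask)):
        boundary[(int(j), int(i))] = "pass" if bmask[j, i] == 1 else "hoa"
    grid = LagoonGrid(
        nx=depth.shape[1], ny=depth.shape[0],
        dx=float(ds.attrs["dx"]), dy=float(ds.attrs["dy"]),
        depth=depth, n_sigma=int(ds.attrs["n_sigma"]),
        sigma_edges=ds["sigma_edges"].values, boundary_cells=boundary,
    )
    sectors = None
    if "sector_id" in ds:
        sectors = SectorPartition(sector_id=ds["sector_id"].values.astype(int),
                                  k=int(ds.attrs["n_sectors"]), cell_area=grid.cell_area)
    return grid, sectors
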