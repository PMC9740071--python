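"""Least-cost dispersal paths on a suitability-derived resistance surface.

A habitat-suitability raster (ESRI ASCII grid, values in [0, 1], NODATA =
sea/mask) is converted to conductance ``c = max(s, floor)``; NODATA cells
are hard barriers (c = 0), distinct from merely unsuitable habitat.  Cells
become graph nodes connected under one of three neighbourhoods — von
Neumann (4), Moore (8), or king's-and-knight's moves (16, adding the eight
knight offsets) — with edge conductance the mean of the two cell
conductances divided by the inter-centre distance (grid units 1, sqrt(2),
sqrt(5), or great-circle metres when geo-correction is on).  The traversal
cost of an edge is the reciprocal of its (distance-corrected) conductance,
and least-cost paths are Dijkstra shortest paths, so a denser neighbourhood
can only shorten routes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .alignment import PopulationMap

__all__ = [
    "SuitabilityRaster",
    "TransitionGraph",
    "LCPResult",
    "read_ascii_grid",
    "write_ascii_grid",
    "suitability_to_conductance",
    "build_transition_graph",
    "least_cost_paths",
    "synthetic_raster",
]

_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_OFFSETS_8 = _OFFSETS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
_OFFSETS_16 = _OFFSETS_8 + [(-1, -2), (-1, 2), (1, -2), (1, 2),
                            (-2, -1), (-2, 1), (2, -1), (2, 1)]
OFFSETS = {4: _OFFSETS_4, 8: _OFFSETS_8, 16: _OFFSETS_16}


@dataclass(frozen=True)
class SuitabilityRaster:
    """ESRI-ASCII-style grid; row 0 is the northernmost row."""

    data: np.ndarray           # float, NaN where NODATA
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self):
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")
        vals = self.data[~np.isnan(self.data)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of a cell centre (y grows north, row 0 = north)."""
        nrows = self.data.shape[0]
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return lat, lon

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        nrows = self.data.shape[0]
        col = int((lon - self.xllcorner) // self.cellsize)
        row = nrows - 1 - int((lat - self.yllcorner) // self.cellsize)
        if not (0 <= row < nrows and 0 <= col < self.data.shape[1]):
            raise ValueError(f"coordinate ({lat}, {lon}) outside raster extent")
        return row, col


def read_ascii_grid(path) -> SuitabilityRaster:
    """Read an ESRI ASCII grid (.asc).  Supports xll/yll corner or center."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "xllcenter", "yllcenter", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    data = np.array(rows, dtype=float)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid is {data.shape}, header says "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    cs = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cs / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cs / 2)
    data[data == nodata] = np.nan
    return SuitabilityRaster(data, xll, yll, cs, nodata)


def write_ascii_grid(raster: SuitabilityRaster, path) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner}\n")
        fh.write(f"yllcorner {raster.yllcorner}\n")
        fh.write(f"cellsize {raster.cellsize}\n")
        fh.write(f"NODATA_value {raster.nodata_value}\n")
        out = np.where(np.isnan(raster.data), raster.nodata_value, raster.data)
        for row in out:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def suitability_to_conductance(raster: SuitabilityRaster,
                               floor: float = 1e-6) -> np.ndarray:
    """Conductance grid: ``max(s, floor)`` on land, 0 on NODATA/sea cells.

    Resistance is the reciprocal of conductance; the floor keeps fully
    unsuitable land traversable at very high cost, while NODATA stays
    impassable.
    """
    c = np.where(np.isnan(raster.data), 0.0, np.maximum(raster.data, floor))
    if not (c > 0).any():
        raise ValueError("all cells are impassable")
    return c


def _haversine_m(lat1, lon1, lat2, lon2) -> float:
    r = 6_371_000.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


@dataclass
class TransitionGraph:
    """Sparse cost graph over passable raster cells."""

    costs: "coo_matrix"        # CSR after construction; cost = 1 / corrected t
    shape: tuple[int, int]
    connectivity: int
    raster: SuitabilityRaster | None = None

    def node(self, row: int, col: int) -> int:
        return row * self.shape[1] + col

    def cell(self, node: int) -> tuple[int, int]:
        return divmod(node, self.shape[1])


def build_transition_graph(conductance: np.ndarray, connectivity: int = 8,
                           geo_correct: bool = False,
                           raster: SuitabilityRaster | None = None) -> TransitionGraph:
    """Weighted traversal graph from a conductance grid.

    Edge conductance is ``mean(c_i, c_j)`` divided by the inter-centre
    distance (grid units, or great-circle metres when ``geo_correct``);
    traversal cost is its reciprocal.  Cells with zero conductance get no
    edges.
    """
    if connectivity not in OFFSETS:
        raise ValueError(f"connectivity must be 4, 8 or 16, got {connectivity}")
    if geo_correct and raster is None:
        raise ValueError("geo_correct requires the source raster")
    nrows, ncols = conductance.shape
    rows_i, cols_j, weights = [], [], []
    for dr, dc in OFFSETS[connectivity]:
        r0 = max(0, -dr); r1 = min(nrows, nrows - dr)
        c0 = max(0, -dc); c1 = min(ncols, ncols - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = conductance[r0:r1, c0:c1]
        b = conductance[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        t = 0.5 * (a + b)
        passable = (a > 0) & (b > 0)
        rr, cc = np.nonzero(passable)
        rr = rr + r0
        cc = cc + c0
        if geo_correct:
            dist = np.array([
                _haversine_m(*raster.cell_center(int(r), int(c)),
                             *raster.cell_center(int(r) + dr, int(c) + dc))
                for r, c in zip(rr, cc)
            ])
        else:
            dist = math.hypot(dr, dc)
        cost = dist / t[rr - r0, cc - c0]
        rows_i.append(rr * ncols + cc)
        cols_j.append((rr + dr) * ncols + (cc + dc))
        weights.append(np.atleast_1d(cost))
    n = nrows * ncols
    if rows_i:
        i = np.concatenate(rows_i)
        j = np.concatenate(cols_j)
        w = np.concatenate(weights)
    else:
        i = j = w = np.array([])
    mat = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    return TransitionGraph(mat, (nrows, ncols), connectivity, raster)


@dataclass(frozen=True)
class LCPResult:
    source: str
    target: str
    cost: float
    path: tuple[tuple[int, int], ...]   # (row, col) cells, source -> target

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.cost)


def _snap(graph: TransitionGraph, conductance: np.ndarray,
          row: int, col: int, radius: int) -> tuple[int, int] | None:
    best, best_d = None, None
    nrows, ncols = conductance.shape
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = row + dr, col + dc
            if 0 <= r < nrows and 0 <= c < ncols and conductance[r, c] > 0:
                d = dr * dr + dc * dc
                if best_d is None or d < best_d:
                    best, best_d = (r, c), d
    return best


def least_cost_paths(graph: TransitionGraph, conductance: np.ndarray,
                     pmap: PopulationMap, snap_radius: int = 3
                     ) -> list[LCPResult]:
    """Pairwise Dijkstra least-cost paths between population locations.

    Populations are placed at their (mean) coordinates, snapped to the
    nearest passable cell within ``snap_radius`` cells; populations outside
    the extent or with no passable cell nearby yield infinite-cost results
    carrying an empty path.
    """
    raster = graph.raster
    if raster is None:
        raise ValueError("graph was built without its source raster")
    coords = pmap.coordinates()
    cells: dict[str, tuple[int, int] | None] = {}
    for _, rec in coords.iterrows():
        pop = rec["population"]
        if np.isnan(rec["lat"]) or np.isnan(rec["lon"]):
            cells[pop] = None
            continue
        try:
            row, col = raster.cell_of(rec["lat"], rec["lon"])
        except ValueError:
            cells[pop] = None
            continue
        cells[pop] = _snap(graph, conductance, row, col, snap_radius)

    pops = list(cells)
    sources = [graph.node(*cells[p]) for p in pops if cells[p] is not None]
    dist, predecessors = dijkstra(
        graph.costs, directed=False, indices=sources, return_predecessors=True
    )
    src_row = {p: k for k, p in enumerate([p for p in pops if cells[p] is not None])}

    results = []
    for a, b in itertools.combinations(pops, 2):
        if cells[a] is None or cells[b] is None:
            results.append(LCPResult(a, b, math.inf, ()))
            continue
        k = src_row[a]
        target = graph.node(*cells[b])
        cost = float(dist[k, target])
        if not math.isfinite(cost):
            results.append(LCPResult(a, b, math.inf, ()))
            continue
        path = [target]
        while path[-1] != graph.node(*cells[a]):
            path.append(int(predecessors[k, path[-1]]))
        cells_path = tuple(graph.cell(n) for n in reversed(path))
        results.append(LCPResult(a, b, cost, cells_path))
    for p in pops:  # self paths: zero cost, single cell
        if cells[p] is not None:
            results.append(LCPResult(p, p, 0.0, (cells[p],)))
    return results


def synthetic_raster(shape: tuple[int, int] = (30, 30), pattern: str = "uniform",
                     seed=None, cellsize: float = 0.05,
                     origin: tuple[float, float] = (120.0, 22.0)) -> SuitabilityRaster:
    """Deterministic toy suitability rasters for tests and demos.

    Patterns: ``uniform`` (all 1), ``gradient`` (west-east ramp),
    ``barrier`` (a zero-suitability band across the middle), ``islands``
    (high-suitability patches separated by near-zero corridors, emulating a
    sea-floor landscape with no usable dispersal route), ``random``.
    """
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    if nrows < 2 or ncols < 2:
        raise ValueError("shape must be at least 2x2")
    if pattern == "uniform":
        data = np.ones(shape)
    elif pattern == "gradient":
        data = np.tile(np.linspace(0.05, 1.0, ncols), (nrows, 1))
    elif pattern == "barrier":
        data = np.ones(shape)
        mid = nrows // 2
        data[mid, :] = 0.0
    elif pattern == "islands":
        data = np.full(shape, 1e-4)
        h, w = nrows // 3, ncols // 3
        data[:h, :w] = 1.0               # northwest island
        data[-h:, -w:] = 1.0             # southeast island
    elif pattern == "random":
        data = rng.uniform(0.01, 1.0, size=shape)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return SuitabilityRaster(data, origin[0], origin[1], cellsize)
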