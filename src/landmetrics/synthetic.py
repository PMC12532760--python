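"""Seeded synthetic land-cover time series.

Generates yearly categorical maps with the structure the downstream
analysis assumes: a persistent edge-anchored ocean mask, several land
classes arranged in spatially clustered patches (a modified-random-clusters
neutral landscape model), and gradual, spatially coherent year-to-year
transitions driven by explicit change operators.  Every changed cell is
recorded in a truth log, so tests can verify parameter recovery exactly.

The generator is fully deterministic: one global random stream seeded from
the scenario, advanced in a fixed order (ocean mask, initial map, then
operators by year and list position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .catalog import ClassCatalog, ClassDef
from .geotiff import GridGeoref, write_categorical

OPERATOR_KINDS = ("expand", "contract", "fragment", "convert")

_STRUCT8 = np.ones((3, 3), bool)
#: site-percolation threshold, square lattice with 8-neighbour (Moore)
#: connectivity; marking probabilities are scaled by it so cluster growth
#: stays subcritical over the whole cluster_density range
_PC_MOORE = 0.407
_SHIFTS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_SHIFTS8 = _SHIFTS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class ChangeOperator:
    """One land-cover change process active over a range of years.

    ``rate`` is cells per year for expand/contract/fragment and whole
    patches per year for convert.  ``region`` (row0, col0, row1, col1,
    half-open) optionally confines the changed cells to a window; ``None``
    means the whole grid.
    """

    start_year: int
    end_year: int
    kind: str
    source: int
    rate: int
    target: int | None = None
    region: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        if self.kind not in OPERATOR_KINDS:
            raise ValueError(f"unknown operator kind: {self.kind!r}")
        if self.rate < 0 or int(self.rate) != self.rate:
            raise ValueError("rate must be a non-negative integer")
        if self.kind != "expand" and self.target is None:
            raise ValueError(f"{self.kind} operator requires a target class")

    def active_in(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass
class SyntheticScenario:
    """Full specification of a synthetic land-cover series."""

    grid_rows: int
    grid_cols: int
    classes: list[tuple[int, float]]  # (land class code, target proportion)
    years: tuple[int, int]
    cell_size: float = 1.0  # km
    ocean_fraction: float = 0.0
    cluster_density: float = 0.4
    operators: list[ChangeOperator] = field(default_factory=list)
    seed: int = 0
    ocean_code: int = 0
    nodata: int = 255

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        props = [p for _, p in self.classes]
        if any(p < 0 for p in props):
            raise ValueError("class proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {sum(props)}")
        if not 0.0 <= self.ocean_fraction < 1.0:
            raise ValueError("ocean_fraction must be in [0, 1)")
        if not 0.0 < self.cluster_density < 1.0:
            raise ValueError("cluster_density must be in (0, 1)")
        if self.years[0] > self.years[1]:
            raise ValueError("years must be an ascending (first, last) pair")
        codes = [c for c, _ in self.classes]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate land class codes")
        if self.ocean_code in codes or self.nodata in codes:
            raise ValueError("land class codes collide with ocean/NoData codes")
        n_land = round(self.grid_rows * self.grid_cols * (1 - self.ocean_fraction))
        if n_land < len([p for p in props if p > 0]):
            raise ValueError("fewer land cells than land classes")
        for op in self.operators:
            if op.target in (self.ocean_code, self.nodata):
                raise ValueError("operator target cannot be ocean or NoData")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def catalog(self) -> ClassCatalog:
        defs = [ClassDef(self.ocean_code, "ocean", is_water=True, is_ocean=True,
                         is_land=False)]
        defs += [ClassDef(code, f"class_{code}") for code, _ in self.classes]
        return ClassCatalog(defs)

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "cell_size": self.cell_size,
            "classes": [{"code": c, "proportion": p} for c, p in self.classes],
            "years": list(self.years),
            "ocean_fraction": self.ocean_fraction,
            "cluster_density": self.cluster_density,
            "seed": self.seed,
            "ocean_code": self.ocean_code,
            "nodata": self.nodata,
            "operators": [
                {
                    "start_year": op.start_year,
                    "end_year": op.end_year,
                    "kind": op.kind,
                    "source": op.source,
                    "target": op.target,
                    "rate": op.rate,
                    "region": list(op.region) if op.region else None,
                }
                for op in self.operators
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        doc = yaml.safe_load(Path(path).read_text())
        ops = [
            ChangeOperator(
                start_year=o["start_year"],
                end_year=o["end_year"],
                kind=o["kind"],
                source=o["source"],
                rate=o["rate"],
                target=o.get("target"),
                region=tuple(o["region"]) if o.get("region") else None,
            )
            for o in doc.get("operators", [])
        ]
        return cls(
            grid_rows=doc["grid_rows"],
            grid_cols=doc["grid_cols"],
            classes=[(c["code"], c["proportion"]) for c in doc["classes"]],
            years=tuple(doc["years"]),
            cell_size=doc.get("cell_size", 1.0),
            ocean_fraction=doc.get("ocean_fraction", 0.0),
            cluster_density=doc.get("cluster_density", 0.4),
            operators=ops,
            seed=doc.get("seed", 0),
            ocean_code=doc.get("ocean_code", 0),
            nodata=doc.get("nodata", 255),
        )


# ---------------------------------------------------------------------------
# initial map
# ---------------------------------------------------------------------------

def _grow_ocean_mask(rows: int, cols: int, n_ocean: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Single contiguous edge-anchored ocean blob of exactly n_ocean cells,
    grown by randomized breadth-first accretion from a random edge cell."""
    mask = np.zeros((rows, cols), bool)
    if n_ocean <= 0:
        return mask
    edge = (
        [(0, c) for c in range(cols)]
        + [(rows - 1, c) for c in range(cols)]
        + [(r, 0) for r in range(1, rows - 1)]
        + [(r, cols - 1) for r in range(1, rows - 1)]
    )
    start = edge[int(rng.integers(len(edge)))]
    frontier = [start]
    in_frontier = {start}
    count = 0
    while frontier and count < n_ocean:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        r, c = frontier.pop()
        in_frontier.discard((r, c))
        if mask[r, c]:
            continue
        mask[r, c] = True
        count += 1
        for dr, dc in _SHIFTS4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and not mask[nr, nc] \
                    and (nr, nc) not in in_frontier:
                frontier.append((nr, nc))
                in_frontier.add((nr, nc))
    return mask


def generate_initial_map(scenario: SyntheticScenario,
                         rng: np.random.Generator | int | None = None) -> np.ndarray:
    """First-year map from a modified-random-clusters neutral landscape model.

    Steps: (1) grow the edge-anchored ocean mask; (2) mark land cells by
    independent Bernoulli percolation with probability cluster_density
    scaled by the 8-neighbour site-percolation threshold (~0.407), so every
    density in (0, 1) stays subcritical and cluster sizes grow smoothly
    with density instead of jumping to one spanning cluster; (3) label
    marked cells into 8-connected clusters; (4) split the unmarked land
    cells: a seeded fraction ``1 - cluster_density`` is filled i.i.d. with
    classes drawn at the target proportions (speckle), the rest attach to
    their nearest marked cell, giving each cluster a contiguous territory;
    (5) assign territories to land classes largest-first, each to the
    class with the largest remaining quota (quota = target proportion x
    territory-cell count).  Assigning whole territories rather than bare
    clusters keeps realized composition unbiased, and the density-scaled
    speckle fraction makes spatial autocorrelation increase monotonically
    with cluster_density (a pure nearest-cell fill is *most* aggregated at
    low density, when few seeds own huge territories).  Higher
    cluster_density also gives larger marked clusters.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if rng is None else rng)
    rows, cols = scenario.grid_rows, scenario.grid_cols
    n_total = rows * cols
    n_ocean = round(n_total * scenario.ocean_fraction)
    ocean = _grow_ocean_mask(rows, cols, n_ocean, rng)
    land = ~ocean

    grid = np.full((rows, cols), scenario.ocean_code, dtype=np.uint8)

    active = [(c, p) for c, p in scenario.classes if p > 0]
    if len(active) == 1:
        grid[land] = active[0][0]
        return grid

    p_mark = scenario.cluster_density * _PC_MOORE
    marked = (rng.random((rows, cols)) < p_mark) & land
    if not marked.any():
        # vanishingly small densities: seed one marked cell per class
        free = np.flatnonzero(land.ravel())
        picks = rng.choice(free, size=min(len(active), free.size), replace=False)
        marked.ravel()[picks] = True
    labels, n_clusters = ndimage.label(marked, structure=_STRUCT8)

    # speckle fill: a (1 - density) fraction of unmarked land is i.i.d.
    speckle = land & ~marked & (rng.random((rows, cols)) >= scenario.cluster_density)
    codes = np.array([c for c, _ in active])
    props = np.array([p for _, p in active])
    speckle_classes = rng.choice(codes, size=int(speckle.sum()), p=props)

    # territory: remaining land cells join their nearest marked cell's cluster
    terr_region = land & ~speckle
    _, (ir, ic) = ndimage.distance_transform_edt(~marked, return_indices=True)
    territory = labels[ir, ic]
    n_terr = int(terr_region.sum())
    terr_sizes = ndimage.sum_labels(terr_region.astype(float), territory,
                                    index=np.arange(1, n_clusters + 1))
    order = sorted(range(1, n_clusters + 1),
                   key=lambda lb: (-terr_sizes[lb - 1], lb))

    quota = {c: p * n_terr for c, p in active}
    assigned_count = {c: 0.0 for c, _ in active}
    cluster_class = np.zeros(n_clusters + 1, dtype=np.int64)
    for lb in order:
        # class with the largest remaining deficit; ties broken by list order
        best = max(active, key=lambda cp: (quota[cp[0]] - assigned_count[cp[0]],
                                           -active.index(cp)))[0]
        cluster_class[lb] = best
        assigned_count[best] += terr_sizes[lb - 1]

    # guarantee every active class holds at least one territory
    missing = [c for c, _ in active if assigned_count[c] == 0]
    if missing:
        smallest_first = sorted(order, key=lambda lb: (terr_sizes[lb - 1], lb))
        for c, lb in zip(missing, smallest_first):
            assigned_count[cluster_class[lb]] -= terr_sizes[lb - 1]
            cluster_class[lb] = c
            assigned_count[c] += terr_sizes[lb - 1]

    filled = cluster_class[territory]
    grid[terr_region] = filled[terr_region].astype(np.uint8)
    grid[speckle] = speckle_classes.astype(np.uint8)
    return grid


# ---------------------------------------------------------------------------
# change operators
# ---------------------------------------------------------------------------

def _region_mask(shape, region) -> np.ndarray:
    mask = np.zeros(shape, bool)
    if region is None:
        mask[:] = True
    else:
        r0, c0, r1, c1 = region
        mask[r0:r1, c0:c1] = True
    return mask


def _protected(grid, scenario_like) -> np.ndarray:
    return (grid == scenario_like.ocean_code) | (grid == scenario_like.nodata)


class _CandidateSet:
    """List+set combo supporting uniform seeded draws with O(1) removal."""

    def __init__(self, cells):
        self.items = list(cells)
        self.index = {c: i for i, c in enumerate(self.items)}

    def __len__(self):
        return len(self.items)

    def add(self, cell):
        if cell not in self.index:
            self.index[cell] = len(self.items)
            self.items.append(cell)

    def discard(self, cell):
        i = self.index.pop(cell, None)
        if i is None:
            return
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.index[last] = i

    def draw(self, rng) -> tuple[int, int]:
        i = int(rng.integers(len(self.items)))
        cell = self.items[i]
        self.discard(cell)
        return cell


def _initial_cells(mask: np.ndarray) -> list[tuple[int, int]]:
    rr, cc = np.nonzero(mask)
    return list(zip(rr.tolist(), cc.tolist()))


def _adjacent_to(grid, code) -> np.ndarray:
    """Cells 4-adjacent to at least one cell of ``code``."""
    m = grid == code
    adj = np.zeros_like(m)
    adj[1:, :] |= m[:-1, :]
    adj[:-1, :] |= m[1:, :]
    adj[:, 1:] |= m[:, :-1]
    adj[:, :-1] |= m[:, 1:]
    return adj


def apply_change_operator(grid: np.ndarray, op: ChangeOperator,
                          rng: np.random.Generator | int,
                          scenario: SyntheticScenario) -> tuple[np.ndarray, list]:
    """Apply one operator for one year; returns (new grid, change entries).

    Entries are ``(row, col, from_class, to_class, kind)`` tuples.  Ocean
    and NoData cells are never modified.  Conversions are drawn one cell at
    a time with the seeded generator, with candidates updated after each
    draw, so expansion produces compact accretion growth.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = grid.copy()
    rows, cols = grid.shape
    region = _region_mask(grid.shape, op.region)
    protected = _protected(grid, scenario)
    entries: list[tuple[int, int, int, int, str]] = []
    if op.rate == 0:
        return grid, entries

    if op.kind in ("contract", "fragment", "convert"):
        if not (grid == op.source).any():
            raise ValueError(f"source class {op.source} absent from grid")

    if op.kind == "expand":
        cand_mask = _adjacent_to(grid, op.source) & (grid != op.source) \
            & ~protected & region
        cands = _CandidateSet(_initial_cells(cand_mask))
        for _ in range(op.rate):
            if not len(cands):
                break
            r, c = cands.draw(rng)
            entries.append((r, c, int(grid[r, c]), op.source, op.kind))
            grid[r, c] = op.source
            for dr, dc in _SHIFTS4:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] != op.source \
                        and not protected[nr, nc] and region[nr, nc]:
                    cands.add((nr, nc))

    elif op.kind == "contract":
        src = grid == op.source
        boundary = src & _edge_adjacent_diff(grid, op.source) & region
        cands = _CandidateSet(_initial_cells(boundary))
        for _ in range(op.rate):
            if not len(cands):
                break
            r, c = cands.draw(rng)
            entries.append((r, c, op.source, op.target, op.kind))
            grid[r, c] = op.target
            for dr, dc in _SHIFTS4:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] == op.source \
                        and region[nr, nc]:
                    cands.add((nr, nc))

    elif op.kind == "fragment":
        for _ in range(op.rate):
            cut = _pick_fragment_cell(grid, op, region, rng)
            if cut is None:
                break
            r, c = cut
            entries.append((r, c, op.source, op.target, op.kind))
            grid[r, c] = op.target

    elif op.kind == "convert":
        labels, n = ndimage.label(grid == op.source, structure=_STRUCT8)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            eligible = []
            for lb in range(1, n + 1):
                cells = labels == lb
                if region[cells].all():
                    eligible.append(lb)
            eligible.sort(key=lambda lb: (sizes[lb - 1], lb))
            for lb in eligible[: op.rate]:
                rr, cc = np.nonzero(labels == lb)
                for r, c in zip(rr.tolist(), cc.tolist()):
                    entries.append((r, c, op.source, op.target, op.kind))
                    grid[r, c] = op.target

    return grid, entries


def _edge_adjacent_diff(grid, code) -> np.ndarray:
    """Cells with at least one 4-neighbour (inside the grid) of a different
    class."""
    m = grid == code
    diff = np.zeros_like(m)
    diff[1:, :] |= ~m[:-1, :]
    diff[:-1, :] |= ~m[1:, :]
    diff[:, 1:] |= ~m[:, :-1]
    diff[:, :-1] |= ~m[:, 1:]
    return diff


def _pick_fragment_cell(grid, op, region, rng):
    """A corridor/articulation cell of the source class (removal splits a
    patch), or a boundary cell when none exists; ``None`` when the class
    has no removable cell."""
    src = grid == op.source
    if not src.any():
        return None
    g = nx.Graph()
    cells = _initial_cells(src)
    g.add_nodes_from(cells)
    rows, cols = grid.shape
    for r, c in cells:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and src[nr, nc]:
                g.add_edge((r, c), (nr, nc))
    arts = [cell for cell in nx.articulation_points(g) if region[cell]]
    if arts:
        arts.sort()
        return arts[int(rng.integers(len(arts)))]
    boundary = src & _edge_adjacent_diff(grid, op.source) & region
    bcells = sorted(_initial_cells(boundary))
    if not bcells:
        return None
    return bcells[int(rng.integers(len(bcells)))]


# ---------------------------------------------------------------------------
# series generation and the truth log
# ---------------------------------------------------------------------------

LOG_COLUMNS = ["year", "row", "col", "from_class", "to_class", "operator"]


def generate_series(scenario: SyntheticScenario, initial_map=None):
    """Generate the full yearly series and its change truth log.

    Returns ``(series, log)`` where ``series`` is a
    :class:`~landmetrics.raster.CategoricalRasterSeries` and ``log`` a
    DataFrame with one row per changed cell (columns ``year, row, col,
    from_class, to_class, operator``).  Operators active in year *y* modify
    the map between *y-1* and *y*, in their listed order; the first year is
    the initial map itself — by default from :func:`generate_initial_map`,
    or an explicit ``initial_map`` array for designed experiments.
    """
    from .raster import CategoricalRasterSeries

    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    years = scenario.year_list
    if initial_map is None:
        grids = [generate_initial_map(scenario, rng)]
    else:
        initial_map = np.asarray(initial_map, dtype=np.uint8)
        if initial_map.shape != (scenario.grid_rows, scenario.grid_cols):
            raise ValueError("initial_map shape does not match scenario grid")
        grids = [initial_map.copy()]
    rows_log: list[tuple] = []
    for year in years[1:]:
        grid = grids[-1]
        for op in scenario.operators:
            if op.active_in(year):
                grid, entries = apply_change_operator(grid, op, rng, scenario)
                rows_log.extend((year, r, c, f, t, k) for r, c, f, t, k in entries)
        grids.append(grid)
    log = pd.DataFrame(rows_log, columns=LOG_COLUMNS)
    georef = GridGeoref(0.0, scenario.grid_rows * scenario.cell_size,
                        scenario.cell_size)
    series = CategoricalRasterSeries(
        years=years,
        data=np.stack(grids),
        georef=georef,
        nodata=scenario.nodata,
        catalog=scenario.catalog(),
    )
    return series, log


def replay_log(initial: np.ndarray, log: pd.DataFrame, year: int) -> np.ndarray:
    """Reconstruct the map for ``year`` by replaying logged changes onto the
    initial map.  Used to verify log completeness."""
    grid = initial.copy()
    sub = log[log["year"] <= year].sort_values(["year"], kind="stable")
    for _, e in sub.iterrows():
        grid[int(e["row"]), int(e["col"])] = int(e["to_class"])
    return grid


def write_series(series, out_dir, prefix: str = "lulc") -> list[Path]:
    """One single-band GeoTIFF per year; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, year in enumerate(series.years):
        p = out_dir / f"{prefix}_{year}.tif"
        write_categorical(p, series.data[i], series.georef, series.nodata)
        paths.append(p)
    return paths


def write_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)
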