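"""Core Cellular Potts Model: lattice, energy function, Metropolis dynamics.

The model is a 2-D lattice whose interior sites each carry a cell identity
sigma(x) in {1..N}; a one-site boundary ring (label 0) is inaccessible to
cells. Each cell has a type tau in {1..n_t}. The Hamiltonian has three
terms::

    H = sum_<x,x'> J(tau(sigma(x)), tau(sigma(x'))) * (1 - delta_{sigma(x),sigma(x')})
      + lambda * sum_i (a_i - A_tau(i))**2
      - sum_x mu(tau(sigma(x))) * C(x)

i.e. type-pair contact (surface) energy over 4-connected neighbor pairs,
a quadratic area constraint, and a chemotactic coupling of each site to
the local morphogen concentration C. Positive mu lowers the energy of a
cell sitting in high concentration, so positive-mu types are attracted
toward the morphogen source.

Dynamics are Metropolis Monte Carlo: pick a random interior site and a
random 4-neighbor, propose copying the neighbor's identity onto the site,
accept if dH <= 0 and with probability exp(-dH/T) otherwise. One Monte
Carlo step (MCS) is as many elementary attempts as there are interior
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import _kernel

__all__ = [
    "GridSpec", "Lattice", "CellTable", "PottsParams", "PottsSystem",
    "build_adhesion_matrix", "build_chemo_vector", "init_cells",
    "home_regions", "total_energy", "delta_energy", "metropolis_step",
    "apply_flip", "run_mcs", "DEFAULT_GRID", "LARGE_GRID",
]

# offsets of the four von Neumann neighbors, (dy, dx)
_NEIGHBORS = ((0, 1), (0, -1), (1, 0), (-1, 0))


@dataclass(frozen=True)
class GridSpec:
    """Rectangular tiling of the interior into equal rectangular cells.

    The full lattice adds a one-site inaccessible ring around the interior,
    so the full shape is (cells_y*cell_h + 2, cells_x*cell_w + 2).
    """

    cells_x: int = 20
    cells_y: int = 5
    cell_w: int = 7
    cell_h: int = 7

    @property
    def n_cells(self) -> int:
        return self.cells_x * self.cells_y

    @property
    def interior_shape(self) -> tuple[int, int]:
        return (self.cells_y * self.cell_h, self.cells_x * self.cell_w)

    @property
    def shape(self) -> tuple[int, int]:
        h, w = self.interior_shape
        return (h + 2, w + 2)

    @property
    def cell_area(self) -> int:
        return self.cell_w * self.cell_h

    @property
    def source_column(self) -> int:
        """Column index of the morphogen source (rightmost lattice column)."""
        return self.shape[1] - 1


#: 100 cells of 7x7 sites: interior 140x35 inside a 142x37 bounded grid,
#: morphogen source along the rightmost lattice column.
DEFAULT_GRID = GridSpec(cells_x=20, cells_y=5)

#: 210-cell variant on a larger grid (30x7 cells, 212x51 bounded grid).
LARGE_GRID = GridSpec(cells_x=30, cells_y=7)


@dataclass
class Lattice:
    """Label field sigma over the bounded grid; label 0 marks the ring."""

    labels: np.ndarray  # (H, W) int32
    n_cells: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def interior(self) -> np.ndarray:
        return self.labels[1:-1, 1:-1]

    @property
    def interior_size(self) -> int:
        h, w = self.shape
        return (h - 2) * (w - 2)

    def copy(self) -> "Lattice":
        return Lattice(self.labels.copy(), self.n_cells)


@dataclass
class CellTable:
    """Per-cell type, area and coordinate sums, kept consistent with the
    lattice by incremental updates on every accepted flip.

    Arrays are indexed by cell id 1..N; index 0 is the boundary sentinel.
    """

    types: np.ndarray  # (N+1,) int32, types[0] == 0
    areas: np.ndarray  # (N+1,) int64
    sum_x: np.ndarray  # (N+1,) int64
    sum_y: np.ndarray  # (N+1,) int64

    @property
    def n_cells(self) -> int:
        return len(self.types) - 1

    def centroids(self) -> np.ndarray:
        """(N, 2) array of (x, y) centroids of cells 1..N, in site units."""
        a = self.areas[1:].astype(float)
        out = np.empty((self.n_cells, 2))
        out[:, 0] = self.sum_x[1:] / a
        out[:, 1] = self.sum_y[1:] / a
        return out

    def copy(self) -> "CellTable":
        return CellTable(self.types.copy(), self.areas.copy(),
                         self.sum_x.copy(), self.sum_y.copy())

    @classmethod
    def from_lattice(cls, lattice: Lattice, types: np.ndarray) -> "CellTable":
        """Build the table by a full recount of the label field."""
        n = lattice.n_cells
        t = np.zeros(n + 1, dtype=np.int32)
        t[1:] = np.asarray(types, dtype=np.int32)
        areas = np.bincount(lattice.labels.ravel(), minlength=n + 1).astype(np.int64)
        areas[0] = 0
        H, W = lattice.shape
        ys, xs = np.mgrid[0:H, 0:W]
        sum_x = np.bincount(lattice.labels.ravel(), weights=xs.ravel(),
                            minlength=n + 1).astype(np.int64)
        sum_y = np.bincount(lattice.labels.ravel(), weights=ys.ravel(),
                            minlength=n + 1).astype(np.int64)
        sum_x[0] = sum_y[0] = 0
        return cls(t, areas, sum_x, sum_y)

    def check_consistent(self, lattice: Lattice) -> None:
        """Raise if the incremental bookkeeping disagrees with a recount."""
        ref = CellTable.from_lattice(lattice, self.types[1:])
        if not np.array_equal(ref.areas, self.areas):
            raise RuntimeError("cell area bookkeeping inconsistent with lattice")
        if not (np.array_equal(ref.sum_x, self.sum_x)
                and np.array_equal(ref.sum_y, self.sum_y)):
            raise RuntimeError("cell centroid bookkeeping inconsistent with lattice")


@dataclass
class PottsParams:
    """Energy-function parameters.

    lam : strength of the quadratic area constraint (energy / site^2)
    T : fluctuation temperature (energy); amplitude of membrane fluctuation
    a_target : target area per type, (n_t+1,) with index 0 unused
    J : (n_t+1, n_t+1) symmetric contact energy; row/col 0 is the boundary
    mu : (n_t+1,) chemotactic potential per type; mu[0] = 0
    """

    J: np.ndarray
    mu: np.ndarray
    lam: float = 0.2
    T: float = 1.0
    a_target: Union[float, np.ndarray] = 49.0
    n_t: int = 4

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.J.shape != (self.n_t + 1, self.n_t + 1):
            raise ValueError("J must be (n_t+1) x (n_t+1) including the boundary row")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if self.mu.shape != (self.n_t + 1,):
            raise ValueError("mu must have length n_t+1 (index 0 = boundary)")
        if np.isscalar(self.a_target) or np.ndim(self.a_target) == 0:
            self.a_target = np.full(self.n_t + 1, float(self.a_target))
        else:
            self.a_target = np.asarray(self.a_target, dtype=float)

    @classmethod
    def default(cls, j: float = 0.0, mu0: float = 0.0,
                j_mode: str = "graded", mu_mode: str = "bipolar",
                n_t: int = 4, **kw) -> "PottsParams":
        return cls(J=build_adhesion_matrix(j, mode=j_mode, n_t=n_t),
                   mu=build_chemo_vector(mu0, mode=mu_mode, n_t=n_t),
                   n_t=n_t, **kw)


@dataclass
class PottsSystem:
    """A runnable simulation state: lattice + cells + params + morphogen."""

    lattice: Lattice
    cells: CellTable
    params: PottsParams
    field: object  # (H, W) ndarray, or an object with .concentration/.advance

    @property
    def concentration(self) -> np.ndarray:
        f = self.field
        return f if isinstance(f, np.ndarray) else f.concentration

    def copy(self) -> "PottsSystem":
        f = self.field
        return PottsSystem(self.lattice.copy(), self.cells.copy(),
                           self.params, f.copy() if isinstance(f, np.ndarray) else f)


def build_adhesion_matrix(j: float, mode: str = "graded", n_t: int = 4,
                          j_same: float = 1.0, j_bnd: float = 1.0) -> np.ndarray:
    """Type-pair contact energy matrix implementing differential adhesion.

    In ``graded`` mode unlike-type contact costs grow with the type
    distance, J(tau, tau') = j_same + j*|tau - tau'|, reflecting that types
    ending up farther apart after sorting are less adhesive to each other.
    In ``uniform`` mode every unlike pair costs j_same + j (cells dislike
    all other types equally). Like-type contact costs j_same; contact with
    the inaccessible boundary ring costs j_bnd (row/column 0).
    """
    if j < 0:
        raise ValueError("differential adhesion magnitude j must be >= 0")
    if n_t < 2:
        raise ValueError("need at least two cell types")
    if mode not in ("graded", "uniform"):
        raise ValueError(f"unknown adhesion mode {mode!r}")
    J = np.full((n_t + 1, n_t + 1), j_same, dtype=float)
    if mode == "graded":
        taus = np.arange(1, n_t + 1)
        J[1:, 1:] = j_same + j * np.abs(taus[:, None] - taus[None, :])
    else:
        J[1:, 1:] = j_same + j * (1 - np.eye(n_t))
    J[0, :] = j_bnd
    J[:, 0] = j_bnd
    J[0, 0] = 0.0  # boundary-boundary pairs share label 0 and never contribute
    return J


def build_chemo_vector(mu0: float, mode: str = "bipolar", n_t: int = 4) -> np.ndarray:
    """Chemotactic potential per type (index 0 = boundary, always 0).

    ``bipolar``: low types repelled, high types attracted, antisymmetric
    and evenly graded, e.g. mu0*(-2, -1, +1, +2) for four types.
    ``attract_only``: all types attracted with graded strength mu0*(1..n_t).
    ``repel_only``: all types repelled, mu0*(-n_t..-1). In every mode mu is
    strictly increasing with type index, so the sorted order away from the
    source is n_t | ... | 2 | 1.
    """
    if mu0 < 0:
        raise ValueError("chemotactic magnitude mu0 must be >= 0")
    mu = np.zeros(n_t + 1)
    if mode == "bipolar":
        half = n_t // 2
        offsets = np.concatenate([np.arange(-half, 0),
                                  np.arange(1, n_t - half + 1)])
        mu[1:] = mu0 * offsets
    elif mode == "attract_only":
        mu[1:] = mu0 * np.arange(1, n_t + 1)
    elif mode == "repel_only":
        mu[1:] = mu0 * np.arange(-n_t, 0)
    else:
        raise ValueError(f"unknown chemotaxis mode {mode!r}")
    return mu


def home_regions(grid: GridSpec, n_t: int = 4) -> np.ndarray:
    """Home region (1..n_t) of each cell in the row-major tiling.

    The interior is divided into n_t contiguous equal-width bands along x
    (the morphogen-gradient direction); region n_t is nearest the source.
    """
    if grid.cells_x % n_t:
        raise ValueError("cells_x must be divisible by the number of regions")
    per = grid.cells_x // n_t
    cols = np.arange(grid.n_cells) % grid.cells_x
    return (cols // per + 1).astype(np.int32)


def init_cells(grid: GridSpec, fates: Sequence[int]) -> tuple[Lattice, CellTable]:
    """Tile the interior with equal rectangular cells and attach fates.

    Cells are numbered 1..N row-major (cell id 1 at the top-left tile).
    """
    fates = np.asarray(fates, dtype=np.int32)
    if fates.shape != (grid.n_cells,):
        raise ValueError(f"expected {grid.n_cells} fates, got {fates.shape}")
    H, W = grid.shape
    labels = np.zeros((H, W), dtype=np.int32)
    tile_rows = np.repeat(np.arange(grid.cells_y), grid.cell_h)
    tile_cols = np.repeat(np.arange(grid.cells_x), grid.cell_w)
    labels[1:-1, 1:-1] = (tile_rows[:, None] * grid.cells_x
                          + tile_cols[None, :] + 1)
    lattice = Lattice(labels, grid.n_cells)
    cells = CellTable.from_lattice(lattice, fates)
    return lattice, cells


def _field_array(field) -> np.ndarray:
    if field is None:
        raise ValueError("a concentration field (possibly all-zero) is required")
    return field if isinstance(field, np.ndarray) else field.concentration


def total_energy(lattice: Lattice, cells: CellTable, params: PottsParams,
                 field, validate: bool = False) -> float:
    """Full Hamiltonian of the current configuration.

    Neighbor pairs are counted once over the 4-connected grid; contacts
    with the boundary ring use the boundary row of J. With ``validate``
    the incremental bookkeeping is checked against a full recount first.
    """
    if validate:
        cells.check_consistent(lattice)
    C = _field_array(field)
    lab = lattice.labels
    t = cells.types[lab]
    e = 0.0
    for a, b, ta, tb in (
        (lab[:, :-1], lab[:, 1:], t[:, :-1], t[:, 1:]),
        (lab[:-1, :], lab[1:, :], t[:-1, :], t[1:, :]),
    ):
        m = a != b
        e += params.J[ta[m], tb[m]].sum()
    diff = cells.areas[1:] - params.a_target[cells.types[1:]]
    e += params.lam * float(diff @ diff)
    ti = t[1:-1, 1:-1]
    e -= float((params.mu[ti] * C[1:-1, 1:-1]).sum())
    return float(e)


def delta_energy(lattice: Lattice, cells: CellTable, params: PottsParams,
                 field, site: tuple[int, int], neighbor: tuple[int, int]) -> float:
    """Energy change of copying sigma(neighbor) onto ``site``, computed
    locally from the terms that touch the site.

    ``site`` and ``neighbor`` are (y, x) index pairs; the site must be
    interior and the neighbor one of its four von Neumann neighbors.
    """
    y, x = site
    H, W = lattice.shape
    if not (1 <= y < H - 1 and 1 <= x < W - 1):
        raise ValueError("site must be interior")
    ny, nx = neighbor
    if (abs(ny - y) + abs(nx - x)) != 1:
        raise ValueError("neighbor must be one of the four von Neumann neighbors")
    lab = lattice.labels
    s_old = lab[y, x]
    s_src = lab[ny, nx]
    if s_src == s_old:
        return 0.0
    if s_src == 0:
        raise ValueError("the boundary ring has no cell identity to copy")
    C = _field_array(field)
    t_old = cells.types[s_old]
    t_src = cells.types[s_src]
    de = 0.0
    for dy, dx in _NEIGHBORS:
        sn = lab[y + dy, x + dx]
        tn = cells.types[sn]
        if sn != s_old:
            de -= params.J[t_old, tn]
        if sn != s_src:
            de += params.J[t_src, tn]
    ao = float(cells.areas[s_old])
    asrc = float(cells.areas[s_src])
    Ao = params.a_target[t_old]
    As = params.a_target[t_src]
    de += params.lam * ((ao - 1 - Ao) ** 2 - (ao - Ao) ** 2
                        + (asrc + 1 - As) ** 2 - (asrc - As) ** 2)
    de -= (params.mu[t_src] - params.mu[t_old]) * C[y, x]
    return float(de)


def apply_flip(lattice: Lattice, cells: CellTable,
               site: tuple[int, int], new_label: int) -> None:
    """Set sigma(site) = new_label, updating areas and centroid sums."""
    y, x = site
    old = lattice.labels[y, x]
    if old == new_label:
        return
    lattice.labels[y, x] = new_label
    cells.areas[old] -= 1
    cells.areas[new_label] += 1
    cells.sum_x[old] -= x
    cells.sum_x[new_label] += x
    cells.sum_y[old] -= y
    cells.sum_y[new_label] += y


def metropolis_step(lattice: Lattice, cells: CellTable, params: PottsParams,
                    field, rng: np.random.Generator,
                    site: Optional[tuple[int, int]] = None,
                    neighbor: Optional[tuple[int, int]] = None,
                    allow_vanish: bool = False) -> bool:
    """One elementary copy attempt; returns True if accepted.

    A uniform random interior site and a uniform random 4-neighbor are
    chosen unless given explicitly (useful for tests). Copies from the
    boundary ring are rejected, as are (by default) flips that would
    reduce a cell to zero area.
    """
    H, W = lattice.shape
    if site is None:
        site = (int(rng.integers(1, H - 1)), int(rng.integers(1, W - 1)))
    if neighbor is None:
        dy, dx = _NEIGHBORS[int(rng.integers(4))]
        neighbor = (site[0] + dy, site[1] + dx)
    s_old = lattice.labels[site]
    s_src = lattice.labels[neighbor]
    if s_src == s_old:
        return True  # no-op copy, dH = 0
    if s_src == 0:
        return False
    if not allow_vanish and cells.areas[s_old] <= 1:
        return False
    de = delta_energy(lattice, cells, params, field, site, neighbor)
    if de <= 0 or rng.random() < np.exp(-de / params.T):
        apply_flip(lattice, cells, site, int(s_src))
        return True
    return False


def run_mcs(system: PottsSystem, n_mcs: int, cadence: int = 100,
            seed: int = 0,
            schedule: Optional[Sequence[tuple[int, PottsParams]]] = None,
            allow_vanish: bool = False,
            snapshot_times: Optional[Sequence[int]] = None,
            progress: Optional[Callable[[int], None]] = None):
    """Run ``n_mcs`` Monte Carlo steps and record a :class:`RunTrace`.

    One MCS is (interior site count) elementary attempts. Cluster count
    and per-cell centroid/area snapshots are recorded at t=0 and every
    ``cadence`` MCS. If the field is a time-evolving (noisy) field it is
    advanced by one step per MCS. ``schedule`` is an optional list of
    (t_mcs, PottsParams) pairs switching the parameters at the given MCS
    (the delayed-adhesion protocol).
    """
    from .metrics import RunTrace, count_clusters  # deferred: metrics imports us

    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    schedule = sorted(schedule or [], key=lambda s: s[0])
    for t_sw, _ in schedule:
        if not (0 <= t_sw <= n_mcs):
            raise ValueError("schedule times must lie in [0, n_mcs]")
    sched_times = [int(t_sw) for t_sw, _ in schedule] or None

    lattice, cells, params = system.lattice, system.cells, system.params
    dynamic = not isinstance(system.field, np.ndarray)
    n_attempts = lattice.interior_size

    rng_state = _kernel.rng_state(int(seed))

    times, n_cl, cents, areas = [], [], [], []
    snap_at = {int(t) for t in (snapshot_times or ())}
    snaps: dict[int, np.ndarray] = {}

    def record(t):
        times.append(t)
        n_cl.append(count_clusters(lattice, cells))
        cents.append(cells.centroids())
        areas.append(cells.areas[1:].copy())
        if t in snap_at:
            snaps[t] = lattice.labels.copy()

    # apply any switch scheduled at t=0
    while schedule and schedule[0][0] == 0:
        params = schedule.pop(0)[1]
    record(0)
    accepted = 0
    t = 0
    while t < n_mcs:
        # advance one MCS at a time if the field evolves, otherwise jump
        # to the next record / parameter-switch boundary in one kernel call
        next_stop = min(
            ((t // cadence) + 1) * cadence,
            n_mcs,
            schedule[0][0] if schedule else n_mcs,
        )
        block = 1 if dynamic else next_stop - t
        C = system.field if isinstance(system.field, np.ndarray) \
            else system.field.concentration
        acc, _ = _kernel.sweep(
            lattice.labels, cells.types, cells.areas, cells.sum_x,
            cells.sum_y, params.J, params.mu, params.lam, params.T,
            params.a_target, C, block * n_attempts, allow_vanish,
            rng_state)
        accepted += acc
        if dynamic:
            system.field.advance(1)
        t += block
        while schedule and schedule[0][0] <= t:
            params = schedule.pop(0)[1]
        if t % cadence == 0 or t == n_mcs:
            if t != times[-1]:
                record(t)
        if progress is not None:
            progress(t)
    system.params = params
    return RunTrace(
        times=np.asarray(times, dtype=np.int64),
        n_clusters=np.asarray(n_cl, dtype=np.int64),
        centroids=np.asarray(cents),
        areas=np.asarray(areas, dtype=np.int64),
        cadence=cadence,
        n_t=params.n_t,
        types=cells.types[1:].copy(),
        seed=int(seed),
        accepted=int(accepted),
        meta={"n_mcs": int(n_mcs), "schedule": sched_times},
        snapshots=snaps,
    )
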