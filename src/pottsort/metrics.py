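"""Quantitative read-outs of sorting performance.

A *cluster* is a connected group of same-type cells; a run is *correct*
when the cluster count reaches the number of cell types n_t at some
recorded time, and a correct run is *stable* when the count stays at n_t
from the sorting time t_s to the end of the run. Ensemble summaries
report the fraction of correct runs F_C, the fraction of stable runs
among correct runs F_S, and the distribution of sorting times.

Cluster counting operates on the cell-adjacency graph: two cells are
adjacent iff any of their sites are 4-neighbors, and a cluster is a
connected component of the graph restricted to same-type edges. A
transient single-site protrusion of a cell into a foreign band therefore
does not create a new cluster (it remains part of its cell) — at zero
differential adhesion, where type interfaces carry no line tension and
interdigitate freely at the site scale, a site-level count would register
spurious breakups at almost every record. A site-level flood-fill count
over type labels is also provided; the two agree whenever every cell is
a connected domain, which the tests exploit as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import sem as _sem, spearmanr, ttest_ind

from .lattice_core import CellTable, Lattice, PottsSystem

__all__ = [
    "RunTrace", "EnsembleSummary", "count_clusters",
    "count_clusters_sites", "classify_run", "summarize_ensemble",
    "size_variation", "cell_speeds", "cluster_lifetimes", "merging_time",
    "initial_cluster_stats",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class RunTrace:
    """Time series recorded during a run at a fixed cadence.

    times, n_clusters : per-record MCS time and cluster count
    centroids : (n_records, N, 2) per-cell (x, y) centroids
    areas : (n_records, N) per-cell areas in sites
    types : (N,) cell types (fixed over a run)
    """

    times: np.ndarray
    n_clusters: np.ndarray
    centroids: np.ndarray
    areas: np.ndarray
    cadence: int
    n_t: int
    types: np.ndarray
    seed: int = 0
    accepted: int = 0
    meta: dict = dc_field(default_factory=dict)
    #: optional label-field copies captured at requested times (not
    #: persisted by save/load; used for snapshot rendering)
    snapshots: dict = dc_field(default_factory=dict)

    @property
    def t_end(self) -> int:
        return int(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one row per record (mcs, n_clusters, per-type
        mean area)."""
        cols = {"mcs": self.times, "n_clusters": self.n_clusters}
        for tau in range(1, self.n_t + 1):
            m = self.types == tau
            cols[f"mean_area_type{tau}"] = (
                self.areas[:, m].mean(axis=1) if m.any()
                else np.full(len(self.times), np.nan))
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Persist as a .npz archive (plus a CSV summary next to it)."""
        path = Path(path)
        np.savez(path,
                 times=self.times, n_clusters=self.n_clusters,
                 centroids=self.centroids, areas=self.areas,
                 types=self.types,
                 cadence=self.cadence, n_t=self.n_t, seed=self.seed,
                 accepted=self.accepted)
        self.to_frame().to_csv(path.with_suffix(".csv"), index=False)

    @classmethod
    def load(cls, path) -> "RunTrace":
        z = np.load(Path(path))
        return cls(times=z["times"], n_clusters=z["n_clusters"],
                   centroids=z["centroids"], areas=z["areas"],
                   types=z["types"], cadence=int(z["cadence"]),
                   n_t=int(z["n_t"]), seed=int(z["seed"]),
                   accepted=int(z["accepted"]))


@dataclass
class EnsembleSummary:
    """Correct/stable fractions and sorting-time statistics of an ensemble."""

    n_runs: int
    n_correct: int
    n_stable: int
    sorting_times: np.ndarray  # t_s of the correct runs, in MCS

    @property
    def f_correct(self) -> float:
        return self.n_correct / self.n_runs

    @property
    def f_stable(self) -> Optional[float]:
        """Fraction of stable runs among correct runs; None when no run
        sorted correctly (the quantity is then undefined)."""
        if self.n_correct == 0:
            return None
        return self.n_stable / self.n_correct

    @property
    def mean_sorting_time(self) -> float:
        return float(np.mean(self.sorting_times)) if self.n_correct else np.nan

    @property
    def sem_sorting_time(self) -> float:
        if self.n_correct < 2:
            return np.nan
        return float(_sem(self.sorting_times))


def count_clusters(lattice: Lattice, cells: CellTable) -> int:
    """Number of same-type clusters: connected components of the
    cell-adjacency graph restricted to same-type edges (cells adjacent
    iff any of their sites are 4-neighbors)."""
    lab = lattice.labels
    pairs = []
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        pairs.append(np.stack([a[m], b[m]], axis=1))
    pairs = np.concatenate(pairs, axis=0)
    same = cells.types[pairs[:, 0]] == cells.types[pairs[:, 1]]
    pairs = pairs[same] - 1
    n = cells.n_cells
    g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                   shape=(n, n))
    ncomp, _ = connected_components(g, directed=False)
    return int(ncomp)


def count_clusters_sites(lattice: Lattice, cells: CellTable) -> int:
    """Site-level cluster count: flood fill of the type-label field under
    4-connectivity. Agrees with :func:`count_clusters` whenever no cell
    is fragmented; used as an independent oracle in the tests."""
    types = cells.types[lattice.labels]
    total = 0
    for tau in range(1, int(cells.types.max()) + 1):
        _, k = ndimage.label(types == tau, structure=_CROSS)
        total += k
    return total


def classify_run(trace: RunTrace, n_t: Optional[int] = None,
                 t_gate: int = 0) -> tuple[bool, bool, Optional[int]]:
    """(correct, stable, t_s) for one run.

    correct: the cluster count equals n_t at some recorded time strictly
    after t_gate (t_gate = 500 MCS for the delayed-adhesion protocol,
    0 otherwise). t_s is the earliest such time. stable: correct and the
    count stays at n_t for every recorded time in [t_s, t_end].
    """
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    n_t = trace.n_t if n_t is None else n_t
    ok = (trace.times > t_gate) & (trace.n_clusters == n_t)
    if not ok.any():
        return False, False, None
    i = int(np.argmax(ok))
    t_s = int(trace.times[i])
    stable = bool((trace.n_clusters[i:] == n_t).all())
    return True, stable, t_s


def summarize_ensemble(traces: Sequence[RunTrace], n_t: Optional[int] = None,
                       t_gate: int = 0) -> EnsembleSummary:
    """Pool runs into F_C, F_S and sorting-time statistics."""
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    n_correct = n_stable = 0
    ts = []
    for tr in traces:
        correct, stable, t_s = classify_run(tr, n_t, t_gate)
        n_correct += correct
        n_stable += stable
        if correct:
            ts.append(t_s)
    return EnsembleSummary(n_runs=len(traces), n_correct=n_correct,
                           n_stable=n_stable,
                           sorting_times=np.asarray(ts, dtype=float))


def size_variation(cells: CellTable, population: bool = True) -> float:
    """Coefficient of variation of the per-type mean cell areas,
    std({A_bar_tau}) / mean({A_bar_tau}).

    Uses the population standard deviation over the n_t type means by
    default (sample std with ``population=False``).
    """
    n_t = int(cells.types[1:].max())
    means = []
    for tau in range(1, n_t + 1):
        m = cells.types[1:] == tau
        if not m.any():
            raise ValueError(f"no cells of type {tau} present")
        means.append(cells.areas[1:][m].mean())
    means = np.asarray(means, dtype=float)
    return float(means.std(ddof=0 if population else 1) / means.mean())


def cell_speeds(trace: RunTrace, window: int = 100) -> np.ndarray:
    """Per-cell mean speed: Euclidean centroid displacement per ``window``
    MCS, averaged over the trace (sites per window)."""
    if window % trace.cadence:
        raise ValueError("trace cadence must divide the speed window")
    stride = window // trace.cadence
    c = trace.centroids[::stride]
    if len(c) < 2:
        raise ValueError("trace too short for the requested window")
    disp = np.linalg.norm(np.diff(c, axis=0), axis=2)
    return disp.mean(axis=0)


def cluster_lifetimes(trace: RunTrace, n_t: Optional[int] = None) -> np.ndarray:
    """Durations (MCS) of maximal intervals with the correct cluster count.

    An interval spanning records t_a..t_b has lifetime t_b - t_a + cadence
    (a single isolated record counts one cadence).
    """
    n_t = trace.n_t if n_t is None else n_t
    ok = trace.n_clusters == n_t
    lifetimes = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            lifetimes.append(trace.times[i - 1] - trace.times[start]
                             + trace.cadence)
            start = None
    if start is not None:
        lifetimes.append(trace.times[-1] - trace.times[start] + trace.cadence)
    return np.asarray(lifetimes, dtype=float)


def merging_time(make_system: Callable[[int], tuple[PottsSystem, int, float]],
                 n_runs: int = 100, horizon: int = 5000,
                 base_seed: int = 0) -> tuple[float, np.ndarray, int]:
    """Mean first time for a marked cell's centroid to cross a boundary line.

    ``make_system(seed)`` must return (system, marked_cell_id, boundary_x);
    the marked cell crosses rightward (toward its own type's block in the
    16-cell fixture), i.e. the crossing condition is centroid_x >=
    boundary_x, checked after every MCS. A cell initialized past the line
    crosses at time 0. Runs that never cross within ``horizon`` are capped
    at the horizon and excluded from the mean; their count is returned.

    Returns (mean_crossing_time, per-run times, n_capped).
    """
    from . import _kernel

    times = np.empty(n_runs)
    capped = 0
    for run in range(n_runs):
        system, marked, boundary_x = make_system(base_seed + run)
        lattice, cells, params = system.lattice, system.cells, system.params
        C = system.concentration
        n_attempts = lattice.interior_size
        state = _kernel.rng_state(base_seed + run)
        t_cross = None
        if cells.sum_x[marked] / cells.areas[marked] >= boundary_x:
            t_cross = 0
        t = 0
        while t_cross is None and t < horizon:
            _kernel.sweep(lattice.labels, cells.types, cells.areas,
                          cells.sum_x, cells.sum_y, params.J, params.mu,
                          params.lam, params.T, params.a_target, C,
                          n_attempts, False, state)
            t += 1
            if cells.sum_x[marked] / cells.areas[marked] >= boundary_x:
                t_cross = t
        if t_cross is None:
            capped += 1
            t_cross = horizon
        times[run] = t_cross
    if capped:
        warnings.warn(f"{capped}/{n_runs} runs never crossed within the "
                      f"{horizon}-MCS horizon; capped and excluded from the "
                      "mean", stacklevel=2)
    ok = times < horizon if capped else np.ones(n_runs, bool)
    mean = float(times[ok].mean()) if ok.any() else float("nan")
    return mean, times, capped


def initial_cluster_stats(runs: pd.DataFrame,
                          min_group: int = 2,
                          min_correct: int = 3) -> pd.DataFrame:
    """Per-(mu0, j) tests of whether the initial cluster count predicts
    the sorting outcome.

    ``runs`` needs columns mu0, j, initial_n_clusters, correct, t_s.
    For each parameter pair: a two-sample t-test comparing the initial
    cluster counts of correct vs incorrect runs (requires at least
    ``min_group`` runs in each group) and a Spearman correlation of the
    initial cluster count with the sorting time over correct runs
    (requires at least ``min_correct`` correct runs). Pairs failing a gate
    are flagged untestable for that test.
    """
    rows = []
    for (mu0, j), g in runs.groupby(["mu0", "j"]):
        corr = g[g["correct"]]
        inc = g[~g["correct"]]
        row = {"mu0": mu0, "j": j,
               "n_correct": len(corr), "n_incorrect": len(inc),
               "ttest_p": np.nan, "ttest_testable": False,
               "spearman_rho": np.nan, "spearman_p": np.nan,
               "spearman_testable": False}
        if len(corr) >= min_group and len(inc) >= min_group:
            row["ttest_p"] = float(ttest_ind(
                corr["initial_n_clusters"], inc["initial_n_clusters"]).pvalue)
            row["ttest_testable"] = True
        if len(corr) >= min_correct:
            rho, p = spearmanr(corr["initial_n_clusters"], corr["t_s"])
            row["spearman_rho"], row["spearman_p"] = float(rho), float(p)
            row["spearman_testable"] = True
        rows.append(row)
    return pd.DataFrame(rows)
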