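"""Minimum-set spatial conservation prioritization by simulated annealing.

Every grid cell is a planning unit (PU) with a cost (from the
human-footprint-like surface) and a status: available (0), locked in (1,
overlaps the existing PA network) or locked out (2, within 5 km of a town
and not locked in).  Each species is a conservation feature whose amount in
a PU is the cell area it occupies; its target is a tiered fraction of its
total range area:

* range <= 1,000 km²  → 100% of the range,
* 1,000 < range <= 10,000 km² → 30%,
* range > 10,000 km² → 10%.

A candidate reserve S is scored by the minimum-set objective

    obj(S) = sum of PU costs in S
           + blm * boundary_length(S)
           + spf * sum over features of max(0, target - held(S))

with boundary length the total length of edges between a selected cell and
an unselected (or exterior) cell under rook adjacency, and the shortfall in
amount units (km²).  Simulated annealing proposes single-PU flips of
available units, accepting uphill moves with probability exp(-delta/T) under
a geometric cooling schedule; a portfolio of runs yields the best solution
and a per-PU selection frequency (the irreplaceability proxy).

Anselin's Local Moran's I with conditional permutation classifies cells of
the selection-frequency (or any) map into high-high / low-low clusters and
high-low / low-high outliers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import BinaryRange, GridSpec
from .synth import SettlementSet

__all__ = [
    "AVAILABLE",
    "LOCKED_IN",
    "LOCKED_OUT",
    "tier_target",
    "PlanningProblem",
    "build_problem",
    "SAParams",
    "Solution",
    "objective",
    "anneal",
    "run_portfolio",
    "PrioritizationResults",
    "blm_sweep",
    "LocalMoranResult",
    "local_morans_i",
    "overlap_cpas",
    "write_marxan_inputs",
    "read_marxan_inputs",
]

AVAILABLE, LOCKED_IN, LOCKED_OUT = 0, 1, 2


def tier_target(range_area_km2: float) -> float:
    """Tiered conservation-target fraction of a species' range area."""
    if range_area_km2 <= 0:
        raise ValueError("range area must be positive")
    if range_area_km2 <= 1000:
        return 1.0
    if range_area_km2 <= 10_000:
        return 0.30
    return 0.10


# ---------------------------------------------------------------------------
# the planning problem (model object)
# ---------------------------------------------------------------------------

class PlanningProblem:
    """Planning-unit table plus the feature (species) amount matrix.

    Usually built with :func:`build_problem`; the explicit constructor
    accepts arbitrary per-PU costs/statuses and per-feature amounts so small
    hand-made instances (used by the brute-force oracle) share the same code
    path as landscape-scale ones.
    """

    def __init__(
        self,
        grid: GridSpec,
        cost: np.ndarray,
        status: np.ndarray,
        feature_ids: list[str],
        feature_pus: list[np.ndarray],
        feature_amounts: list[np.ndarray],
        targets: np.ndarray,
    ):
        n = grid.n_cells
        self.grid = grid
        self.cost = np.asarray(cost, dtype=float).ravel()
        self.status = np.asarray(status, dtype=int).ravel()
        if len(self.cost) != n or len(self.status) != n:
            raise ValueError("cost/status length must equal the PU count")
        if (self.cost < 0).any():
            raise ValueError("PU costs must be non-negative")
        self.feature_ids = list(feature_ids)
        self.feature_pus = [np.asarray(p, dtype=int) for p in feature_pus]
        self.feature_amounts = [np.asarray(a, dtype=float) for a in feature_amounts]
        self.targets = np.asarray(targets, dtype=float)
        self.n_pu = n
        self.n_features = len(self.feature_ids)

        self.total_amounts = np.array(
            [a.sum() for a in self.feature_amounts], dtype=float
        )
        # achievable amount once locked-out PUs are excluded
        achievable = np.array(
            [
                a[self.status[p] != LOCKED_OUT].sum()
                for p, a in zip(self.feature_pus, self.feature_amounts)
            ]
        )
        self.infeasible = achievable < self.targets - 1e-9

        # per-PU sparse feature lists for incremental objective updates
        self.pu_features: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for f, (pus, amts) in enumerate(zip(self.feature_pus, self.feature_amounts)):
            for p, a in zip(pus, amts):
                self.pu_features[p].append((f, a))

        # rook neighbours (for boundary deltas)
        nr, nc = grid.shape
        idx = np.arange(n).reshape(nr, nc)
        self.neighbors: list[np.ndarray] = []
        for r in range(nr):
            for c in range(nc):
                nbr = []
                if r > 0:
                    nbr.append(idx[r - 1, c])
                if r < nr - 1:
                    nbr.append(idx[r + 1, c])
                if c > 0:
                    nbr.append(idx[r, c - 1])
                if c < nc - 1:
                    nbr.append(idx[r, c + 1])
                self.neighbors.append(np.array(nbr, dtype=int))

    @property
    def locked_in(self) -> np.ndarray:
        return np.flatnonzero(self.status == LOCKED_IN)

    @property
    def locked_out(self) -> np.ndarray:
        return np.flatnonzero(self.status == LOCKED_OUT)

    @property
    def available(self) -> np.ndarray:
        return np.flatnonzero(self.status == AVAILABLE)

    def held_amounts(self, selected: np.ndarray) -> np.ndarray:
        """Amount of each feature inside the selected set."""
        selected = np.asarray(selected, dtype=bool)
        return np.array(
            [
                a[selected[p]].sum()
                for p, a in zip(self.feature_pus, self.feature_amounts)
            ]
        )

    def boundary_length(self, selected: np.ndarray) -> float:
        """Total edge length between selected and unselected/exterior cells."""
        sel = np.asarray(selected, dtype=bool).reshape(self.grid.shape)
        side = self.grid.cell_size_km
        edges = 0
        padded = np.pad(sel, 1, constant_values=False)
        for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rolled = np.roll(padded, shift, axis=(0, 1))
            edges += int(np.sum(sel & ~rolled[1:-1, 1:-1]))
        return edges * side

    def default_spf(self) -> float:
        """Shortfall penalty weight: 10 x the maximum PU cost per km²."""
        mx = float(self.cost.max()) if self.n_pu else 1.0
        return 10.0 * max(mx, 1.0)


def build_problem(
    ranges: list[BinaryRange],
    pa_mask: np.ndarray,
    cost_surface: np.ndarray,
    settlements: SettlementSet | None,
    grid: GridSpec,
    buffer_km: float = 5.0,
) -> PlanningProblem:
    """Assemble the planning problem from ranges, PA mask, costs and towns.

    PA overlap wins over town proximity when both apply (a locked-in PU is
    never locked out).  Features with their whole achievable amount in
    locked-out PUs are flagged infeasible at build time.
    """
    pa_mask = np.asarray(pa_mask, dtype=bool)
    cost = np.asarray(cost_surface, dtype=float)
    if pa_mask.shape != grid.shape or cost.shape != grid.shape:
        raise ValueError("mask/cost shape must match the grid")
    status = np.zeros(grid.n_cells, dtype=int)
    status[pa_mask.ravel()] = LOCKED_IN
    if settlements is not None and buffer_km > 0:
        towns = settlements.of_kind("city")
        if len(towns):
            rows, cols = np.indices(grid.shape)
            cx, cy = grid.xy_of(rows, cols)
            d2min = np.full(grid.shape, np.inf)
            for tx, ty in towns:
                d2min = np.minimum(d2min, (cx - tx) ** 2 + (cy - ty) ** 2)
            near = (d2min <= buffer_km**2).ravel()
            status[near & (status != LOCKED_IN)] = LOCKED_OUT

    area = grid.cell_area_km2
    feature_ids, feature_pus, feature_amounts, targets = [], [], [], []
    for r in ranges:
        if r.grid != grid:
            raise ValueError("range grid mismatch")
        pus = np.flatnonzero(r.mask.ravel())
        if len(pus) == 0:
            continue  # locally extinct: no feature to represent
        feature_ids.append(r.species_id)
        feature_pus.append(pus)
        feature_amounts.append(np.full(len(pus), area))
        targets.append(tier_target(r.area_km2) * r.area_km2)
    problem = PlanningProblem(
        grid, cost.ravel(), status, feature_ids, feature_pus, feature_amounts,
        np.array(targets, dtype=float),
    )
    if problem.infeasible.any():
        bad = [feature_ids[i] for i in np.flatnonzero(problem.infeasible)]
        warnings.warn(
            f"features infeasible at build time (targets unreachable once "
            f"locked-out PUs are excluded): {bad}"
        )
    return problem


# ---------------------------------------------------------------------------
# objective and annealing
# ---------------------------------------------------------------------------

@dataclass
class SAParams:
    """Annealing parameters.

    ``spf=None`` resolves to the problem's default (10 x max PU cost per km²
    of shortfall).  ``t0=None`` sets the initial temperature adaptively so
    roughly 80% of uphill probe moves would be accepted.  ``full_scale``
    raises the portfolio to 1,000 runs x 10,000 iterations (the 10-million
    iteration budget); the desk-scale default is 100 runs.
    """

    blm: float = 0.001
    spf: float | None = None
    n_iterations: int = 10_000
    n_runs: int = 100
    t0: float | None = None
    t_final_ratio: float = 1e-4
    initial_fraction: float = 0.5
    full_scale: bool = False

    def __post_init__(self) -> None:
        if self.blm < 0:
            raise ValueError("blm must be non-negative")
        if self.full_scale:
            self.n_runs = 1000
            self.n_iterations = 10_000

    def resolve_spf(self, problem: PlanningProblem) -> float:
        return self.spf if self.spf is not None else problem.default_spf()


@dataclass
class Solution:
    """One reserve configuration with its objective decomposition."""

    selected: np.ndarray = field(repr=False)  # bool per PU
    total: float = np.nan
    cost: float = np.nan
    boundary: float = np.nan
    penalty: float = np.nan
    held: np.ndarray = field(default=None, repr=False)
    feasible: np.ndarray = field(default=None, repr=False)  # per feature

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def selected_mask(self, grid: GridSpec) -> np.ndarray:
        return self.selected.reshape(grid.shape)


def objective(
    selected: np.ndarray, problem: PlanningProblem, params: SAParams
) -> Solution:
    """Score a configuration from scratch (also validates lock constraints)."""
    selected = np.asarray(selected, dtype=bool).ravel()
    if not selected[problem.locked_in].all():
        raise ValueError("solution must include every locked-in PU")
    if selected[problem.locked_out].any():
        raise ValueError("solution must exclude every locked-out PU")
    spf = params.resolve_spf(problem)
    cost = float(problem.cost[selected].sum())
    boundary = problem.boundary_length(selected)
    held = problem.held_amounts(selected)
    shortfall = np.maximum(0.0, problem.targets - held)
    penalty = float(spf * shortfall.sum())
    total = cost + params.blm * boundary + penalty
    return Solution(
        selected=selected.copy(), total=total, cost=cost,
        boundary=params.blm * boundary, penalty=penalty,
        held=held, feasible=shortfall <= 1e-9,
    )


def anneal(problem: PlanningProblem, params: SAParams, seed: int = 0) -> Solution:
    """One simulated-annealing run; returns the best configuration visited.

    Starts from the locked-in set plus a random subset of available PUs and
    proposes single-PU flips of available units only, so the lock constraints
    hold by construction throughout.
    """
    rng = np.random.default_rng(seed)
    available = problem.available
    if len(available) == 0 and len(problem.locked_in) == 0:
        raise ValueError("no selectable or locked-in planning units")
    spf = params.resolve_spf(problem)
    side = problem.grid.cell_size_km

    selected = np.zeros(problem.n_pu, dtype=bool)
    selected[problem.locked_in] = True
    if len(available):
        take = rng.random(len(available)) < params.initial_fraction
        selected[available[take]] = True

    cost_sum = float(problem.cost[selected].sum())
    boundary = problem.boundary_length(selected)
    held = problem.held_amounts(selected)
    targets = problem.targets
    shortfall_sum = float(np.maximum(0.0, targets - held).sum())

    def flip_delta(pu: int) -> float:
        """Objective change of flipping ``pu`` (without applying it)."""
        adding = not selected[pu]
        sign = 1.0 if adding else -1.0
        d_cost = sign * problem.cost[pu]
        k = int(selected[problem.neighbors[pu]].sum())
        d_boundary = sign * side * (4 - 2 * k)
        d_short = 0.0
        for f, amt in problem.pu_features[pu]:
            old = held[f]
            new = old + sign * amt
            d_short += max(0.0, targets[f] - new) - max(0.0, targets[f] - old)
        return d_cost + params.blm * d_boundary + spf * d_short

    def apply_flip(pu: int) -> None:
        nonlocal cost_sum, boundary, shortfall_sum
        adding = not selected[pu]
        sign = 1.0 if adding else -1.0
        cost_sum += sign * problem.cost[pu]
        k = int(selected[problem.neighbors[pu]].sum())
        boundary += sign * side * (4 - 2 * k)
        for f, amt in problem.pu_features[pu]:
            old = held[f]
            new = old + sign * amt
            shortfall_sum += max(0.0, targets[f] - new) - max(0.0, targets[f] - old)
            held[f] = new
        selected[pu] = adding

    def current_total() -> float:
        return cost_sum + params.blm * boundary + spf * shortfall_sum

    if len(available) == 0:
        return objective(selected, problem, params)

    # adaptive initial temperature: ~80% acceptance of uphill probe moves
    if params.t0 is None:
        probes = [flip_delta(int(pu))
                  for pu in rng.choice(available, size=min(100, len(available)))]
        uphill = [d for d in probes if d > 0]
        t0 = (np.mean(uphill) / math.log(1 / 0.8)) if uphill else 1.0
    else:
        t0 = params.t0
    t_final = params.t_final_ratio * t0
    factor = (t_final / t0) ** (1.0 / max(params.n_iterations - 1, 1))

    best_total = current_total()
    best_selected = selected.copy()
    temp = t0
    for _ in range(params.n_iterations):
        pu = int(available[rng.integers(len(available))])
        delta = flip_delta(pu)
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            apply_flip(pu)
            total = current_total()
            if total < best_total - 1e-12:
                best_total = total
                best_selected = selected.copy()
        temp *= factor

    return objective(best_selected, problem, params)


class PrioritizationResults:
    """Portfolio output: best solution, per-run objectives, selection frequency."""

    def __init__(self, problem: PlanningProblem, params: SAParams,
                 solutions: list[Solution], seed: int):
        self.problem = problem
        self.params = params
        self.solutions = solutions
        self.seed = seed
        self.objectives = np.array([s.total for s in solutions])
        self.best = solutions[int(np.argmin(self.objectives))]
        self.selection_frequency = np.mean(
            [s.selected for s in solutions], axis=0
        )

    def selection_frequency_map(self) -> np.ndarray:
        return self.selection_frequency.reshape(self.problem.grid.shape)

    def best_map(self) -> np.ndarray:
        return self.best.selected_mask(self.problem.grid)

    @property
    def cpa_fraction(self) -> float:
        """Fraction of the grid selected in the best solution."""
        return self.best.n_selected / self.problem.n_pu

    def summary(self) -> str:
        b = self.best
        met = int(b.feasible.sum())
        lines = [
            "Prioritization results",
            f"  runs: {len(self.solutions)}   iterations/run: "
            f"{self.params.n_iterations}   blm: {self.params.blm}",
            f"  best objective: {b.total:.3f} "
            f"(cost {b.cost:.3f} + boundary {b.boundary:.3f} "
            f"+ penalty {b.penalty:.3f})",
            f"  selected PUs: {b.n_selected}/{self.problem.n_pu} "
            f"({100 * self.cpa_fraction:.1f}% of grid)",
            f"  targets met: {met}/{self.problem.n_features}",
        ]
        return "\n".join(lines)


def run_portfolio(
    problem: PlanningProblem, params: SAParams, seed: int = 0
) -> PrioritizationResults:
    """Run ``params.n_runs`` annealing runs with seeds derived from ``seed``."""
    if params.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(2**31, size=params.n_runs)
    solutions = [anneal(problem, params, seed=int(s)) for s in run_seeds]
    return PrioritizationResults(problem, params, solutions, seed)


def blm_sweep(
    problem: PlanningProblem,
    blm_values,
    params: SAParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cost/boundary trade-off of the best solution across a BLM sweep."""
    base = params or SAParams()
    rows = []
    for blm in blm_values:
        p = SAParams(
            blm=float(blm), spf=base.spf, n_iterations=base.n_iterations,
            n_runs=base.n_runs, t0=base.t0,
            t_final_ratio=base.t_final_ratio,
            initial_fraction=base.initial_fraction,
        )
        res = run_portfolio(problem, p, seed=seed)
        raw_boundary = problem.boundary_length(res.best.selected)
        rows.append(
            {"blm": float(blm), "cost": res.best.cost,
             "boundary_length": raw_boundary, "objective": res.best.total,
             "n_selected": res.best.n_selected}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Local Moran's I cluster/outlier analysis
# ---------------------------------------------------------------------------

@dataclass
class LocalMoranResult:
    I: np.ndarray
    p_sim: np.ndarray
    labels: np.ndarray  # 'HH', 'LL', 'HL', 'LH', 'ns'
    global_I: float


def local_morans_i(
    values: np.ndarray,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> LocalMoranResult:
    """Anselin Local Moran's I on a grid with queen adjacency.

    I_i = (z_i / m2) * sum_j w_ij z_j with z the deviations from the map
    mean, m2 their mean square, and w row-standardized queen weights.
    Pseudo-significance by conditional permutation: each cell's neighbour
    values are redrawn from the other n-1 cells; the one-sided pseudo-p is
    ``(more-extreme-count + 1) / (n_permutations + 1)``.  Significant cells
    are labelled by quadrant (HH/LL clusters, HL/LH outliers).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be a 2-D grid")
    nr, nc = v.shape
    n = nr * nc
    if n < 9:
        raise ValueError("need at least 9 cells")
    z = (v - v.mean()).ravel()
    m2 = float(np.mean(z**2))
    labels = np.full(n, "ns", dtype="<U2")
    if m2 == 0:
        warnings.warn("constant map: Local Moran's I undefined, all cells 'ns'")
        return LocalMoranResult(
            np.zeros(v.shape), np.ones(v.shape), labels.reshape(v.shape), 0.0
        )

    # queen neighbours
    neighbors: list[np.ndarray] = []
    idx = np.arange(n).reshape(nr, nc)
    for r in range(nr):
        for c in range(nc):
            nbr = [
                idx[rr, cc]
                for rr in range(max(r - 1, 0), min(r + 2, nr))
                for cc in range(max(c - 1, 0), min(c + 2, nc))
                if (rr, cc) != (r, c)
            ]
            neighbors.append(np.array(nbr, dtype=int))

    lag = np.array([z[nbr].mean() for nbr in neighbors])
    I = z * lag / m2
    global_I = float(I.mean())

    rng = np.random.default_rng(seed)
    kmax = max(len(nbr) for nbr in neighbors)
    rids = rng.integers(0, n - 1, size=(n_permutations, kmax))
    p_sim = np.empty(n)
    for i in range(n):
        k = len(neighbors[i])
        ids = rids[:, :k]
        ids = ids + (ids >= i)  # skip self: draw from the other n-1 cells
        lag_perm = z[ids].mean(axis=1)
        I_perm = z[i] * lag_perm / m2
        larger = int(np.sum(I_perm >= I[i]))
        if larger > n_permutations / 2:
            larger = n_permutations - larger
        p_sim[i] = (larger + 1) / (n_permutations + 1)

    sig = p_sim <= alpha
    hh = sig & (z > 0) & (lag > 0)
    ll = sig & (z < 0) & (lag < 0)
    hl = sig & (z > 0) & (lag <= 0)
    lh = sig & (z <= 0) & (lag > 0)
    labels[hh], labels[ll], labels[hl], labels[lh] = "HH", "LL", "HL", "LH"
    return LocalMoranResult(
        I.reshape(v.shape), p_sim.reshape(v.shape),
        labels.reshape(v.shape), global_I,
    )


# ---------------------------------------------------------------------------
# CPA overlap
# ---------------------------------------------------------------------------

def overlap_cpas(
    selected_current: np.ndarray, selected_future: np.ndarray,
    grid: GridSpec | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify cells by membership in the current and future priority areas.

    Returns a label grid with values in {overlapped, current_only,
    future_only, none} and a summary table of areas and grid percentages.
    """
    cur = np.asarray(selected_current, dtype=bool)
    fut = np.asarray(selected_future, dtype=bool)
    if cur.shape != fut.shape:
        raise ValueError("solutions must share the grid")
    labels = np.full(cur.shape, "none", dtype="<U12")
    labels[cur & fut] = "overlapped"
    labels[cur & ~fut] = "current_only"
    labels[~cur & fut] = "future_only"
    area = grid.cell_area_km2 if grid is not None else 1.0
    n = cur.size
    rows = [
        {
            "class": name,
            "n_cells": int(np.sum(labels == name)),
            "area_km2": float(np.sum(labels == name) * area),
            "pct_of_grid": 100.0 * float(np.sum(labels == name)) / n,
        }
        for name in ("overlapped", "current_only", "future_only", "none")
    ]
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Marxan input dialect
# ---------------------------------------------------------------------------

def write_marxan_inputs(problem: PlanningProblem, directory: str | Path,
                        spf: float | None = None) -> None:
    """Write pu.dat, spec.dat, puvspr.dat and bound.dat (1-based PU/species ids).

    bound.dat lists every rook-adjacent pair once (id1 < id2) plus exposed
    exterior edges as self-pairs, with the shared boundary length.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    side = problem.grid.cell_size_km

    pu = pd.DataFrame(
        {"id": np.arange(1, problem.n_pu + 1), "cost": problem.cost,
         "status": problem.status}
    )
    pu.to_csv(directory / "pu.dat", index=False)

    spf_val = spf if spf is not None else problem.default_spf()
    spec = pd.DataFrame(
        {"id": np.arange(1, problem.n_features + 1),
         "target": problem.targets, "spf": spf_val,
         "name": problem.feature_ids}
    )
    spec.to_csv(directory / "spec.dat", index=False)

    rows = []
    for f, (pus, amts) in enumerate(
        zip(problem.feature_pus, problem.feature_amounts), start=1
    ):
        for p, a in zip(pus, amts):
            rows.append((f, p + 1, a))
    puvspr = pd.DataFrame(rows, columns=["species", "pu", "amount"])
    puvspr = puvspr.sort_values(["pu", "species"])  # Marxan wants pu-sorted
    puvspr.to_csv(directory / "puvspr.dat", index=False)

    nr, nc = problem.grid.shape
    idx = np.arange(problem.n_pu).reshape(nr, nc)
    brows = []
    exterior = np.zeros(problem.n_pu, dtype=int)
    for r in range(nr):
        for c in range(nc):
            i = idx[r, c]
            if r + 1 < nr:
                brows.append((i + 1, idx[r + 1, c] + 1, side))
            else:
                exterior[i] += 1
            if c + 1 < nc:
                brows.append((i + 1, idx[r, c + 1] + 1, side))
            else:
                exterior[i] += 1
            if r == 0:
                exterior[i] += 1
            if c == 0:
                exterior[i] += 1
    for i in np.flatnonzero(exterior):
        brows.append((i + 1, i + 1, exterior[i] * side))
    bound = pd.DataFrame(brows, columns=["id1", "id2", "boundary"])
    bound.to_csv(directory / "bound.dat", index=False)


def read_marxan_inputs(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the four input tables back as DataFrames."""
    directory = Path(directory)
    return {
        name: pd.read_csv(directory / f"{name}.dat")
        for name in ("pu", "spec", "puvspr", "bound")
    }
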