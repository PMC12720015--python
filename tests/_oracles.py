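"""Independent oracles for the minimum-set objective and small instances.

The brute-force enumerator scores every subset of available planning units
with its own vectorized arithmetic (cost, boundary via edge lists, penalty),
sharing no code with the annealer's incremental bookkeeping.
"""

import numpy as np

from consplan.grids import GridSpec
from consplan.prioritize import LOCKED_IN, LOCKED_OUT, PlanningProblem, SAParams


def rook_edges(grid: GridSpec) -> list[tuple[int, int]]:
    edges = []
    idx = np.arange(grid.n_cells).reshape(grid.shape)
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            if r + 1 < grid.nrows:
                edges.append((idx[r, c], idx[r + 1, c]))
            if c + 1 < grid.ncols:
                edges.append((idx[r, c], idx[r, c + 1]))
    return edges


def objective_by_hand(selected, problem: PlanningProblem, params: SAParams):
    """Slow explicit-loop recomputation of the objective."""
    selected = np.asarray(selected, dtype=bool)
    spf = params.resolve_spf(problem)
    cost = sum(problem.cost[i] for i in range(problem.n_pu) if selected[i])
    side = problem.grid.cell_size_km
    boundary = 0.0
    sel2d = selected.reshape(problem.grid.shape)
    nr, nc = problem.grid.shape
    for r in range(nr):
        for c in range(nc):
            if not sel2d[r, c]:
                continue
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < nr and 0 <= cc < nc) or not sel2d[rr, cc]:
                    boundary += side
    penalty = 0.0
    for pus, amts, target in zip(
        problem.feature_pus, problem.feature_amounts, problem.targets
    ):
        held = sum(a for p, a in zip(pus, amts) if selected[p])
        penalty += spf * max(0.0, target - held)
    return cost + params.blm * boundary + penalty


def brute_force_optimum(problem: PlanningProblem, params: SAParams) -> float:
    """Exact optimum over all subsets of available PUs (vectorized)."""
    avail = problem.available
    n = len(avail)
    if n > 20:
        raise ValueError("instance too large for enumeration")
    spf = params.resolve_spf(problem)
    side = problem.grid.cell_size_km
    m = 1 << n
    bits = (np.arange(m)[:, None] >> np.arange(n)) & 1  # (m, n) availability
    M = bits.astype(bool)

    locked = np.zeros(problem.n_pu, dtype=bool)
    locked[problem.locked_in] = True
    pos_of = {int(p): j for j, p in enumerate(avail)}

    cost = M @ problem.cost[avail] + problem.cost[locked].sum()

    n_sel = M.sum(axis=1) + locked.sum()
    edges_within = np.zeros(m)
    for a, b in rook_edges(problem.grid):
        a_locked, b_locked = locked[a], locked[b]
        if problem.status[a] == LOCKED_OUT or problem.status[b] == LOCKED_OUT:
            continue  # a locked-out endpoint is never selected
        if a_locked and b_locked:
            edges_within += 1
        elif a_locked:
            edges_within += M[:, pos_of[b]]
        elif b_locked:
            edges_within += M[:, pos_of[a]]
        else:
            edges_within += M[:, pos_of[a]] & M[:, pos_of[b]]
    boundary = side * (4 * n_sel - 2 * edges_within)

    penalty = np.zeros(m)
    for pus, amts, target in zip(
        problem.feature_pus, problem.feature_amounts, problem.targets
    ):
        held = np.full(m, amts[locked[pus]].sum())
        for p, a in zip(pus, amts):
            if not locked[p] and problem.status[p] != LOCKED_OUT:
                held = held + a * M[:, pos_of[p]]
        penalty += spf * np.maximum(0.0, target - held)

    return float(np.min(cost + params.blm * boundary + penalty))


def random_instance(seed: int):
    """A random <= 15-available-PU planning instance with 2-4 features."""
    rng = np.random.default_rng(seed)
    shape = [(3, 4), (3, 5), (2, 6), (2, 7), (4, 3)][int(rng.integers(5))]
    grid = GridSpec(*shape)
    n = grid.n_cells
    cost = rng.uniform(1, 10, size=n)
    status = np.zeros(n, dtype=int)
    if rng.random() < 0.4:
        status[rng.integers(n)] = LOCKED_IN
    if rng.random() < 0.4:
        free = np.flatnonzero(status == 0)
        status[free[rng.integers(len(free))]] = LOCKED_OUT
    n_feat = int(rng.integers(2, 5))
    feature_pus, feature_amounts, targets = [], [], []
    for _ in range(n_feat):
        k = int(rng.integers(1, max(2, n // 2)))
        pus = rng.choice(n, size=k, replace=False)
        amts = np.ones(k)
        frac = rng.choice([0.3, 0.5, 1.0])
        feature_pus.append(pus)
        feature_amounts.append(amts)
        targets.append(frac * k)
    problem = PlanningProblem(
        grid, cost, status, [f"f{i}" for i in range(n_feat)],
        feature_pus, feature_amounts, np.array(targets),
    )
    params = SAParams(
        blm=float(rng.choice([0.0, 0.001, 0.05])),
        n_iterations=1500, n_runs=1,
    )
    return problem, params
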