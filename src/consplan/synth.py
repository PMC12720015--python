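"""Synthetic landscapes and virtual species with known truth.

The generators emulate the statistical structure the downstream analysis
assumes: a stack of spatially autocorrelated, standardized bioclim-style
layers on an equal-area 1 km grid; virtual species defined by a logistic
suitability function of those layers (so the true range is known exactly);
presence-only occurrence records, optionally spatially biased; a patchy
protected-area mask; a strictly positive human-footprint-like cost surface
that peaks near settlements; and settlement points (cities, institutions,
museums) used for record cleaning and planning-unit lock-outs.

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import BinaryRange, EnvStack, GridSpec

__all__ = [
    "SettlementSet",
    "VirtualSpecies",
    "generate_env_stack",
    "make_future_replicates",
    "define_virtual_species",
    "sample_occurrences",
    "generate_pa_mask",
    "generate_cost_surface",
    "generate_settlements",
]


@dataclass
class SettlementSet:
    """Settlement points: (x, y, kind) with kind in {city, institution, museum}."""

    points: pd.DataFrame  # columns: x, y, kind

    def __post_init__(self) -> None:
        required = {"x", "y", "kind"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"settlement table needs columns {sorted(required)}")

    def of_kind(self, *kinds: str) -> np.ndarray:
        sel = self.points[self.points["kind"].isin(kinds)]
        return sel[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VirtualSpecies:
    """A simulated species whose true range is known exactly.

    Suitability is logistic in the environmental layers:
    ``p(cell) = 1 / (1 + exp(-(b0 + sum_j b_j x_j)))``.  The truth threshold
    is the suitability quantile whose exceedance set has the occupied
    fraction closest to the requested prevalence; the current and future
    true ranges are its exceedance sets on the two stacks.
    """

    species_id: str
    coefficients: dict[str, float]  # includes "intercept"
    truth_threshold: float
    true_range_current: BinaryRange
    true_range_future: BinaryRange | None = None

    def suitability(self, stack: EnvStack) -> np.ndarray:
        eta = np.full(stack.grid.shape, self.coefficients.get("intercept", 0.0))
        for name, beta in self.coefficients.items():
            if name == "intercept":
                continue
            eta = eta + beta * stack[name]
        return 1.0 / (1.0 + np.exp(-eta))


def _smoothed_standard_field(rng: np.random.Generator, grid: GridSpec,
                             autocorr_range_km: float) -> np.ndarray:
    """Gaussian random field with mean 0, sd 1 and controllable range.

    White noise smoothed with a Gaussian kernel (sigma = range / cell size),
    then re-standardized to zero mean, unit sd over the grid.
    """
    field = rng.standard_normal(grid.shape)
    if autocorr_range_km > 0:
        sigma = autocorr_range_km / grid.cell_size_km
        field = gaussian_filter(field, sigma=sigma, mode="reflect")
    sd = field.std()
    if sd == 0:
        raise ValueError("degenerate field (zero variance); grid too small "
                         "for the requested autocorrelation range")
    return (field - field.mean()) / sd


def generate_env_stack(
    grid: GridSpec,
    n_layers: int = 10,
    autocorr_range_km: float = 10.0,
    seed: int = 0,
    correlation: np.ndarray | None = None,
    layer_prefix: str = "bio",
) -> EnvStack:
    """Generate a stack of autocorrelated standard-normal layers.

    Parameters
    ----------
    n_layers : int
        Number of layers (>= 2).  Default 10 mirrors a post-collinearity-filter
        bioclim set; pass 19 with a ``correlation`` matrix to exercise the
        collinearity filter on raw-style layers.
    autocorr_range_km : float
        Gaussian smoothing range; 0 gives i.i.d. cells.
    correlation : (n_layers, n_layers) array, optional
        Target cross-layer correlation; layers are mixed with its Cholesky
        factor (marginal sd stays 1).
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if autocorr_range_km < 0:
        raise ValueError("autocorrelation range must be non-negative")
    rng = np.random.default_rng(seed)
    fields = np.stack(
        [_smoothed_standard_field(rng, grid, autocorr_range_km) for _ in range(n_layers)]
    )
    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (n_layers, n_layers):
            raise ValueError("correlation matrix shape must be (n_layers, n_layers)")
        L = np.linalg.cholesky(correlation)
        flat = fields.reshape(n_layers, -1)
        fields = (L @ flat).reshape(n_layers, *grid.shape)
    layers = {f"{layer_prefix}{j + 1}": fields[j] for j in range(n_layers)}
    return EnvStack(grid, layers, scenario="current")


def make_future_replicates(
    stack: EnvStack,
    n_reps: int = 5,
    shift: dict[str, float] | float = 0.0,
    noise_sd: float = 0.0,
    autocorr_range_km: float = 10.0,
    seed: int = 0,
) -> tuple[list[EnvStack], EnvStack]:
    """Build future-climate replicates (GCM stand-ins) and their cell-wise mean.

    Replicate k = current + per-layer shift + independent autocorrelated noise
    with marginal sd ``noise_sd``.  Returns ``(replicates, future_mean)``
    where ``future_mean`` is the exact cell-wise mean of the replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not isinstance(shift, dict):
        shift = {name: float(shift) for name in stack.layer_names}
    rng = np.random.default_rng(seed)
    replicates: list[EnvStack] = []
    for k in range(n_reps):
        layers = {}
        for name in stack.layer_names:
            layer = stack[name] + shift.get(name, 0.0)
            if noise_sd > 0:
                layer = layer + noise_sd * _smoothed_standard_field(
                    rng, stack.grid, autocorr_range_km
                )
            layers[name] = layer
        replicates.append(EnvStack(stack.grid, layers, f"future_replicate_{k + 1}"))
    mean_layers = {
        name: np.mean([rep[name] for rep in replicates], axis=0)
        for name in stack.layer_names
    }
    future_mean = EnvStack(stack.grid, mean_layers, "future_mean")
    return replicates, future_mean


def define_virtual_species(
    stack: EnvStack,
    coefficients: dict[str, float],
    target_prevalence: float,
    species_id: str = "vsp",
    future_stack: EnvStack | None = None,
    no_dispersal: bool = True,
) -> VirtualSpecies:
    """Define a virtual species and derive its true ranges.

    The truth threshold is the ``k``-th largest current suitability value with
    ``k = round(target_prevalence * n_cells)``, so realized occupancy is within
    one cell of the target (ties aside).  The future true range is the
    exceedance of the same threshold on ``future_stack``; under no-dispersal
    it is intersected with the current truth.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target_prevalence must be in (0, 1)")
    missing = [n for n in coefficients if n != "intercept" and n not in stack.layers]
    if missing:
        raise ValueError(f"coefficient layers not in stack: {missing}")
    vs = VirtualSpecies(
        species_id=species_id,
        coefficients=dict(coefficients),
        truth_threshold=np.nan,
        true_range_current=None,  # type: ignore[arg-type]
    )
    suit = vs.suitability(stack)
    if np.ptp(suit) == 0:
        raise ValueError(
            f"degenerate suitability for {species_id!r}: constant "
            f"{suit.flat[0]:.3f} everywhere (all non-intercept coefficients "
            "zero or layers constant)"
        )
    k = int(round(target_prevalence * stack.grid.n_cells))
    k = min(max(k, 1), stack.grid.n_cells)
    threshold = float(np.sort(suit.ravel())[::-1][k - 1])
    vs.truth_threshold = threshold
    vs.true_range_current = BinaryRange(
        species_id, "current", stack.grid, suit >= threshold
    )
    if future_stack is not None:
        fut_mask = vs.suitability(future_stack) >= threshold
        fut = BinaryRange(species_id, "future", stack.grid, fut_mask)
        if no_dispersal:
            fut = fut.intersect(vs.true_range_current, scenario="future")
        vs.true_range_future = fut
    return vs


def sample_occurrences(
    vs: VirtualSpecies,
    n: int,
    seed: int = 0,
    bias_layer: np.ndarray | None = None,
    source: str = "synthetic",
) -> pd.DataFrame:
    """Draw presence-only records from the current true range.

    Cells are sampled with replacement with probability proportional to
    ``exp(bias)`` (uniform if no bias layer); coordinates are jittered
    uniformly within the cell.  Returns a DataFrame with columns
    ``species, x, y, source``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng_range = vs.true_range_current
    if rng_range is None or rng_range.is_empty:
        raise ValueError(
            f"species {vs.species_id!r} has an empty true range (locally absent)"
        )
    grid = rng_range.grid
    rows, cols = np.nonzero(rng_range.mask)
    if bias_layer is None:
        p = None
    else:
        bias = np.asarray(bias_layer, dtype=float)[rows, cols]
        w = np.exp(bias - bias.max())
        p = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=True, p=p)
    cx, cy = grid.xy_of(rows[idx], cols[idx])
    half = grid.cell_size_km / 2
    x = cx + rng.uniform(-half, half, size=n)
    y = cy + rng.uniform(-half, half, size=n)
    return pd.DataFrame(
        {"species": vs.species_id, "x": x, "y": y, "source": source}
    )


def generate_pa_mask(
    grid: GridSpec,
    fraction: float = 0.10,
    n_patches: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Protected-area mask: ``n_patches`` 4-connected blobs covering ~``fraction``.

    Patches are grown by seeded random accretion (each step annexes a random
    unclaimed rook-neighbour of the patch) until the requested cell count is
    reached, so every patch is 4-connected by construction.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_target = int(round(fraction * grid.n_cells))
    if n_target < n_patches:
        raise ValueError("fraction * n_cells < n_patches; shrink n_patches")
    rng = np.random.default_rng(seed)
    mask = np.zeros(grid.shape, dtype=bool)
    seeds = rng.choice(grid.n_cells, size=n_patches, replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    for s in seeds:
        r, c = divmod(int(s), grid.ncols)
        mask[r, c] = True
        frontiers.append([(r, c)])
    placed = int(mask.sum())
    while placed < n_target:
        grew = False
        for frontier in frontiers:
            if placed >= n_target:
                break
            while frontier:
                i = rng.integers(len(frontier))
                r, c = frontier[i]
                nbrs = [
                    (rr, cc)
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                    if 0 <= rr < grid.nrows and 0 <= cc < grid.ncols and not mask[rr, cc]
                ]
                if not nbrs:
                    frontier[i] = frontier[-1]
                    frontier.pop()
                    continue
                rr, cc = nbrs[rng.integers(len(nbrs))]
                mask[rr, cc] = True
                frontier.append((rr, cc))
                placed += 1
                grew = True
                break
        if not grew:  # all patches boxed in (saturated grid)
            break
    return mask


def generate_settlements(
    grid: GridSpec,
    n_city: int = 3,
    n_inst: int = 4,
    seed: int = 0,
) -> SettlementSet:
    """Random settlement points inside the grid bounding box.

    ``n_inst`` points alternate between institution and museum kinds.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    n = n_city + n_inst
    x = rng.uniform(xmin, xmax, size=n)
    y = rng.uniform(ymin, ymax, size=n)
    kinds = ["city"] * n_city + [
        "institution" if i % 2 == 0 else "museum" for i in range(n_inst)
    ]
    return SettlementSet(pd.DataFrame({"x": x, "y": y, "kind": kinds}))


def generate_cost_surface(
    grid: GridSpec,
    settlements: SettlementSet | None = None,
    seed: int = 0,
    base_scale: float = 1.0,
    settlement_amplitude: float = 5.0,
    settlement_range_km: float = 4.0,
) -> np.ndarray:
    """Human-footprint-like cost layer: strictly positive, peaking near settlements.

    Cost = exp(autocorrelated field) * base_scale plus Gaussian bumps of
    height ``settlement_amplitude`` centred on each settlement point.
    """
    rng = np.random.default_rng(seed)
    base = base_scale * np.exp(0.5 * _smoothed_standard_field(rng, grid, 5.0))
    if settlements is not None and len(settlements):
        rows, cols = np.indices(grid.shape)
        cx, cy = grid.xy_of(rows, cols)
        for _, pt in settlements.points.iterrows():
            d2 = (cx - pt["x"]) ** 2 + (cy - pt["y"]) ** 2
            base = base + settlement_amplitude * np.exp(
                -d2 / (2 * settlement_range_km**2)
            )
    return base
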