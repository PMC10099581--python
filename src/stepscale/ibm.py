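"""Stochastic individual-based simulation of step-selection movement kernels.

Single animals are simulated by exact categorical sampling of the
movement kernel over grid cells (then jittered uniformly within the
chosen cell, so trajectories live in continuous space).  Interacting
animals are coupled through their occurrence distributions (ODs): each
animal's recent path is interpolated with stepping stones, smoothed by a
Gaussian kernel density estimate, and fed into the other animals'
kernels as a dynamic end-point covariate.  This feedback — animal j
avoids (or seeks) where animal j' has recently been, and vice versa —
is what makes the system nonlinear and puts it beyond the reach of the
linear steady-state machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import KernelDensity

from .kernel import KernelSpec, evaluate_kernel, make_coupled_kernels
from .landscape import RasterLayer, StudyArea, Trajectory, bearing_between
from .master_equation import build_transition_matrix

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "ODRegistry",
    "sample_step",
    "simulate",
    "simulate_replicates",
    "occurrence_distribution",
    "endpoint_ud",
    "coupled_simulation_config",
]


def _kde_layer(
    points: np.ndarray,
    bandwidth: float,
    area: StudyArea,
    name: str,
) -> RasterLayer:
    """Gaussian KDE of 2-D points evaluated at cell centres, normalised to 1."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(points)
    cx, cy = area.cell_centres()
    grid = np.column_stack([cx.ravel(), cy.ravel()])
    dens = np.exp(kde.score_samples(grid)).reshape(area.shape)
    dens = np.where(area.admissible, dens, 0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel density estimate has no mass on the grid")
    return RasterLayer(dens / total, area.cell_size, area.origin, name=name)


class ODRegistry:
    """Current occurrence distributions of the simulated animals.

    Dynamic covariates read from here via ``registry.get(j, t)``.  Before
    an animal has moved, a uniform layer is returned, so interactions
    exert no force until a path exists.
    """

    def __init__(self, area: StudyArea):
        self.area = area
        uniform = area.admissible.astype(float)
        self._uniform = RasterLayer(
            uniform / uniform.sum(), area.cell_size, area.origin, name="od-uniform"
        )
        self._layers: dict[int, RasterLayer] = {}

    def get(self, j: int, t: float) -> RasterLayer:
        return self._layers.get(j, self._uniform)

    def set(self, j: int, layer: RasterLayer) -> None:
        self._layers[j] = layer


@dataclass
class SimulationConfig:
    """Protocol for a (possibly coupled) individual-based simulation.

    Parameters
    ----------
    kernel_specs : list of KernelSpec
        One movement kernel per animal.  Dynamic covariates should read
        from ``od_registry`` (see :func:`coupled_simulation_config`).
    initial_locations : list of (x, y)
        Starting point of each animal, inside the study area.
    n_steps : int
        Number of movement steps (trajectories get n_steps + 1 fixes).
    stepping_stones_per_step : int
        Interpolated sub-step points per step when building ODs.
    od_window : int
        Number of most recent steps contributing to each OD.
    od_bandwidth : float
        Gaussian KDE bandwidth, in coordinate units.
    od_update_interval : int
        Steps between OD refreshes; ODs at time t use steps strictly
        before t.
    seed : int
        Seed for all randomness; fixed seed gives bit-identical output.
    """

    kernel_specs: Sequence[KernelSpec]
    initial_locations: Sequence[tuple[float, float]]
    n_steps: int
    stepping_stones_per_step: int = 10
    od_window: int = 500
    od_bandwidth: float = 2.0
    od_update_interval: int = 1
    seed: int = 0
    od_registry: ODRegistry | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if len(self.kernel_specs) != len(self.initial_locations):
            raise ValueError("one initial location per kernel spec is required")
        if self.od_window < 1:
            raise ValueError("od_window must be at least 1")
        if self.od_update_interval < 1:
            raise ValueError("od_update_interval must be at least 1")
        if self.stepping_stones_per_step < 0:
            raise ValueError("stepping_stones_per_step must be non-negative")
        for x in self.initial_locations:
            area = self.kernel_specs[0].study_area
            if not area.contains(*x):
                raise ValueError(f"initial location {x} is outside the study area")

    @property
    def n_animals(self) -> int:
        return len(self.kernel_specs)


@dataclass
class SimulationResult:
    trajectories: list[Trajectory]
    od_history: list[dict[int, RasterLayer]]  # snapshots at refresh times
    final_ods: dict[int, RasterLayer]


def coupled_simulation_config(
    resource: RasterLayer,
    centres: Sequence[tuple[float, float]],
    lam: float,
    beta_r: Sequence[float] | float,
    beta_c: Sequence[float] | float,
    interaction: np.ndarray,
    n_steps: int,
    seed: int = 0,
    kappa: float = 0.0,
    **od_options,
) -> SimulationConfig:
    """Build a coupled-animal simulation: resource selection, central-place
    attraction, and mutual avoidance/attraction mediated by ODs.

    Each animal starts at its own central place.  The dynamic OD
    covariates are wired to an internal :class:`ODRegistry` that
    :func:`simulate` keeps up to date.
    """
    area = StudyArea.from_raster(resource)
    registry = ODRegistry(area)
    specs = make_coupled_kernels(
        resource, centres, lam, beta_r, beta_c, interaction,
        od_provider=registry.get, kappa=kappa,
    )
    return SimulationConfig(
        kernel_specs=specs,
        initial_locations=list(centres),
        n_steps=n_steps,
        seed=seed,
        od_registry=registry,
        **od_options,
    )


def sample_step(
    spec: KernelSpec,
    x: tuple[float, float],
    bearing: float | None,
    t: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw the next location from the movement kernel.

    Exact categorical sampling over grid cells from
    :func:`stepscale.kernel.evaluate_kernel`, followed by a uniform
    jitter within the chosen cell.
    """
    area = spec.study_area
    probs = evaluate_kernel(spec, x, bearing, t).ravel()
    cdf = np.cumsum(probs)
    idx = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
    i, j = divmod(idx, area.n_cols)
    x0, y0 = area.origin
    cs = area.cell_size
    return (
        x0 + (j + rng.random()) * cs,
        y0 + (i + rng.random()) * cs,
    )


def occurrence_distribution(
    traj: Trajectory,
    window: int,
    stepping_stones_per_step: int,
    bandwidth: float,
    area: StudyArea,
    upto: int | None = None,
) -> RasterLayer:
    """Occurrence distribution of an animal's recent path.

    The last ``window`` steps (ending at fix ``upto``, default the last
    fix) are interpolated with ``stepping_stones_per_step`` straight-line
    stepping stones per step — approximating the locations visited
    between fixes — and smoothed with a Gaussian KDE of the given
    bandwidth, evaluated at cell centres and normalised to sum 1.
    """
    n_fix = len(traj) if upto is None else min(upto + 1, len(traj))
    if n_fix < 2:
        raise ValueError("occurrence distribution needs at least one step")
    start = max(0, n_fix - 1 - window)
    pts = [np.array([[traj.xs[start], traj.ys[start]]])]
    m = max(stepping_stones_per_step, 1)
    for k in range(start, n_fix - 1):
        frac = np.arange(1, m + 1)[:, None] / m  # end point included once
        p0 = np.array([traj.xs[k], traj.ys[k]])
        p1 = np.array([traj.xs[k + 1], traj.ys[k + 1]])
        pts.append(p0 + frac * (p1 - p0))
    points = np.vstack(pts)
    return _kde_layer(points, bandwidth, area, name=f"od-{traj.individual}")


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run a (coupled) individual-based simulation.

    Each step, animals move in a freshly randomised order; every
    ``od_update_interval`` steps each animal's OD is rebuilt from its
    last ``od_window`` steps (strictly before the current time) and
    published to the registry for the other animals' kernels to read.
    Output is bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_animals
    xs = [[loc[0]] for loc in config.initial_locations]
    ys = [[loc[1]] for loc in config.initial_locations]
    bearings: list[float] = [math.nan] * n
    any_dynamic = any(not s.is_static() for s in config.kernel_specs)
    od_history: list[dict[int, RasterLayer]] = []

    for step in range(config.n_steps):
        t = float(step)
        # refresh ODs from steps strictly before t
        if (
            any_dynamic
            and config.od_registry is not None
            and step > 0
            and step % config.od_update_interval == 0
        ):
            snapshot = {}
            for j in range(n):
                traj = Trajectory(
                    individual=str(j),
                    times=np.arange(len(xs[j]), dtype=float),
                    xs=np.array(xs[j]),
                    ys=np.array(ys[j]),
                )
                od = occurrence_distribution(
                    traj,
                    config.od_window,
                    config.stepping_stones_per_step,
                    config.od_bandwidth,
                    config.kernel_specs[j].study_area,
                )
                config.od_registry.set(j, od)
                snapshot[j] = od
            od_history.append(snapshot)
        for j in rng.permutation(n):
            x = (xs[j][-1], ys[j][-1])
            nxt = sample_step(config.kernel_specs[j], x, bearings[j], t, rng)
            bearings[j] = bearing_between(x[0], x[1], nxt[0], nxt[1])
            xs[j].append(nxt[0])
            ys[j].append(nxt[1])

    trajectories = [
        Trajectory(
            individual=str(j),
            times=np.arange(config.n_steps + 1, dtype=float),
            xs=np.array(xs[j]),
            ys=np.array(ys[j]),
        )
        for j in range(n)
    ]
    final_ods = {}
    for j in range(n):
        final_ods[j] = occurrence_distribution(
            trajectories[j],
            config.od_window,
            config.stepping_stones_per_step,
            config.od_bandwidth,
            config.kernel_specs[j].study_area,
        )
    return SimulationResult(trajectories, od_history, final_ods)


def simulate_replicates(
    spec: KernelSpec,
    x0: tuple[float, float],
    n_steps: int,
    n_replicates: int,
    seed: int = 0,
) -> np.ndarray:
    """End-points at time ``n_steps`` of many independent replicate paths.

    All replicates start at ``x0``.  Cell transitions are drawn from the
    same per-cell categorical law as :func:`sample_step` (columns of the
    transition matrix), vectorised across replicates, and the final cell
    is jittered uniformly.  Returns an (n_replicates, 2) array of
    end-point coordinates — genuinely independent samples of u(x, t).

    Requires a static kernel with kappa = 0.
    """
    if not spec.is_static():
        raise ValueError("replicate sampling requires a static kernel")
    rng = np.random.default_rng(seed)
    area = spec.study_area
    P = build_transition_matrix(spec).matrix
    cdfs = np.cumsum(np.asarray(P), axis=0)
    i0, j0 = area.cell_of(*x0)
    states = np.full(n_replicates, i0 * area.n_cols + j0, dtype=np.int64)
    for _ in range(n_steps):
        r = rng.random(n_replicates)
        states = (cdfs[:, states] > r[None, :]).argmax(axis=0)
    ii, jj = np.divmod(states, area.n_cols)
    x0_, y0_ = area.origin
    cs = area.cell_size
    xs = x0_ + (jj + rng.random(n_replicates)) * cs
    ys = y0_ + (ii + rng.random(n_replicates)) * cs
    return np.column_stack([xs, ys])


def endpoint_ud(
    endpoints: np.ndarray,
    bandwidth: float,
    area: StudyArea,
) -> RasterLayer:
    """KDE estimate of u(x, t) from replicate-simulation end-points."""
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.ndim != 2 or endpoints.shape[1] != 2:
        raise ValueError("endpoints must be an (n, 2) array")
    if endpoints.shape[0] < 2:
        raise ValueError("at least 2 end-points are required")
    return _kde_layer(endpoints, bandwidth, area, name="endpoint-ud")
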