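"""Parametric step-selection movement kernels on rasterised landscapes.

A movement kernel gives the probability density of stepping from a start
location x to an end location z in one fix interval tau:

    p_tau(z | x, alpha, t)  proportional to  phi_tau(z, x, alpha) * exp(beta . Z(x, z, t))

where phi_tau is a selection-free step-length (and optionally turn-angle)
component and exp(beta . Z) is the step selection function over movement
covariates Z.  The kernel is truncated to the study area Omega (the
"no go" boundary condition) and normalised so that it sums to one over
admissible grid cells.  The normalising integral is discretised by the
midpoint rule over cell centres, so the resulting per-cell distribution
is exactly stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .landscape import RasterLayer, StudyArea

__all__ = [
    "SelectionFreeKernel",
    "Covariate",
    "KernelSpec",
    "evaluate_kernel",
    "unnormalised_weights",
    "normalising_constant",
    "make_resource_central_place_kernel",
    "make_coupled_kernels",
]

_FAMILIES = ("exponential-decay", "gaussian", "uniform", "delta")


@dataclass
class SelectionFreeKernel:
    """Selection-free movement component psi_tau(l) (and optional turn kernel).

    Parameters
    ----------
    family : str
        One of ``exponential-decay`` (psi(l) = exp(-rate*l)), ``gaussian``
        (psi(l) = exp(-l^2 / 2 scale^2)), ``uniform`` (psi = 1 over Omega)
        or ``delta`` (all mass stays in the current cell).
    rate : float
        Decay rate lambda for the exponential family.
    scale : float
        Standard deviation for the gaussian family.
    kappa : float
        Concentration of the von Mises turn-angle component; 0 means no
        directional persistence (the kernel is then bearing-independent).
    tau : float
        Fix interval; step lengths are used directly (l, not l/tau), which
        coincide for the default tau = 1.
    """

    family: str = "exponential-decay"
    rate: float = 1.0
    scale: float = 1.0
    kappa: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown selection-free family {self.family!r}; "
                f"choose from {_FAMILIES}"
            )
        if self.family == "exponential-decay" and self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.family == "gaussian" and self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def step_weight(self, lengths: np.ndarray) -> np.ndarray:
        """psi_tau evaluated at an array of step lengths (unnormalised)."""
        lengths = np.asarray(lengths, dtype=float)
        if self.family == "exponential-decay":
            return np.exp(-self.rate * lengths)
        if self.family == "gaussian":
            return np.exp(-0.5 * (lengths / self.scale) ** 2)
        if self.family == "uniform":
            return np.ones_like(lengths)
        # delta: positive weight only for a zero-length step (same cell)
        return (lengths == 0.0).astype(float)

    def turn_weight(self, bearings: np.ndarray, prev_bearing: float) -> np.ndarray:
        """von Mises factor exp(kappa*cos(theta - theta_prev)); 1 when kappa=0."""
        if self.kappa == 0.0 or prev_bearing is None or math.isnan(prev_bearing):
            return np.ones_like(np.asarray(bearings, dtype=float))
        return np.exp(self.kappa * np.cos(np.asarray(bearings) - prev_bearing))


@dataclass
class Covariate:
    """One movement covariate Z_i entering the step selection function.

    kind:
      - ``"endpoint"``   — a raster layer evaluated at the step end z
      - ``"startpoint"`` — a raster layer evaluated at the step start x
      - ``"distance-to-point"`` — Euclidean distance to a fixed point
        (e.g. a den or nest site), evaluated at the step end by default
        (``at="end"``) or at the start (``at="start"``)
      - ``"dynamic"``    — a time-indexed layer provider (e.g. another
        animal's occurrence distribution), evaluated at the step end
    """

    name: str
    kind: str
    layer: RasterLayer | None = None
    point: tuple[float, float] | None = None
    provider: Callable[[float], RasterLayer] | None = None
    at: str = "end"

    def __post_init__(self) -> None:
        kinds = ("endpoint", "startpoint", "distance-to-point", "dynamic")
        if self.kind not in kinds:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("endpoint", "startpoint") and self.layer is None:
            raise ValueError(f"covariate {self.name!r} needs a raster layer")
        if self.kind == "distance-to-point" and self.point is None:
            raise ValueError(f"covariate {self.name!r} needs a point")
        if self.kind == "dynamic" and self.provider is None:
            raise ValueError(f"covariate {self.name!r} needs a layer provider")
        if self.at not in ("end", "start"):
            raise ValueError("at must be 'end' or 'start'")

    def is_endpoint_only(self) -> bool:
        """True when Z_i depends on the step end-point z only."""
        if self.kind in ("endpoint", "dynamic"):
            return True
        if self.kind == "distance-to-point":
            return self.at == "end"
        return False

    def values(
        self,
        area: StudyArea,
        x: tuple[float, float],
        t: float,
    ) -> np.ndarray:
        """Covariate value for a step from ``x`` to every cell, shape = grid."""
        if self.kind == "endpoint":
            return self.layer.values
        if self.kind == "startpoint":
            i, j = area.cell_of(*x)
            return np.full(area.shape, self.layer.values[i, j])
        if self.kind == "dynamic":
            layer = self.provider(t)
            if layer.shape != area.shape:
                raise ValueError(
                    f"dynamic covariate {self.name!r} returned a layer of "
                    f"shape {layer.shape}, expected {area.shape}"
                )
            return layer.values
        # distance-to-point
        px, py = self.point
        if self.at == "end":
            cx, cy = area.cell_centres()
            return np.hypot(cx - px, cy - py)
        d = math.hypot(x[0] - px, x[1] - py)
        return np.full(area.shape, d)


@dataclass
class KernelSpec:
    """A full movement kernel: selection-free component, covariates, beta."""

    selection_free: SelectionFreeKernel
    covariates: Sequence[Covariate]
    beta: Sequence[float]
    study_area: StudyArea

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.covariates):
            raise ValueError(
                f"beta has {len(self.beta)} entries for "
                f"{len(self.covariates)} covariates"
            )

    def is_endpoint_only(self) -> bool:
        return all(c.is_endpoint_only() for c in self.covariates)

    def is_static(self) -> bool:
        return all(c.kind != "dynamic" for c in self.covariates)


def _log_selection(
    spec: KernelSpec, x: tuple[float, float], t: float
) -> np.ndarray:
    """beta . Z(x, z, t) over all end cells z (grid-shaped)."""
    logw = np.zeros(spec.study_area.shape)
    for b, cov in zip(spec.beta, spec.covariates):
        if b != 0.0:
            logw += b * cov.values(spec.study_area, x, t)
    return logw


def unnormalised_weights(
    spec: KernelSpec,
    x: tuple[float, float],
    bearing: float | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Grid of unnormalised kernel weights phi * exp(beta . Z) from start x.

    Weights are zero outside the admissible set (the "no go" condition).
    The selection exponent is centred by its maximum before exponentiation
    for overflow safety; this cancels under normalisation.
    """
    area = spec.study_area
    if not area.contains(*x):
        raise ValueError(f"start location {x} is outside the study area")
    cx, cy = area.cell_centres()
    dx = cx - x[0]
    dy = cy - x[1]
    lengths = np.hypot(dx, dy)
    sf = spec.selection_free
    if sf.family == "delta":
        # all mass in the start cell, whatever the covariates say
        w = np.zeros(area.shape)
        i, j = area.cell_of(*x)
        w[i, j] = 1.0
    else:
        logw = _log_selection(spec, x, t)
        logw = logw - logw.max()
        w = sf.step_weight(lengths) * np.exp(logw)
        if sf.kappa > 0 and bearing is not None and not math.isnan(bearing):
            step_bearings = np.arctan2(dx, dy)  # clockwise from north
            w = w * sf.turn_weight(step_bearings, bearing)
    w = np.where(area.admissible, w, 0.0)
    return w


def evaluate_kernel(
    spec: KernelSpec,
    x: tuple[float, float],
    bearing: float | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """Per-cell movement-kernel probabilities from start location ``x``.

    Returns a grid-shaped array summing to 1 over admissible cells.
    Raises ``ValueError`` if every unnormalised weight is zero (e.g. a
    delta kernel aimed at an inadmissible cell).
    """
    w = unnormalised_weights(spec, x, bearing, t)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(
            f"kernel from {x} has no admissible mass (total weight {total})"
        )
    return w / total


def normalising_constant(
    spec: KernelSpec,
    x: tuple[float, float],
    bearing: float | None = None,
    t: float = 0.0,
) -> float:
    """Midpoint-rule normalising constant K(x, t) = sum of weights * cell area.

    Unlike :func:`unnormalised_weights` the selection exponent is *not*
    recentred, so K scales exactly as exp(c) when a constant c is added to
    beta . Z.
    """
    area = spec.study_area
    if not area.contains(*x):
        raise ValueError(f"start location {x} is outside the study area")
    cx, cy = area.cell_centres()
    lengths = np.hypot(cx - x[0], cy - x[1])
    sf = spec.selection_free
    if sf.family == "delta":
        i, j = area.cell_of(*x)
        w = np.zeros(area.shape)
        w[i, j] = math.exp(_log_selection(spec, x, t)[i, j])
    else:
        w = sf.step_weight(lengths) * np.exp(_log_selection(spec, x, t))
        if sf.kappa > 0 and bearing is not None and not math.isnan(bearing):
            step_bearings = np.arctan2(cx - x[0], cy - x[1])
            w = w * sf.turn_weight(step_bearings, bearing)
    w = np.where(area.admissible, w, 0.0)
    K = float(w.sum() * area.cell_area)
    if K <= 0 or not np.isfinite(K):
        raise ValueError(f"kernel from {x} has no admissible mass (K = {K})")
    return K


def make_resource_central_place_kernel(
    resource: RasterLayer,
    x_c: tuple[float, float],
    lam: float,
    beta_r: float,
    beta_c: float,
    kappa: float = 0.0,
    tau: float = 1.0,
) -> KernelSpec:
    """Movement kernel with resource selection plus central-place attraction.

    The unnormalised step weight is

        exp(-lam * |z - x|) * exp(beta_r * R(z) - beta_c * |z - x_C|),

    modelling movement in a heterogeneous environment with a localising
    tendency towards a single point (a den or nest site).  The
    central-place distance is taken at the step end-point so the covariate
    actually localises the animal (a start-point distance would cancel in
    the normalisation) and the kernel stays within the end-point-only
    class that admits a closed-form steady state.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    area = StudyArea.from_raster(resource)
    if not area.contains(*x_c):
        raise ValueError(f"central place {x_c} is outside the study area")
    covs = [
        Covariate(name="resource", kind="endpoint", layer=resource),
        Covariate(name="central-place", kind="distance-to-point", point=x_c),
    ]
    sf = SelectionFreeKernel(
        family="exponential-decay", rate=lam, kappa=kappa, tau=tau
    )
    return KernelSpec(sf, covs, [beta_r, -beta_c], area)


def make_coupled_kernels(
    resource: RasterLayer,
    centres: Sequence[tuple[float, float]],
    lam: float,
    beta_r: Sequence[float] | float,
    beta_c: Sequence[float] | float,
    interaction: np.ndarray,
    od_provider: Callable[[int, float], RasterLayer],
    kappa: float = 0.0,
) -> list[KernelSpec]:
    """Coupled movement kernels for N interacting animals.

    Animal j steps with unnormalised weight

        exp(-lam|z-x|) * exp(beta_r[j] R(z) - beta_c[j] |z - c_j|
                             - sum_{j'!=j} interaction[j, j'] O_{j'}(z, t))

    where O_{j'} is the occurrence distribution of animal j' at time t,
    looked up from ``od_provider(j', t)``.  A positive interaction entry
    is avoidance, a negative one attraction.  The diagonal must be zero:
    self-interaction is expressed via an explicit dynamic covariate, not
    this sum.
    """
    n = len(centres)
    interaction = np.asarray(interaction, dtype=float)
    if interaction.shape != (n, n):
        raise ValueError(f"interaction matrix must be {n}x{n}")
    if np.any(np.diag(interaction) != 0):
        raise ValueError("interaction matrix must have a zero diagonal")
    beta_r = np.broadcast_to(np.asarray(beta_r, dtype=float), (n,))
    beta_c = np.broadcast_to(np.asarray(beta_c, dtype=float), (n,))
    specs = []
    for j in range(n):
        spec = make_resource_central_place_kernel(
            resource, centres[j], lam, beta_r[j], beta_c[j], kappa=kappa
        )
        covs = list(spec.covariates)
        betas = list(spec.beta)
        for jp in range(n):
            if jp == j or interaction[j, jp] == 0.0:
                continue
            covs.append(
                Covariate(
                    name=f"od-animal-{jp}",
                    kind="dynamic",
                    provider=(lambda t, jp=jp: od_provider(jp, t)),
                )
            )
            betas.append(-interaction[j, jp])
        specs.append(KernelSpec(spec.selection_free, covs, betas, spec.study_area))
    return specs
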