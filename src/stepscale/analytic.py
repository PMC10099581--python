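"""Closed-form steady-state utilisation distributions and the PDE diffusion constant.

For movement kernels whose selection-free component depends only on step
length, psi(|x - z|), and whose covariates depend only on the step
end-point, Z_i = Z~_i(z), the steady state of the master equation has the
exact closed form (Barnett & Moorcroft)

    u*(x)  proportional to  exp(beta . Z~(x)) * integral_Omega exp(beta . Z~(z)) psi(|x - z|) dz.

Two limits bracket this expression: a psi uniform over the whole study
area collapses it to the classical resource-selection function

    u*(x) = exp(beta . Z~(x)) / sum exp(beta . Z~),

while an arbitrarily narrow psi (selection at a much finer scale than the
landscape) doubles the selection coefficients,

    u*(x) = exp(2 beta . Z~(x)) / sum exp(2 beta . Z~).

These closed forms serve as independent oracles for the numerical
master-equation engine.  The module also computes the diffusion constant
of the advection-diffusion (PDE) limit from the second moment of psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate

from .kernel import Covariate, KernelSpec, SelectionFreeKernel
from .landscape import RasterLayer, StudyArea
from .master_equation import UD

__all__ = [
    "steady_state_barnett_moorcroft",
    "steady_state_rsf",
    "steady_state_doubled",
    "diffusion_constant",
    "compare_steady_states",
    "SteadyStateComparison",
    "highest_density_region_area",
    "endpoint_log_selection",
]


def _check_endpoint_only(covariates: Sequence[Covariate]) -> None:
    for cov in covariates:
        if not cov.is_endpoint_only():
            raise ValueError(
                f"covariate {cov.name!r} (kind {cov.kind!r}, at={cov.at!r}) "
                "is not end-point-only; the closed-form steady states apply "
                "only to covariates of the step end-point"
            )
        if cov.kind == "dynamic":
            raise ValueError(
                f"covariate {cov.name!r} is dynamic; closed-form steady "
                "states require a time-invariant kernel"
            )


def endpoint_log_selection(
    beta: Sequence[float],
    covariates: Sequence[Covariate],
    area: StudyArea,
) -> np.ndarray:
    """beta . Z~(z) over the grid for end-point-only covariates."""
    _check_endpoint_only(covariates)
    logw = np.zeros(area.shape)
    for b, cov in zip(np.asarray(beta, dtype=float), covariates):
        if b != 0.0:
            logw += b * cov.values(area, (area.origin[0], area.origin[1]), 0.0)
    return logw


def _masked_softmax(logw: np.ndarray, area: StudyArea) -> UD:
    logw = logw - logw[area.admissible].max()
    w = np.where(area.admissible, np.exp(logw), 0.0)
    return UD(w / w.sum())


def steady_state_rsf(
    beta: Sequence[float],
    z_layers: Sequence[Covariate],
    area: StudyArea,
) -> UD:
    """Resource-selection-function steady state (uniform-psi limit)."""
    return _masked_softmax(endpoint_log_selection(beta, z_layers, area), area)


def steady_state_doubled(
    beta: Sequence[float],
    z_layers: Sequence[Covariate],
    area: StudyArea,
) -> UD:
    """Narrow-psi limiting steady state: selection coefficients doubled."""
    return _masked_softmax(
        2.0 * endpoint_log_selection(beta, z_layers, area), area
    )


def steady_state_barnett_moorcroft(
    psi: SelectionFreeKernel,
    beta: Sequence[float],
    z_layers: Sequence[Covariate],
    area: StudyArea,
    truncate_ratio: float = 1e-12,
) -> UD:
    """Exact closed-form steady state for end-point-only kernels.

    The inner integral over z is discretised by the midpoint rule over
    cell centres (matching the master-equation discretisation), with psi
    truncated at the radius where it falls below ``truncate_ratio`` times
    psi(0).

    Raises ``ValueError`` if psi has a turn-angle component or any
    covariate is not end-point-only.
    """
    if psi.kappa > 0:
        raise ValueError(
            "closed-form steady states require kappa = 0 (no turn-angle component)"
        )
    logw = endpoint_log_selection(beta, z_layers, area)
    logw = logw - logw[area.admissible].max()
    w = np.where(area.admissible, np.exp(logw), 0.0)  # exp(beta . Z~), rescaled

    if psi.family == "uniform":
        inner = np.full(area.shape, w.sum() * area.cell_area)
    elif psi.family == "delta":
        inner = w * area.cell_area
    else:
        # pairwise cell-centre distances; truncation radius from psi(0)
        cx, cy = area.cell_centres()
        pts = np.column_stack([cx.ravel(), cy.ravel()])
        if psi.family == "exponential-decay":
            r_max = -math.log(truncate_ratio) / psi.rate
        else:  # gaussian
            r_max = psi.scale * math.sqrt(-2.0 * math.log(truncate_ratio))
        wf = w.ravel()
        n = pts.shape[0]
        inner_flat = np.zeros(n)
        # block the pairwise distance matrix to bound peak memory
        block = max(1, int(4e6 // max(n, 1)))
        for start in range(0, n, block):
            sl = slice(start, min(start + block, n))
            d = np.hypot(
                pts[sl, 0][:, None] - pts[None, :, 0],
                pts[sl, 1][:, None] - pts[None, :, 1],
            )
            psi_d = psi.step_weight(d)
            psi_d[d > r_max] = 0.0
            inner_flat[sl] = psi_d @ wf
        inner = inner_flat.reshape(area.shape) * area.cell_area

    u = w * inner
    u = np.where(area.admissible, u, 0.0)
    total = u.sum()
    if total <= 0:
        raise ValueError("steady state has no admissible mass")
    return UD(u / total)


def diffusion_constant(psi: SelectionFreeKernel, tau: float | None = None) -> float:
    """Diffusion constant of the PDE limit from the second moment of psi.

    psi is normalised to a 2-D probability density over the plane before
    the moment is taken, giving

        D_tau = (1 / 4 tau) * E|x'|^2
              = (pi / 2 tau) * int_0^inf r^3 psi(r) dr / (2 pi int_0^inf r psi(r) dr)

    computed by adaptive radial quadrature.  A delta kernel gives 0; a
    psi whose second moment diverges (e.g. uniform over the plane) is
    rejected.
    """
    tau = psi.tau if tau is None else tau
    if tau <= 0:
        raise ValueError("tau must be positive")
    if psi.family == "delta":
        return 0.0
    if psi.family == "uniform":
        raise ValueError(
            "uniform psi has no normalisable density over the plane; its "
            "second moment diverges"
        )
    norm, norm_err = integrate.quad(
        lambda r: r * psi.step_weight(np.array([r]))[0],
        0.0, np.inf, epsabs=1e-13, epsrel=1e-11,
    )
    second, second_err = integrate.quad(
        lambda r: r**3 * psi.step_weight(np.array([r]))[0],
        0.0, np.inf, epsabs=1e-13, epsrel=1e-11,
    )
    if not (np.isfinite(norm) and np.isfinite(second)) or norm <= 0:
        raise ValueError("psi moment integrals did not converge")
    if norm_err > 1e-7 * norm or second_err > 1e-7 * max(second, 1e-300):
        raise ValueError("psi moment quadrature did not converge to tolerance")
    # E|x'|^2 = 2 pi int r^3 psi / (2 pi int r psi) = second / norm
    return second / norm / (4.0 * tau)


def highest_density_region_area(ud: UD, mass: float = 0.95) -> float:
    """Area of the smallest cell set holding ``mass`` of the distribution.

    Cells are sorted by density and accumulated until the target mass is
    reached; no smoothing is applied.  Returns the area in squared
    coordinate units (cell count times cell area for unit cells).
    """
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    p = np.sort(ud.flat())[::-1]
    csum = np.cumsum(p)
    n_cells = int(np.searchsorted(csum, mass) + 1)
    return float(n_cells)


@dataclass
class SteadyStateComparison:
    """L1 distances to a reference UD and 95% highest-density-region areas."""

    l1_exact: float
    l1_rsf: float
    l1_doubled: float
    area_exact: float
    area_rsf: float
    area_doubled: float
    area_reference: float

    def ordering_holds(self) -> bool:
        """True when the RSF region contains the exact region contains the
        doubled region (the over-/under-estimation ordering for a
        concentrating kernel)."""
        return self.area_rsf >= self.area_exact >= self.area_doubled


def compare_steady_states(
    ud_exact: UD,
    ud_rsf: UD,
    ud_doubled: UD,
    reference: UD,
    mass: float = 0.95,
    cell_area: float = 1.0,
) -> SteadyStateComparison:
    """Compare the three closed-form steady states against a reference UD."""
    for u in (ud_exact, ud_rsf, ud_doubled):
        if u.shape != reference.shape:
            raise ValueError("all UDs must share one grid")

    def l1(u: UD) -> float:
        return float(np.abs(u.flat() - reference.flat()).sum())

    def area(u: UD) -> float:
        return highest_density_region_area(u, mass) * cell_area

    return SteadyStateComparison(
        l1_exact=l1(ud_exact),
        l1_rsf=l1(ud_rsf),
        l1_doubled=l1(ud_doubled),
        area_exact=area(ud_exact),
        area_rsf=area(ud_rsf),
        area_doubled=area(ud_doubled),
        area_reference=area(reference),
    )
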