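"""Goodness-of-fit and pattern metrics for utilisation/occurrence distributions.

Comparing emergent space-use patterns between data and model output can
reveal covariates missing from a step-selection model: overlap is
measured by Bhattacharyya's affinity, distribution size by the
locational variance (proportional to standard home-range size measures
such as the 95% KDE area, but requiring no smoothing).  A simple
segregation index — one minus the mean pairwise affinity — supports
parameter sweeps over interaction strength.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .landscape import RasterLayer
from .master_equation import UD

__all__ = [
    "bhattacharyya_affinity",
    "locational_variance",
    "ud_size_ratio",
    "segregation_index",
]


def _as_grid(u) -> tuple[np.ndarray, float, tuple[float, float]]:
    """(values, cell_size, origin) from a UD, RasterLayer or bare array."""
    if isinstance(u, UD):
        return u.probabilities, 1.0, (0.0, 0.0)
    if isinstance(u, RasterLayer):
        return u.values, u.cell_size, u.origin
    return np.asarray(u, dtype=float), 1.0, (0.0, 0.0)


def _normalised(u) -> np.ndarray:
    v, _, _ = _as_grid(u)
    if np.any(v < 0):
        raise ValueError("distribution has negative entries")
    s = v.sum()
    if s <= 0:
        raise ValueError("distribution has no mass")
    if abs(s - 1.0) > 1e-8:
        warnings.warn(
            f"distribution sums to {s!r}; renormalising", stacklevel=3
        )
        v = v / s
    return v


def bhattacharyya_affinity(u1, u2) -> float:
    """Bhattacharyya's affinity BA = sum_cells sqrt(u1 * u2), in [0, 1].

    1 for identical distributions, 0 for disjoint supports.  Inputs not
    summing to 1 are renormalised with a warning.
    """
    v1 = _normalised(u1)
    v2 = _normalised(u2)
    if v1.shape != v2.shape:
        raise ValueError(
            f"grid mismatch: {v1.shape} vs {v2.shape}"
        )
    return float(np.sqrt(v1 * v2).sum())


def locational_variance(points_or_ud) -> float:
    """Mean squared distance from the (mass-weighted) centroid.

    For an (n, 2) point set: the average of |p - mean|^2.  For a UD or
    raster: sum_s u(s) |c_s - c_bar|^2 over cell centres c_s.  Units are
    squared coordinate units; invariant to translation and rotation, and
    scales as the square of a spatial dilation.
    """
    arr = (
        points_or_ud
        if isinstance(points_or_ud, np.ndarray)
        else None
    )
    if arr is not None and arr.ndim == 2 and arr.shape[1] == 2:
        if arr.shape[0] < 1:
            raise ValueError("empty point set")
        centred = arr - arr.mean(axis=0)
        return float((centred**2).sum(axis=1).mean())
    v, cs, origin = _as_grid(points_or_ud)
    w = _normalised(points_or_ud)
    n_rows, n_cols = w.shape
    xs = origin[0] + (np.arange(n_cols) + 0.5) * cs
    ys = origin[1] + (np.arange(n_rows) + 0.5) * cs
    cx, cy = np.meshgrid(xs, ys)
    mx = float((w * cx).sum())
    my = float((w * cy).sum())
    return float((w * ((cx - mx) ** 2 + (cy - my) ** 2)).sum())


def ud_size_ratio(model, reference) -> float:
    """Ratio of locational variances model / reference; 1 = size agreement."""
    ref_var = locational_variance(reference)
    if ref_var <= 0:
        raise ValueError(
            "reference distribution has zero locational variance (point mass)"
        )
    return locational_variance(model) / ref_var


def segregation_index(uds: Sequence) -> float:
    """1 - mean pairwise Bhattacharyya affinity over a set of distributions.

    0 when all distributions are identical; approaches 1 when all pairs
    have disjoint supports.  A monotone diagnostic for avoidance sweeps.
    """
    if len(uds) < 2:
        raise ValueError("segregation index needs at least 2 distributions")
    affs = []
    for a in range(len(uds)):
        for b in range(a + 1, len(uds)):
            affs.append(bhattacharyya_affinity(uds[a], uds[b]))
    return 1.0 - float(np.mean(affs))
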