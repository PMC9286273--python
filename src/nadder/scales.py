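"""Micron indexing of the Gaussian scale space.

The Gaussian standard deviation ``s`` (in samples) is not a physical
quantity: it depends on sampling rate and kernel support.  The analysis
scale is therefore expressed as a radius of curvature r_hat in micrometers
— the tightest turn surviving the smoothing.  For a target scale r_hat,
every point whose base radius of curvature lies below r_hat contributes the
first grid ``s`` at which its smoothed radius of curvature reaches r_hat;
the resulting set ``S`` of standard deviations is the working neighbourhood
in which the dimension decomposition is stabilized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import Curve3D, DifferentialProfile, differential_profile, gaussian_smooth

__all__ = ["ScaleSpaceFamily", "default_s_grid", "build_scale_space",
           "scales_for_target_radius"]

logger = logging.getLogger(__name__)


def default_s_grid(n_points: int, s_min: float = 0.5, s_max: float | None = None,
                   factor: float = 1.15) -> np.ndarray:
    """Geometric grid of Gaussian standard deviations (samples), led by 0.

    The ceiling defaults to a third of the curve's sample count: beyond
    that the kernel support covers the whole curve and every scale is
    equivalent.
    """
    if s_max is None:
        s_max = max(n_points / 3.0, 2 * s_min)
    grid = [s_min]
    while grid[-1] * factor < s_max:
        grid.append(grid[-1] * factor)
    grid.append(s_max)
    return np.concatenate([[0.0], grid])


@dataclass
class ScaleSpaceFamily:
    """A curve with its smoothed versions and cached differential profiles.

    ``curves[i]`` is the base curve convolved with a Gaussian of std
    ``s_grid[i]`` samples; entry ``s = 0`` is the base curve itself.  All
    members share the base curve's point count.
    """

    base: Curve3D
    s_grid: np.ndarray
    curves: list[Curve3D] = field(repr=False)
    profiles: list[DifferentialProfile] = field(repr=False)

    def __len__(self) -> int:
        return len(self.s_grid)

    def index_of(self, s: float) -> int:
        i = int(np.argmin(np.abs(self.s_grid - s)))
        if not np.isclose(self.s_grid[i], s):
            raise KeyError(f"s={s} not on the grid")
        return i

    @property
    def r_kappa_matrix(self) -> np.ndarray:
        """``(n_scales, n_points)`` radius-of-curvature array (um)."""
        return np.vstack([p.r_kappa for p in self.profiles])


def build_scale_space(curve: Curve3D, s_grid=None) -> ScaleSpaceFamily:
    """Smooth ``curve`` at every ``s`` of the grid and cache the profiles."""
    if s_grid is None:
        s_grid = default_s_grid(curve.n_points)
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("s_grid is empty")
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing")
    curves = [gaussian_smooth(curve, s) for s in s_grid]
    profiles = [differential_profile(c) for c in curves]
    return ScaleSpaceFamily(base=curve, s_grid=s_grid, curves=curves,
                            profiles=profiles)


def scales_for_target_radius(family: ScaleSpaceFamily, r_hat: float,
                             return_multiplicity: bool = False):
    """Set S of Gaussian stds realizing a micron scale of interest.

    For every point whose base radius of curvature is below ``r_hat``, the
    first grid ``s`` at which the point's smoothed radius of curvature
    reaches ``r_hat``; points never reaching it contribute the grid
    maximum.  Returns the deduplicated, sorted s values (empty if the base
    curve is already everywhere flatter than ``r_hat``); with
    ``return_multiplicity`` also the number of points crossing at each s
    (S is per point, so one s can be contributed many times).
    """
    if r_hat <= 0:
        raise ValueError("r_hat must be positive")
    rk = family.r_kappa_matrix
    below = rk[0] < r_hat
    empty = (np.array([]), np.array([], dtype=int))
    if not np.any(below):
        return empty if return_multiplicity else empty[0]
    reached = rk[:, below] >= r_hat  # (n_scales, n_below)
    first = np.argmax(reached, axis=0)
    never = ~reached.any(axis=0)
    if np.any(never):
        logger.debug("%d point(s) never reach r_kappa=%g within the s grid; "
                     "using the grid maximum", int(never.sum()), r_hat)
        first[never] = len(family.s_grid) - 1
    S, counts = np.unique(family.s_grid[first], return_counts=True)
    return (S, counts) if return_multiplicity else S
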