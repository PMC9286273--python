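"""Per-point local 3D scale of a curve.

The local 3D scale of a point is the smallest analysis scale (um) at which
the curve around it stops being intrinsically 3D.  Because the per-scale
dimension label of a point need not be monotone in scale, the first scale
of the *longest* non-3D run along the scale axis is used; a point that is
3D at every probed scale is assigned the highest scale of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dimdecomp import (DEFAULT_EPS_KAPPA, DEFAULT_EPS_TAU,
                        decompose_at_scale)
from .geometry import Curve3D
from .scales import build_scale_space

__all__ = ["LocalScaleProfile", "default_r_hat_grid", "dimension_track",
           "local_3d_scale", "curve_local_3d_scale", "max_scale_heuristic",
           "SCALE_MAX_PRESETS"]

#: per-analysis maxima of the scale grid (um) used for the published maps:
#: tadpole dendrites 60, zebrafish whole brain 100, mouse neurons 160,
#: torus-semicircularis afferents 175.
SCALE_MAX_PRESETS = {"tadpole": 60.0, "zebrafish": 100.0, "mouse": 160.0,
                     "ts_afferents": 175.0}


@dataclass
class LocalScaleProfile:
    """Per-point local 3D scale (um) with the label matrix behind it."""

    values: np.ndarray
    r_hat_grid: np.ndarray
    label_matrix: np.ndarray  # (n_scales, n_points)

    def to_frame(self, arc_length: np.ndarray | None = None) -> pd.DataFrame:
        d = {"local_3d_scale_um": self.values}
        if arc_length is not None:
            d = {"arc_length": arc_length, **d}
        return pd.DataFrame(d)


def default_r_hat_grid(max_scale: float, n: int = 20) -> np.ndarray:
    """Regularly spaced micron scales of interest from 1 um to the maximum.

    The grid starts at 1 um — the default sampling distance — since scales
    below the sampling distance are meaningless.
    """
    if max_scale <= 1:
        raise ValueError("max_scale must exceed 1 um")
    return np.linspace(1.0, max_scale, n)


def dimension_track(curve: Curve3D, r_hat_grid,
                    eps_kappa: float = DEFAULT_EPS_KAPPA,
                    eps_tau: float = DEFAULT_EPS_TAU,
                    eps_omega: float | None = None,
                    family=None) -> np.ndarray:
    """Per-point dimension labels at every scale of the grid.

    Row i of the result holds ``decompose_at_scale`` labels at
    ``r_hat_grid[i]``; the scale space is built once and shared.
    """
    r_hat_grid = np.asarray(r_hat_grid, dtype=float)
    if np.any(np.diff(r_hat_grid) <= 0):
        raise ValueError("r_hat_grid must be strictly increasing")
    if family is None:
        family = build_scale_space(curve)
    rows = [decompose_at_scale(curve, r, eps_kappa, eps_tau, eps_omega,
                               family=family).labels
            for r in r_hat_grid]
    return np.vstack(rows)


def local_3d_scale(label_matrix: np.ndarray, r_hat_grid) -> LocalScaleProfile:
    """Reduce a (scales x points) label matrix to the local 3D scale.

    Per point: the first scale of the longest run of non-3D labels along
    the scale axis (ties -> the run at smaller scale); max(grid) if the
    point is 3D everywhere.
    """
    label_matrix = np.asarray(label_matrix)
    r_hat_grid = np.asarray(r_hat_grid, dtype=float)
    if label_matrix.size == 0:
        raise ValueError("empty label matrix")
    if label_matrix.shape[0] != len(r_hat_grid):
        raise ValueError("matrix rows must match the scale grid")
    n_scales, n_points = label_matrix.shape
    values = np.empty(n_points)
    non3d = label_matrix != 3
    for j in range(n_points):
        col = non3d[:, j]
        best_len, best_start = 0, -1
        a = 0
        while a < n_scales:
            if col[a]:
                b = a
                while b + 1 < n_scales and col[b + 1]:
                    b += 1
                if b - a + 1 > best_len:  # strict: ties keep the earlier run
                    best_len, best_start = b - a + 1, a
                a = b + 1
            else:
                a += 1
        values[j] = r_hat_grid[best_start] if best_len else r_hat_grid[-1]
    return LocalScaleProfile(values, r_hat_grid, label_matrix)


def curve_local_3d_scale(curve: Curve3D, max_scale: float = 100.0,
                         n_scales: int = 20,
                         eps_kappa: float = DEFAULT_EPS_KAPPA,
                         eps_tau: float = DEFAULT_EPS_TAU,
                         eps_omega: float | None = None,
                         ) -> LocalScaleProfile:
    """Local 3D scale of a single (already resampled) curve."""
    grid = default_r_hat_grid(max_scale, n_scales)
    track = dimension_track(curve, grid, eps_kappa, eps_tau, eps_omega)
    return local_3d_scale(track, grid)


def max_scale_heuristic(branch_length: float) -> float:
    """Largest radius-of-curvature scale a branch can meaningfully probe.

    A radius r corresponds to a semicircle of length pi*r, so a branch of
    length l cannot exhibit turns flatter than l/pi.
    """
    if branch_length <= 0:
        raise ValueError("branch length must be positive")
    return branch_length / np.pi
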