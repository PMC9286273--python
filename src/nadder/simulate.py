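"""Ground-truth-labelled synthetic 3D curves.

Composite test curves are assembled from three fragment generators:

* 1D — uniformly sampled straight segment in a random 3D orientation;
* 2D — active Brownian motion in the z = 1 plane (directed speed v,
  angular drift Omega, rotational/translational diffusion D_R/D_T),
  followed by a random 3D rotation: curvy but exactly planar;
* 3D — a spherical-angle extension of the active Brownian model where the
  two angles (phi, theta) drift at rates cos(Omega) and sin(Omega) with
  shared rotational diffusion, producing genuinely non-planar paths.

The stochastic differential equations are integrated with the
Euler-Maruyama scheme.  Fragments are concatenated (by default rotated so
the initial tangent continues the previous fragment's final tangent, with
a random twist about it), resampled to a fixed point count and corrupted
with isotropic Gaussian white noise.  All randomness flows through a
caller-supplied ``numpy.random.Generator`` (PCG64), so a fixed seed
replays bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .dimdecomp import Fragment
from .geometry import Curve3D

__all__ = ["ABMParams", "SimulatedCurve", "abm_params_from_physics",
           "simulate_line", "simulate_planar_abm", "simulate_3d_abm",
           "simulate_composite", "random_rotation"]

# Boltzmann constant (J/K) for the optional physical parameterization
_KB = 1.380649e-23


@dataclass(frozen=True)
class ABMParams:
    """Active-Brownian-motion parameters.

    v is the directed speed (um per unit time), omega the angular drift
    (rad per unit time), d_t / d_r the translational (um^2/time) and
    rotational (rad^2/time) diffusion coefficients, dt the Euler-Maruyama
    step.  Defaults give ~1 um steps and radii of curvature of a few tens
    of um — regular, neurite-like paths whose angular drift dominates the
    rotational diffusion, so fragments keep their nominal dimensionality
    along their whole length.
    """

    v: float = 10.0
    omega: float = 0.33
    d_t: float = 0.001
    d_r: float = 0.002
    dt: float = 0.1

    def __post_init__(self):
        if self.d_t < 0 or self.d_r < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def abm_params_from_physics(temperature: float, viscosity: float,
                            radius: float, **kwargs) -> ABMParams:
    """Stokes-Einstein convenience: D_T = kT/(6 pi eta R), D_R = kT/(8 pi eta R^3)."""
    d_t = _KB * temperature / (6 * np.pi * viscosity * radius)
    d_r = _KB * temperature / (8 * np.pi * viscosity * radius**3)
    return ABMParams(d_t=d_t, d_r=d_r, **kwargs)


@dataclass
class SimulatedCurve:
    """A synthetic curve with per-point ground-truth dimension labels."""

    curve: Curve3D
    labels: np.ndarray
    boundaries: list[int] = field(default_factory=list)  # first index of each fragment
    sigma: float = 0.0
    clean: Curve3D | None = None

    def truth_fragments(self) -> list[Fragment]:
        """Ground-truth label runs as Fragment objects."""
        spacing = (self.clean or self.curve).spacing
        frags, a = [], 0
        lab = self.labels
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[a]:
                frags.append(Fragment(a, i - 1, int(lab[a]),
                                      (i - 1 - a) * spacing))
                a = i
        return frags


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn uniformly from SO(3) (unit-quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def simulate_line(n_points: int = 100, length: float | None = None,
                  rng: np.random.Generator | None = None) -> SimulatedCurve:
    """Straight segment of ``length`` um in a uniformly random orientation."""
    rng = np.random.default_rng() if rng is None else rng
    if n_points < 2:
        raise ValueError("need at least 2 points")
    if length is None:
        length = float(n_points - 1)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = np.linspace(0.0, length, n_points)
    pts = t[:, None] * direction[None, :]
    return SimulatedCurve(Curve3D(pts), np.ones(n_points, dtype=int))


def simulate_planar_abm(n_steps: int = 100, params: ABMParams | None = None,
                        rng: np.random.Generator | None = None,
                        rotate: bool = True) -> SimulatedCurve:
    """Active Brownian path in the z = 1 plane, then a random 3D rotation.

    Euler-Maruyama:  phi += Omega dt + sqrt(2 D_R dt) N,
    x += v cos(phi) dt + sqrt(2 D_T dt) N,  y likewise with sin(phi).
    """
    rng = np.random.default_rng() if rng is None else rng
    p = params or ABMParams()
    n = n_steps + 1
    dphi = p.omega * p.dt + np.sqrt(2 * p.d_r * p.dt) * rng.normal(size=n_steps)
    phi = np.concatenate([[rng.uniform(0, 2 * np.pi)], np.zeros(n_steps)])
    phi[1:] = phi[0] + np.cumsum(dphi)
    step_noise = np.sqrt(2 * p.d_t * p.dt) * rng.normal(size=(n_steps, 2))
    dxy = p.v * p.dt * np.column_stack([np.cos(phi[:-1]), np.sin(phi[:-1])])
    xy = np.vstack([[0.0, 0.0], np.cumsum(dxy + step_noise, axis=0)])
    pts = np.column_stack([xy, np.ones(n)])
    if rotate:
        pts = pts @ random_rotation(rng).T
    return SimulatedCurve(Curve3D(pts), np.full(n, 2, dtype=int))


def simulate_3d_abm(n_steps: int = 100, params: ABMParams | None = None,
                    rng: np.random.Generator | None = None) -> SimulatedCurve:
    """Spherical-angle active Brownian path (genuinely 3D).

    Euler-Maruyama:  phi += cos(Omega) dt + sqrt(2 D_R dt) N,
    theta += sin(Omega) dt + sqrt(2 D_R dt) N, and unit-speed velocity
    (v cos(theta) sin(phi), v sin(theta) sin(phi), v cos(phi)).
    """
    rng = np.random.default_rng() if rng is None else rng
    p = params or ABMParams()
    n = n_steps + 1
    dphi = (np.cos(p.omega) * p.dt
            + np.sqrt(2 * p.d_r * p.dt) * rng.normal(size=n_steps))
    dtheta = (np.sin(p.omega) * p.dt
              + np.sqrt(2 * p.d_r * p.dt) * rng.normal(size=n_steps))
    phi = np.concatenate([[rng.uniform(np.pi / 4, 3 * np.pi / 4)],
                          np.zeros(n_steps)])
    theta = np.concatenate([[rng.uniform(0, 2 * np.pi)], np.zeros(n_steps)])
    phi[1:] = phi[0] + np.cumsum(dphi)
    theta[1:] = theta[0] + np.cumsum(dtheta)
    vel = p.v * np.column_stack([np.cos(theta[:-1]) * np.sin(phi[:-1]),
                                 np.sin(theta[:-1]) * np.sin(phi[:-1]),
                                 np.cos(phi[:-1])])
    noise = np.sqrt(2 * p.d_t * p.dt) * rng.normal(size=(n_steps, 3))
    pts = np.vstack([np.zeros(3), np.cumsum(vel * p.dt + noise, axis=0)])
    return SimulatedCurve(Curve3D(pts), np.full(n, 3, dtype=int))


def _draw_fragment(dim: int, n_steps: int, rng: np.random.Generator,
                   radius_range: tuple[float, float]) -> SimulatedCurve:
    """One ~100 um fragment with feature radii of a few tens of um.

    Planar fragments are arcs of radius v/|Omega| drawn from
    ``radius_range``; 3D fragments use the spherical-angle model at unit
    angular rate, whose feature radius is ~v, with Omega kept away from
    multiples of pi/2 so both spherical angles genuinely drift (otherwise
    the path degenerates to near-planar).
    """
    if dim == 1:
        return simulate_line(n_steps + 1, float(n_steps), rng)
    if dim == 2:
        radius = rng.uniform(*radius_range)
        v = 10.0
        omega = rng.choice([-1.0, 1.0]) * v / radius
        return simulate_planar_abm(
            n_steps, ABMParams(v=v, omega=omega, dt=0.1), rng)
    # both angle drifts |cos|,|sin| in ~[0.5, 0.86]: curvature and torsion
    # radii land in ~[1.2 v, 2 v]
    v = rng.uniform(radius_range[0] * 0.8, radius_range[1] * 0.55)
    omega = (np.pi / 4 + rng.uniform(-0.25, 0.25)
             + rng.choice([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
    return simulate_3d_abm(
        n_steps, ABMParams(v=v, omega=omega, dt=1.0 / v), rng)


def simulate_composite(n_fragments: int | None = None, n_points: int = 1000,
                       sigma: float = 0.0,
                       rng: np.random.Generator | None = None,
                       dims=None, n_steps_per_fragment: int = 100,
                       join: str = "tangent",
                       radius_range: tuple[float, float] = (20.0, 50.0),
                       ) -> SimulatedCurve:
    """Composite curve of consecutive 1D/2D/3D fragments plus white noise.

    Up to five fragments of ~100 um arc length each are drawn with random
    intrinsic dimensions (consecutive ones distinct), joined continuously,
    resampled to ``n_points`` equidistant points (ground-truth labels
    carried along) and corrupted with isotropic N(0, sigma^2) noise per
    coordinate.  ``radius_range`` sets the feature radii (um) of the
    curved fragments: a few tens of um, so that analysis scales of
    1-100 um probe them without erasing them.

    ``join='tangent'`` (default) rotates each fragment so its initial
    tangent continues the previous one's final tangent, then applies a
    random twist about it; ``join='free'`` keeps each fragment's own random
    orientation, allowing corners at the joints.
    """
    rng = np.random.default_rng() if rng is None else rng
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if join not in ("tangent", "free"):
        raise ValueError("join must be 'tangent' or 'free'")
    if dims is None:
        if n_fragments is None:
            n_fragments = int(rng.integers(1, 6))
        if not 1 <= n_fragments <= 5:
            raise ValueError("n_fragments must be in 1..5")
        # consecutive fragments get distinct dimensions, so every joint is
        # a real ground-truth boundary
        dims = [int(rng.integers(1, 4))]
        while len(dims) < n_fragments:
            dims.append(int(rng.choice([d for d in (1, 2, 3)
                                        if d != dims[-1]])))
    dims = list(np.asarray(dims, dtype=int))
    pieces = [_draw_fragment(d, n_steps_per_fragment, rng, radius_range)
              for d in dims]
    # chain the pieces end-to-start
    pts_all, labels_all = [pieces[0].curve.points], [pieces[0].labels]
    for piece in pieces[1:]:
        pts = piece.curve.points - piece.curve.points[0]
        if join == "tangent":
            prev = pts_all[-1]
            t_prev = prev[-1] - prev[-2]
            t_new = pts[1] - pts[0]
            R = _rotation_aligning(t_new, t_prev)
            twist = _axis_angle(t_prev, rng.uniform(0, 2 * np.pi))
            pts = pts @ (twist @ R).T
        pts = pts + pts_all[-1][-1]
        pts_all.append(pts[1:])  # drop the duplicated joint point
        labels_all.append(piece.labels[1:])
    pts = np.vstack(pts_all)
    labels = np.concatenate(labels_all)
    # resample to n_points equidistant in arc length, carrying labels
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u_new = np.linspace(0.0, u[-1], n_points)
    spline = make_interp_spline(u, pts, k=2)
    clean_pts = np.asarray(spline(u_new))
    idx_src = np.searchsorted(u, u_new, side="right") - 1
    new_labels = labels[np.clip(idx_src, 0, len(labels) - 1)]
    boundaries = [0] + list(np.flatnonzero(np.diff(new_labels) != 0) + 1)
    clean = Curve3D(clean_pts)
    noisy_pts = clean_pts + rng.normal(scale=sigma, size=clean_pts.shape) \
        if sigma > 0 else clean_pts.copy()
    return SimulatedCurve(Curve3D(noisy_pts), new_labels, boundaries,
                          sigma=sigma, clean=clean)
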