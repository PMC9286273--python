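"""Hierarchical intrinsic-dimension decomposition at a scale of interest.

A point is *linear* when its curvature is numerically zero and *planar*
when its torsion is numerically zero; because torsion is undefined on
straight pieces, the working planarity mask is the planar-linear indicator
T = L ∪ H (a line lying in a plane must count as planar).  The
decomposition is computed not at a single Gaussian scale but across the
set S of standard deviations realizing a micron scale of interest: for
each candidate mask the fragment combination that persists over the
longest contiguous subinterval of S is selected (two passes — first
planar-linear vs 3D, then linear fragments nested inside the planar
regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .geometry import Curve3D, DifferentialProfile
from .scales import ScaleSpaceFamily, build_scale_space, scales_for_target_radius

__all__ = ["IndicatorMasks", "Fragment", "Decomposition", "indicators_at_s",
           "fragments_from_mask", "stable_fragments", "decompose_at_scale",
           "absorb_short_runs", "estimate_noise_std",
           "DEFAULT_EPS_KAPPA", "DEFAULT_EPS_TAU", "DEFAULT_EPS_OMEGA"]

logger = logging.getLogger(__name__)

# Tolerances for "numerically zero" curvature/torsion (1/um): a curvature
# radius of 100 um or more counts as straight; the torsion tolerance is
# slightly looser because finite-difference torsion is the noisier
# estimate.  The fragment length threshold (um) absorbs irrelevant short
# fragments.
DEFAULT_EPS_KAPPA = 0.01
DEFAULT_EPS_TAU = 0.015
DEFAULT_EPS_OMEGA = 5.0


@dataclass(frozen=True)
class IndicatorMasks:
    """Per-point linear (L), planar (H) and planar-linear (T = L ∪ H) masks."""

    L: np.ndarray
    H: np.ndarray
    T: np.ndarray
    s: float

    def __post_init__(self):
        if not np.all(self.T >= self.L):
            raise ValueError("T must contain L (union)")


@dataclass(frozen=True)
class Fragment:
    """Contiguous index interval [start, end] carrying a dimension label."""

    start: int
    end: int
    label: int
    length: float  # um

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.label not in (1, 2, 3):
            raise ValueError("label must be 1, 2 or 3")

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class Decomposition:
    """Ordered fragments tiling a curve at one micron scale of interest.

    ``labels`` holds the per-point dimension (1/2/3); ``fragments`` are its
    maximal runs.  ``planar_regions`` are the pass-1 planar-linear regions
    inside which the 1D fragments are nested (the hierarchy).
    """

    labels: np.ndarray
    fragments: list[Fragment]
    r_hat: float
    spacing: float
    planar_regions: list[Fragment] = field(default_factory=list)

    def __post_init__(self):
        covered = sum(f.n_samples for f in self.fragments)
        if covered != len(self.labels):
            raise AssertionError("fragments do not tile the curve")

    def to_frame(self) -> pd.DataFrame:
        """Fragment table with boundaries in micrometers."""
        return pd.DataFrame(
            [(f.start * self.spacing, f.end * self.spacing, f.label)
             for f in self.fragments],
            columns=["start_um", "end_um", "label"])

    def to_points_frame(self) -> pd.DataFrame:
        """Per-point table (index, arc_length, dim_label)."""
        idx = np.arange(len(self.labels))
        return pd.DataFrame({"index": idx,
                             "arc_length": idx * self.spacing,
                             "dim_label": self.labels})


def indicators_at_s(profile: DifferentialProfile,
                    eps_kappa: float = DEFAULT_EPS_KAPPA,
                    eps_tau: float = DEFAULT_EPS_TAU,
                    s: float = np.nan) -> IndicatorMasks:
    """Binary linear/planar indicators from a differential profile.

    Where torsion is undefined (curvature at the numerical floor) the
    planar mask inherits the linear one: a straight piece belongs to any
    plane containing it.
    """
    L = profile.kappa <= eps_kappa
    with np.errstate(invalid="ignore"):
        H = np.where(profile.tau_defined, np.abs(profile.tau) <= eps_tau, L)
    H = H.astype(bool)
    return IndicatorMasks(L=L, H=H, T=L | H, s=s)


def fragments_from_mask(mask: np.ndarray, eps_omega: float,
                        spacing: float = 1.0, label: int = 2,
                        fill_gaps: bool = True) -> list[Fragment]:
    """Maximal runs of 1s in ``mask`` longer than ``eps_omega`` (um).

    With ``fill_gaps`` (default), complement runs shorter than
    ``eps_omega`` are filled first — a 2-sample hole in a long planar
    region is itself an irrelevant small fragment, and removing it keeps
    the fragment count stable across scales.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    if fill_gaps and eps_omega > 0:
        mask = _binary_clean(mask, int(np.ceil(eps_omega / spacing)))
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    out = []
    for a, b in zip(starts, ends):
        length = (b - a) * spacing
        if length >= eps_omega:
            out.append(Fragment(int(a), int(b), label, length))
    return out


def _binary_clean(mask: np.ndarray, min_samples: int) -> np.ndarray:
    """Resolve a binary mask at the fragment-length resolution.

    A majority filter of width ``min_samples`` settles salt-and-pepper
    flicker to the locally dominant value; remaining 0-gaps shorter than
    ``min_samples`` are then filled and short 1-runs dropped.
    """
    if min_samples > 2 and len(mask) > min_samples:
        w = min(min_samples | 1, (len(mask) - 1) | 1)
        mask = uniform_filter1d(mask.astype(float), w, mode="nearest") > 0.5
    mask = mask.copy()
    for target in (False, True):
        a = 0
        n = len(mask)
        i = 1
        while i <= n:
            if i == n or mask[i] != mask[a]:
                boundary_gap = (target is False) and (a == 0 or i == n)
                if mask[a] == target and i - a < min_samples \
                        and not boundary_gap:
                    mask[a:i] = not target
                a = i
            i += 1
    return mask


def _runs_of_equal(values: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal runs of equal consecutive values."""
    runs = []
    a = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[a]:
            runs.append((a, i))
            a = i
    return runs


def stable_fragments(family: ScaleSpaceFamily, S: np.ndarray, mask_kind: str,
                     eps_kappa: float = DEFAULT_EPS_KAPPA,
                     eps_tau: float = DEFAULT_EPS_TAU,
                     eps_omega: float = DEFAULT_EPS_OMEGA,
                     weights: np.ndarray | None = None,
                     candidate: str = "longest",
                     ) -> tuple[list[Fragment], np.ndarray]:
    """Most stable fragment combination of a mask across the scale set S.

    Fragments of the chosen mask are computed at every s in S; consecutive
    s values sharing the same fragment count form subintervals, and the
    heaviest subinterval (ties -> larger s) defines the winning
    combination.  Subinterval weight defaults to its number of s values;
    ``weights`` (e.g. how many points of the curve cross r_hat at each s)
    refines the vote.  Zero-fragment subintervals are only eligible when
    every s yields zero fragments — "no fragments" is the degenerate
    all-3D outcome, not a combination.  Within the winning subinterval
    each fragment position keeps its longest candidate across s
    (``candidate='first'`` keeps the least-smoothed one instead); overlaps
    between selected fragments are split in half.

    Returns the fragments and the s values of the winning subinterval.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("scale set S is empty")
    if mask_kind not in ("L", "T"):
        raise ValueError("mask_kind must be 'L' or 'T'")
    if weights is None:
        weights = np.ones(len(S))
    weights = np.asarray(weights, dtype=float)
    label = 1 if mask_kind == "L" else 2
    per_s: list[list[Fragment]] = []
    masks_s, spacings = [], []
    for s in S:
        i = family.index_of(s)
        masks = indicators_at_s(family.profiles[i], eps_kappa, eps_tau, s=s)
        mask = masks.L if mask_kind == "L" else masks.T
        spacing = family.curves[i].spacing
        masks_s.append(mask)
        spacings.append(spacing)
        per_s.append(fragments_from_mask(mask, eps_omega, spacing, label))
    counts = np.array([len(f) for f in per_s])
    runs = _runs_of_equal(counts)
    eligible = [r for r in runs if counts[r[0]] > 0]
    if not eligible:
        a, b = max(runs, key=lambda r: (weights[r[0]:r[1]].sum(), r[0]))
        return [], S[a:b]
    a, b = max(eligible, key=lambda r: (weights[r[0]:r[1]].sum(), r[0]))
    sub = per_s[a:b]
    n_frag = counts[a]
    if candidate == "consensus":
        # majority vote of the masks over the winning subinterval
        w = weights[a:b]
        maj = (np.average(np.vstack(masks_s[a:b]), axis=0, weights=w) >= 0.5)
        mid = a + (b - 1 - a) // 2
        return (fragments_from_mask(maj, eps_omega, spacings[mid], label),
                S[a:b])
    # fragment positions are matched across s by their order along the curve
    chosen = []
    for k in range(n_frag):
        candidates = [frags[k] for frags in sub]
        if candidate == "longest":
            chosen.append(max(candidates, key=lambda f: f.n_samples))
        elif candidate == "first":
            chosen.append(candidates[0])
        elif candidate == "median":
            start = int(np.median([f.start for f in candidates]))
            end = int(np.median([f.end for f in candidates]))
            sp = spacings[a + (b - 1 - a) // 2]
            chosen.append(Fragment(start, max(end, start), label,
                                   (max(end, start) - start) * sp))
        else:
            raise ValueError("candidate must be 'longest', 'first', "
                             "'median' or 'consensus'")
    chosen.sort(key=lambda f: f.start)
    # split any overlap between neighbours in half
    resolved = [chosen[0]]
    for f in chosen[1:]:
        prev = resolved[-1]
        if f.start <= prev.end:
            mid = (f.start + prev.end) // 2
            spacing = prev.length / max(prev.n_samples - 1, 1)
            if mid < prev.start or mid + 1 > f.end:
                # one fragment swallows the other; keep the longer
                if f.n_samples > prev.n_samples:
                    resolved[-1] = f
                continue
            resolved[-1] = Fragment(prev.start, mid, prev.label,
                                    (mid - prev.start) * spacing)
            f = Fragment(mid + 1, f.end, f.label,
                         (f.end - mid - 1) * spacing)
        resolved.append(f)
    return resolved, S[a:b]


def absorb_short_runs(labels: np.ndarray, eps_omega: float,
                      spacing: float) -> np.ndarray:
    """Merge label runs shorter than ``eps_omega`` um into a neighbour.

    The shortest run is merged first (into its left neighbour, or the
    right one at the curve start) and the scan repeats until every run is
    long enough — the same length filter the indicator masks go through,
    applied to an assembled labelling.
    """
    labels = np.asarray(labels).copy()
    min_samples = int(np.ceil(eps_omega / spacing))
    while True:
        runs = [(a, b) for a, b in _runs_of_equal(labels)]
        if len(runs) <= 1:
            return labels
        i = min(range(len(runs)), key=lambda k: runs[k][1] - runs[k][0])
        a, b = runs[i]
        if b - a >= min_samples:
            return labels
        na, _ = runs[i - 1] if i > 0 else runs[i + 1]
        labels[a:b] = labels[na]


def _runs_to_fragments(labels: np.ndarray, spacing: float) -> list[Fragment]:
    frags = []
    a = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[a]:
            frags.append(Fragment(a, i - 1, int(labels[a]),
                                  (i - 1 - a) * spacing))
            a = i
    return frags


def estimate_noise_std(points: np.ndarray) -> float:
    """Robust white-noise std estimate from second differences (um).

    For a smooth curve plus iid Gaussian noise, the second differences
    are noise-dominated with std ``sigma * sqrt(6)`` per coordinate; the
    median absolute value gives a robust estimate.
    """
    d2 = np.diff(np.asarray(points, dtype=float), n=2, axis=0)
    return float(np.median(np.abs(d2)) / (0.6745 * np.sqrt(6)))


def decompose_at_scale(curve: Curve3D, r_hat: float,
                       eps_kappa: float = DEFAULT_EPS_KAPPA,
                       eps_tau: float = DEFAULT_EPS_TAU,
                       eps_omega: float | None = None,
                       family: ScaleSpaceFamily | None = None,
                       s_grid=None, stability_weight: str = "points",
                       candidate: str = "median",
                       scale_quantile: float = 0.5,
                       scale_halfwidth: int | None = 3,
                       noise_sigma: float | None = None,
                       noise_margin: float = 2.0) -> Decomposition:
    """Two-pass hierarchical decomposition of a curve at a micron scale.

    The per-point crossing scales (first s at which a point's smoothed
    radius of curvature reaches ``r_hat``) define the working scale
    neighbourhood: the grid scales within ``scale_halfwidth`` steps of the
    ``scale_quantile`` of the crossing distribution — the regime where the
    curve's sub-``r_hat`` detail has just been flattened
    (``scale_halfwidth=None`` uses the full crossing set instead).  If the
    curve carries measurement noise, the neighbourhood is additionally
    floored at the smoothing scale where residual white noise of std
    ``noise_sigma`` (estimated from second differences when not given; on
    a pre-smoothed curve pass the raw estimate) can no longer masquerade
    as curvature above ``eps_kappa``.  Pass 1 finds the stable
    planar-linear (T) regions across that neighbourhood — their
    complement is 3D.  Pass 2 reruns the search on the linear (L) mask
    restricted to the s-subinterval found in pass 1, nesting 1D fragments
    inside the planar regions.

    ``eps_omega`` (minimum fragment length, um) defaults to half the
    analysis scale with a 10 um floor: structure shorter than the scale
    of interest cannot be resolved at that scale.

    A prebuilt ``family`` for the same curve may be passed to amortize the
    scale-space cost over several calls.
    """
    if family is None:
        family = build_scale_space(curve, s_grid)
    if eps_omega is None:
        eps_omega = max(10.0, 0.5 * r_hat)
    spacing = curve.spacing
    n = curve.n_points
    if curve.length < eps_omega:
        logger.warning("curve shorter than eps_omega=%g um; labelling it 3D",
                       eps_omega)
        labels = np.full(n, 3)
        return Decomposition(labels, _runs_to_fragments(labels, spacing),
                             r_hat, spacing)
    S, mult = scales_for_target_radius(family, r_hat,
                                       return_multiplicity=True)
    if S.size == 0:
        # base curve already flatter than r_hat everywhere
        anchor = 0
    else:
        cum = np.cumsum(mult)
        s_star = S[min(np.searchsorted(cum, scale_quantile * cum[-1]),
                       len(S) - 1)]
        anchor = int(np.argmin(np.abs(family.s_grid - s_star)))
    if noise_sigma is None:
        noise_sigma = estimate_noise_std(curve.points)
    if noise_sigma > 0.05:
        # smallest s at which white noise of this std no longer produces
        # curvature above eps_kappa (with a safety margin):
        # kappa_noise(s) ~ sigma / (sqrt(2 sqrt(pi) s) * (s h)^2)
        tail = family.curves[-1]
        h = tail.length / tail.n_points
        s_noise = (noise_margin * noise_sigma
                   / (1.88 * eps_kappa * h * h)) ** 0.4
        anchor = max(anchor, int(np.argmin(np.abs(family.s_grid - s_noise))))
    if scale_halfwidth is None and S.size:
        S_work, weights = S, mult.astype(float)
    else:
        lo = max(anchor - (scale_halfwidth or 0), 0)
        hi = min(anchor + (scale_halfwidth or 0), len(family.s_grid) - 1)
        S_work = family.s_grid[lo:hi + 1]
        weights = np.ones(hi - lo + 1)
    if stability_weight != "points":
        weights = None
    planar, S_sub = stable_fragments(family, S_work, "T", eps_kappa, eps_tau,
                                     eps_omega, weights=weights,
                                     candidate=candidate)
    # sample->um conversions use the arc length of the working member:
    # the base curve's own arc length is inflated by noise
    sp_work = family.curves[family.index_of(S_sub[len(S_sub) // 2])].spacing
    sub_w = weights[np.isin(S_work, S_sub)] if weights is not None else None
    linear, _ = stable_fragments(family, S_sub, "L", eps_kappa, eps_tau,
                                 eps_omega, weights=sub_w,
                                 candidate=candidate)
    labels = np.full(n, 3)
    for f in planar:
        labels[f.start:f.end + 1] = 2
    for f in linear:
        idx = f.indices()
        idx = idx[labels[idx] == 2]  # hierarchy: 1D only inside pass-1 regions
        labels[idx] = 1
    labels = absorb_short_runs(labels, eps_omega, sp_work)
    return Decomposition(labels, _runs_to_fragments(labels, sp_work),
                         r_hat, sp_work, planar_regions=planar)
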