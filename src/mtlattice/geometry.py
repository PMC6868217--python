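"""Lattice measurements: diameter, dimer separations, lateral angle, skew.

These are the quantities by which decorated-MT architectures are
compared: the MT diameter (from dimer centre-of-mass radii), the
centre-of-mass distance between adjacent B-lattice dimers within one
3-start helical turn, the interprotofilament lateral angle subtended at
the helical axis, and the protofilament skew expressed as the rotation
angle about the axis (PHI) change per dimer toward the plus end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .lattice_synth import Lattice

__all__ = [
    "SkewMeasurement",
    "LatticeComparison",
    "fit_helical_axis",
    "measure_diameter",
    "adjacent_dimer_separations",
    "lateral_angle",
    "compare_lateral_angle",
    "fit_phi_slope",
    "compare_lattices",
]


@dataclass(frozen=True)
class SkewMeasurement:
    """Protofilament skew aggregated over a set of MTs."""

    dphi_per_dimer: float  # deg/dimer, mean across MTs
    theta_deg: float  # skew angle via closure at the stated radius
    per_mt_values: tuple[float, ...]
    mean: float
    sd: float


@dataclass(frozen=True)
class LatticeComparison:
    """Reference-minus-test architecture differences."""

    diameter_diff: float  # A, reference - test
    separation_diffs: tuple[float, ...]  # per junction, reference - test
    mean_sep_diff: float
    sep_diff_sd: float
    lateral_angle_diff: float  # deg, reference - test


def _as_axis(lat_or_points, axis):
    """Resolve (points_for_fit, axis_point, axis_dir) for a lattice/array."""
    if axis is not None:
        p, d = axis
        d = np.asarray(d, dtype=float)
        return np.asarray(p, dtype=float), d / np.linalg.norm(d)
    if isinstance(lat_or_points, Lattice):
        t = lat_or_points.truth
        return t.axis_point, t.axis_direction
    pts = np.asarray(lat_or_points, dtype=float)
    return fit_helical_axis(pts)


def fit_helical_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cylinder axis through a point cloud.

    Minimises the variance of point-to-axis distances over axis position
    (2 dof) and direction (2 dof), starting from the z axis through the
    centroid.  Returns (point_on_axis, unit_direction).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 6:
        raise ValueError("need at least 6 points to fit a cylinder axis")
    centroid = pts.mean(axis=0)

    def residual(params):
        x0, y0, ax, ay = params
        d = np.array([ax, ay, 1.0])
        d /= np.linalg.norm(d)
        p0 = centroid + np.array([x0, y0, 0.0])
        rel = pts - p0
        radial = rel - np.outer(rel @ d, d)
        dist = np.linalg.norm(radial, axis=1)
        return dist - dist.mean()

    sol = least_squares(residual, x0=np.zeros(4), method="lm")
    x0, y0, ax, ay = sol.x
    d = np.array([ax, ay, 1.0])
    d /= np.linalg.norm(d)
    return centroid + np.array([x0, y0, 0.0]), d


def _radial_distances(coms: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray):
    rel = coms - axis_point
    radial = rel - np.outer(rel @ axis_dir, axis_dir)
    return np.linalg.norm(radial, axis=-1)


def measure_diameter(lat: Lattice, axis=None) -> tuple[float, np.ndarray]:
    """MT diameter and per-protofilament radii from dimer COMs.

    The diameter is twice the mean radial distance of all dimer centres
    of mass to the helical axis.  Generated lattices carry their true
    axis (updated under rigid motion); pass ``axis=(point, direction)``
    to override, or use :func:`fit_helical_axis` for external models.
    """
    if lat.n_pf < 3:
        raise ValueError("axis is undefined for fewer than 3 protofilaments")
    axis_point, axis_dir = _as_axis(lat, axis)
    coms = lat.dimer_coms()  # (N, n_dimers, 3)
    radii = _radial_distances(coms.reshape(-1, 3), axis_point, axis_dir)
    per_pf = radii.reshape(lat.n_pf, lat.n_dimers).mean(axis=1)
    return 2.0 * float(radii.mean()), per_pf


def adjacent_dimer_separations(
    lat: Lattice, exclude_seam: bool = True, ring: int | None = None
) -> np.ndarray:
    """COM distances between laterally adjacent dimers in one 3-start turn.

    For each lateral junction k (pf k vs pf k+1 mod N) the dimer on pf k
    at the chosen ring level is paired with the axially nearest dimer on
    pf k+1 and the Euclidean COM distance reported.  The seam junction
    is excluded by default (the comparison concerns B-lattice dimers),
    leaving N-1 values per ring.
    """
    N = lat.n_pf
    # the wrap-around junction's lateral partner sits ~S monomers up, so
    # keep the ring far enough from the lattice top for it to exist
    top = max(0, lat.n_dimers - 1 - (lat.spec.start + 1) // 2)
    if ring is None:
        ring = min(lat.n_dimers // 2, top)
    elif not 0 <= ring <= top:
        raise ValueError(f"ring must be in [0, {top}] for this lattice")
    coms = lat.dimer_coms()
    axis_point, axis_dir = lat.truth.axis_point, lat.truth.axis_direction
    z = (coms - axis_point) @ axis_dir  # axial coordinate per dimer
    seps = []
    for k in range(N):
        if exclude_seam and k == lat.truth.seam_index:
            continue
        k2 = (k + 1) % N
        ref = coms[k, ring]
        j = int(np.argmin(np.abs(z[k2] - z[k, ring])))
        seps.append(float(np.linalg.norm(coms[k2, j] - ref)))
    return np.array(seps)


def lateral_angle(lat: Lattice, axis=None) -> float:
    """Mean angle (deg) subtended at the axis by adjacent protofilaments.

    Each protofilament's centre line is reduced to the azimuth of its
    mean position about the helical axis; successive azimuth gaps are
    averaged.  For an ideal N-protofilament MT this is 360/N.
    """
    if lat.n_pf < 3:
        raise ValueError("lateral angle needs at least 3 protofilaments")
    axis_point, axis_dir = _as_axis(lat, axis)
    # orthonormal frame perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis_dir) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis_dir) * axis_dir
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)

    positions = lat.monomer_positions().reshape(lat.n_pf, -1, 3)
    azimuths = []
    for k in range(lat.n_pf):
        rel = positions[k].mean(axis=0) - axis_point
        azimuths.append(np.degrees(np.arctan2(rel @ v, rel @ u)))
    azimuths = np.sort(np.mod(azimuths, 360.0))
    gaps = np.diff(np.concatenate([azimuths, [azimuths[0] + 360.0]]))
    return float(gaps.mean())


def compare_lateral_angle(lat_a: Lattice, lat_b: Lattice) -> float:
    """Lateral-angle difference A - B in degrees.

    Angles subtended at each lattice's own fitted/true axis are
    intrinsic, so no explicit superposition on a shared protofilament
    is required before differencing.
    """
    return lateral_angle(lat_a) - lateral_angle(lat_b)


def _unwrap(phi: np.ndarray, period: float) -> np.ndarray:
    """Unwrap angles by mapping successive differences into (-p/2, p/2]."""
    out = np.array(phi, dtype=float)
    for i in range(1, len(out)):
        d = out[i] - out[i - 1]
        d -= period * np.floor(d / period + 0.5)
        out[i] = out[i - 1] + d
    return out


def fit_phi_slope(
    mts: Sequence[np.ndarray],
    dimer_repeat: float = 82.0,
    n_pf: int = 13,
    radius: float = 105.0,
) -> SkewMeasurement:
    """Protofilament skew from per-segment (z, phi) observations.

    ``mts`` is a sequence of arrays of shape (n_segments, 2) holding the
    axial position z (A) and rotation angle phi (deg) of each ~82 A
    segment, ordered toward the plus end.  Per MT, phi is unwrapped into
    the nearest branch of the protofilament spacing (period 360/n_pf)
    and regressed against the dimer index z / dimer_repeat; the slope is
    the PHI change per dimer.  Slopes are aggregated as mean +/- SD
    across MTs, and the skew angle theta follows from lattice closure at
    the stated radius.
    """
    period = 360.0 / n_pf
    slopes = []
    for seg in mts:
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2 or seg.shape[0] < 3:
            raise ValueError("each MT needs at least 3 segments")
        z, phi = seg[:, 0], seg[:, 1]
        if np.ptp(z) == 0:
            raise ValueError("slope undefined: all segments at identical z")
        x = z / dimer_repeat
        y = _unwrap(phi, period)
        slopes.append(float(np.polyfit(x, y, 1)[0]))
    slopes = np.array(slopes)
    mean = float(slopes.mean())
    sd = float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0
    theta = float(
        np.degrees(np.arctan(np.radians(mean) * radius / dimer_repeat))
    )
    return SkewMeasurement(
        dphi_per_dimer=mean,
        theta_deg=theta,
        per_mt_values=tuple(slopes),
        mean=mean,
        sd=sd,
    )


def compare_lattices(reference: Lattice, test: Lattice) -> LatticeComparison:
    """Architecture comparison (reference - test), mirroring the
    diameter-contraction / dimer-separation / lateral-angle readouts."""
    d_ref, _ = measure_diameter(reference)
    d_test, _ = measure_diameter(test)
    s_ref = adjacent_dimer_separations(reference)
    s_test = adjacent_dimer_separations(test)
    diffs = s_ref - s_test
    return LatticeComparison(
        diameter_diff=d_ref - d_test,
        separation_diffs=tuple(float(x) for x in diffs),
        mean_sep_diff=float(diffs.mean()),
        sep_diff_sd=float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        lateral_angle_diff=compare_lateral_angle(reference, test),
    )
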