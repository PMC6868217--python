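"""Synthetic pseudo-helical microtubule lattices with ground truth.

A microtubule (MT) wall is modelled as N protofilaments of alternating
alpha/beta tubulin monomers arranged on a cylinder.  Lateral monomer
contacts trace an S-start helix (S = 3 for canonical MTs) whose closure
around the wall couples the protofilament skew angle theta, the lateral
monomer rise h and the per-dimer rotation about the axis (Delta-PHI):

    tan(theta) = (S*a - N*h) / (2*pi*r)
    dPHI/dimer = (2*a*tan(theta) / r) * 180/pi

where a is the axial monomer repeat (~41 A, so the dimer repeat is
~82 A) and r the radius of the monomer centres.  Positive theta is a
right-handed skew: the azimuth PHI increases toward the plus end (+z).

Each monomer carries a small 5-point rigid pseudo-atom body (~20 A
across) so that skew generated by whole-protofilament *tilt* (bodies
co-rotate with the protofilament) can be distinguished from skew
generated by interdimer *stagger* (bodies stay axis-aligned while
successive dimers are offset tangentially) -- the two accommodation
mechanisms a point lattice cannot tell apart.

The wall is a B-lattice (alpha beside alpha) with a single A-lattice
seam junction (alpha beside beta) whose position and global alpha/beta
register are part of the ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "MONOMER_TEMPLATE",
    "LatticeSpec",
    "MonomerSite",
    "LatticeTruth",
    "Lattice",
    "accommodation_solve",
    "build_lattice",
    "perturb_lattice",
    "spec_to_dict",
    "spec_from_dict",
]

# Canonical 5-point rigid body, centred on its centroid.  Spans ~20 A in
# every direction and is chiral/non-planar so a rigid fit to it has a
# unique rotation.
_RAW_TEMPLATE = np.array(
    [
        [0.0, 0.0, -9.0],
        [8.0, 0.0, -2.0],
        [0.0, 7.0, 3.0],
        [-7.0, -2.0, 2.0],
        [1.0, -6.0, 8.0],
    ]
)
MONOMER_TEMPLATE = _RAW_TEMPLATE - _RAW_TEMPLATE.mean(axis=0)

_SKEW_MODES = ("by_theta", "by_rise", "by_dphi")
_MECHANISMS = ("none", "tilt", "stagger")


@dataclass(frozen=True)
class LatticeSpec:
    """Parametric description of one synthetic MT lattice.

    Parameters
    ----------
    n_pf:
        Protofilament count N (8..17; 13 and 14 are the biologically
        dominant architectures).
    start:
        Monomer-based helix start number S (default 3); must be odd so
        that a single seam is consistent with wall closure.
    monomer_repeat:
        Axial monomer spacing a along a protofilament, Angstrom.
    radius:
        Radial distance of monomer centres from the helical axis, A.
    skew_mode, skew_value:
        Which of (theta [deg], h [A], dPHI-per-dimer [deg]) is supplied;
        the other two follow from lattice closure.
    mechanism:
        How skew is realised in the bodies: ``none``, ``tilt`` or
        ``stagger`` (see module docstring).
    seam_index:
        Lateral junction (between pf k and k+1 mod N) carrying the
        A-lattice seam contact.
    register:
        Global alpha/beta register, 0 or 1; 1 translates the whole
        decoration by one monomer (a Angstrom) along the axis.
    n_dimers:
        Dimers per protofilament.
    pf_radial_offsets:
        Per-protofilament radial displacement Delta-r_k in Angstrom.
    lateral_compression:
        Reduction (A) of the adjacent B-lattice dimer COM separation,
        realised as a uniform radial contraction.
    coord_noise_sd:
        Isotropic Gaussian jitter applied to every pseudo-atom, A.
    seed:
        Seed of the single generator owning all randomness.
    """

    n_pf: int = 13
    start: int = 3
    monomer_repeat: float = 41.0
    radius: float = 105.0
    skew_mode: str = "by_theta"
    skew_value: float = 0.0
    mechanism: str = "none"
    seam_index: int = 0
    register: int = 0
    n_dimers: int = 12
    pf_radial_offsets: tuple[float, ...] | None = None
    lateral_compression: float = 0.0
    coord_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 8 <= self.n_pf <= 17:
            raise ValueError(f"n_pf must be in [8, 17], got {self.n_pf}")
        if self.start < 1:
            raise ValueError("start number S must be >= 1")
        if self.start % 2 == 0:
            raise ValueError(
                "even start numbers cannot close a B-lattice wall with a "
                "single A-lattice seam; S must be odd"
            )
        if self.monomer_repeat <= 0 or self.radius <= 0:
            raise ValueError("monomer_repeat and radius must be positive")
        if self.skew_mode not in _SKEW_MODES:
            raise ValueError(f"skew_mode must be one of {_SKEW_MODES}")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if not 0 <= self.seam_index < self.n_pf:
            raise ValueError("seam_index must lie in [0, n_pf)")
        if self.register not in (0, 1):
            raise ValueError("register must be 0 or 1")
        if self.n_dimers < 1:
            raise ValueError("need at least one dimer per protofilament")
        if self.pf_radial_offsets is not None:
            offs = tuple(float(x) for x in self.pf_radial_offsets)
            if len(offs) != self.n_pf:
                raise ValueError("pf_radial_offsets must have length n_pf")
            object.__setattr__(self, "pf_radial_offsets", offs)
        if self.coord_noise_sd < 0:
            raise ValueError("coord_noise_sd must be non-negative")

    @property
    def offsets(self) -> np.ndarray:
        if self.pf_radial_offsets is None:
            return np.zeros(self.n_pf)
        return np.asarray(self.pf_radial_offsets, dtype=float)

    @property
    def dimer_repeat(self) -> float:
        return 2.0 * self.monomer_repeat


@dataclass(frozen=True)
class MonomerSite:
    """One tubulin monomer: centre, kind and its 5-atom rigid body."""

    pf_index: int
    axial_index: int
    kind: str  # "alpha" | "beta"
    dimer_index: int
    position: np.ndarray  # (3,) body centroid
    body_atoms: np.ndarray  # (5, 3)
    orientation: np.ndarray  # (3, 3) rotation, columns = body frame


@dataclass(frozen=True)
class LatticeTruth:
    """Realised ground-truth parameters of a generated lattice."""

    theta_deg: float
    rise: float
    dphi_per_dimer: float
    diameter: float
    seam_index: int
    register: int
    axis_point: np.ndarray  # a point on the helical axis
    axis_direction: np.ndarray  # unit vector toward the plus end


@dataclass(frozen=True)
class Lattice:
    spec: LatticeSpec
    monomers: tuple[MonomerSite, ...]
    truth: LatticeTruth

    @property
    def n_pf(self) -> int:
        return self.spec.n_pf

    @property
    def n_dimers(self) -> int:
        return self.spec.n_dimers

    def atom_coords(self) -> np.ndarray:
        """All pseudo-atom coordinates, shape (n_monomers, 5, 3)."""
        return np.array([m.body_atoms for m in self.monomers])

    def monomer_positions(self) -> np.ndarray:
        return np.array([m.position for m in self.monomers])

    def monomer(self, pf: int, axial: int) -> MonomerSite:
        return self.monomers[pf * 2 * self.spec.n_dimers + axial]

    def dimer_com(self, pf: int, dimer: int) -> np.ndarray:
        """Centre of mass of a dimer's 10 pseudo-atoms."""
        a = self.monomer(pf, 2 * dimer)
        b = self.monomer(pf, 2 * dimer + 1)
        return (a.body_atoms.sum(axis=0) + b.body_atoms.sum(axis=0)) / 10.0

    def dimer_coms(self) -> np.ndarray:
        """COMs of all dimers, shape (n_pf, n_dimers, 3)."""
        out = np.empty((self.n_pf, self.n_dimers, 3))
        for k in range(self.n_pf):
            for d in range(self.n_dimers):
                out[k, d] = self.dimer_com(k, d)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Lattice":
        """Apply a global rigid motion x -> R x + t; truth axis follows."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        monomers = tuple(
            replace(
                m,
                position=R @ m.position + t,
                body_atoms=m.body_atoms @ R.T + t,
                orientation=R @ m.orientation,
            )
            for m in self.monomers
        )
        truth = replace(
            self.truth,
            axis_point=R @ self.truth.axis_point + t,
            axis_direction=R @ self.truth.axis_direction,
        )
        return Lattice(self.spec, monomers, truth)


def accommodation_solve(spec: LatticeSpec) -> tuple[float, float, float]:
    """Solve lattice closure for (theta [deg], h [A], dPHI/dimer [deg]).

    Exactly one of the three is supplied through ``spec.skew_mode`` /
    ``spec.skew_value``; the other two follow from

        tan(theta) = (S*a - N*h) / (2*pi*r)
        dPHI/dimer = (2*a*tan(theta)/r) * 180/pi

    Raises ``ValueError`` for non-physical solutions (|theta| >= 90 deg
    or lateral rise h <= 0).
    """
    N, S = spec.n_pf, spec.start
    a, r = spec.monomer_repeat, spec.radius
    mode, value = spec.skew_mode, float(spec.skew_value)

    if mode == "by_theta":
        if abs(value) >= 90.0:
            raise ValueError("|theta| must be < 90 degrees")
        tan_theta = math.tan(math.radians(value))
    elif mode == "by_rise":
        if value <= 0:
            raise ValueError("lateral rise h must be positive")
        tan_theta = (S * a - N * value) / (2.0 * math.pi * r)
    else:  # by_dphi
        tan_theta = math.radians(value) * r / (2.0 * a)

    theta = math.degrees(math.atan(tan_theta))
    h = (S * a - 2.0 * math.pi * r * tan_theta) / N
    dphi = math.degrees(2.0 * a * tan_theta / r)
    if abs(theta) >= 90.0:
        raise ValueError("solved skew angle is non-physical (|theta| >= 90)")
    if h <= 0:
        raise ValueError(f"solved lateral rise h = {h:.3f} A is non-physical")
    return theta, h, dphi


def _parity_offsets(n_pf: int, seam_index: int, register: int) -> np.ndarray:
    """Per-pf one-monomer shifts placing the A-lattice seam at seam_index.

    Junction k sits between pf k and pf (k+1) mod N.  Crossing the seam
    junction flips the shift by one monomer; the wrap-around junction is
    then automatically B-lattice for odd start numbers.
    """
    o = np.full(n_pf, register, dtype=int)
    if seam_index < n_pf - 1:
        o[seam_index + 1 :] = (register + 1) % 2
    return o


def _lateral_scale(spec: LatticeSpec, h: float) -> float:
    """Radial scale factor realising ``lateral_compression`` exactly.

    The ideal adjacent B-lattice dimer COM separation is
    sqrt(chord^2 + h^2) with chord = 2 r sin(pi/N); shrinking it by c
    requires chord' = sqrt((sep - c)^2 - h^2).
    """
    c = spec.lateral_compression
    if c == 0.0:
        return 1.0
    chord = 2.0 * spec.radius * math.sin(math.pi / spec.n_pf)
    sep = math.hypot(chord, h)
    target = sep - c
    if target <= abs(h):
        raise ValueError("lateral_compression too large for this geometry")
    return math.sqrt(target * target - h * h) / chord


def build_lattice(spec: LatticeSpec) -> Lattice:
    """Realise a LatticeSpec as pseudo-atom coordinates with ground truth.

    Monomer j of protofilament k sits at axial position
    z = (j + o_k) * a + k * h (o_k the seam/register parity shift) and
    azimuth phi = k*360/N + z*tan(theta)*(180/pi)/r; its body frame is
    the local cylindrical frame, tilted about the radial axis for
    mechanism="tilt" or azimuthally quantised per dimer for
    mechanism="stagger".  Deterministic for a fixed spec (incl. seed).
    """
    theta, h, dphi = accommodation_solve(spec)
    N, a, r = spec.n_pf, spec.monomer_repeat, spec.radius
    tan_theta = math.tan(math.radians(theta))
    scale = _lateral_scale(spec, h)
    offsets = spec.offsets
    radii = r * scale + offsets
    if np.any(radii <= 0):
        raise ValueError("per-protofilament radius would become non-positive")
    o = _parity_offsets(N, spec.seam_index, spec.register)

    rng = np.random.default_rng(spec.seed)
    monomers: list[MonomerSite] = []
    for k in range(N):
        for j in range(2 * spec.n_dimers):
            z = (j + o[k]) * a + k * h
            if spec.mechanism == "stagger":
                z_eval = (2 * (j // 2) + o[k]) * a + k * h
            else:
                z_eval = z
            phi = math.radians(k * 360.0 / N) + z_eval * tan_theta / r
            e_r = np.array([math.cos(phi), math.sin(phi), 0.0])
            e_t = np.array([-math.sin(phi), math.cos(phi), 0.0])
            e_z = np.array([0.0, 0.0, 1.0])
            frame = np.column_stack([e_r, e_t, e_z])
            if spec.mechanism == "tilt":
                # lean the body tangentially so its axis follows the
                # tilted protofilament path (e_z -> cos(th) e_z + sin(th) e_t)
                tilt = Rotation.from_rotvec(-math.radians(theta) * e_r).as_matrix()
                frame = tilt @ frame
            centre = radii[k] * e_r + z * e_z
            atoms = centre + MONOMER_TEMPLATE @ frame.T
            monomers.append(
                MonomerSite(
                    pf_index=k,
                    axial_index=j,
                    kind="alpha" if j % 2 == 0 else "beta",
                    dimer_index=j // 2,
                    position=atoms.mean(axis=0),
                    body_atoms=atoms,
                    orientation=frame,
                )
            )

    if spec.coord_noise_sd > 0:
        noise = rng.normal(0.0, spec.coord_noise_sd, size=(len(monomers), 5, 3))
        monomers = [
            replace(
                m,
                body_atoms=m.body_atoms + noise[i],
                position=(m.body_atoms + noise[i]).mean(axis=0),
            )
            for i, m in enumerate(monomers)
        ]

    truth = LatticeTruth(
        theta_deg=theta,
        rise=h,
        dphi_per_dimer=dphi,
        diameter=2.0 * float(np.mean(radii)),
        seam_index=spec.seam_index,
        register=spec.register,
        axis_point=np.zeros(3),
        axis_direction=np.array([0.0, 0.0, 1.0]),
    )
    return Lattice(spec, tuple(monomers), truth)


def spec_to_dict(spec: LatticeSpec) -> dict:
    """JSON-serialisable representation of a LatticeSpec."""
    d = dataclasses.asdict(spec)
    if d["pf_radial_offsets"] is not None:
        d["pf_radial_offsets"] = list(d["pf_radial_offsets"])
    return d


def spec_from_dict(d: dict) -> LatticeSpec:
    known = {f.name for f in dataclasses.fields(LatticeSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown LatticeSpec fields: {sorted(unknown)}")
    kwargs = dict(d)
    if kwargs.get("pf_radial_offsets") is not None:
        kwargs["pf_radial_offsets"] = tuple(kwargs["pf_radial_offsets"])
    return LatticeSpec(**kwargs)


def perturb_lattice(
    lat: Lattice,
    pf_radial_offsets: Sequence[float] | None = None,
    lateral_compression: float = 0.0,
    coord_noise_sd: float | None = None,
    seed: int | None = None,
) -> Lattice:
    """Return a new lattice with binding-site perturbations injected.

    Radial offsets add to any existing per-pf offsets; lateral
    compression adds to the spec value; noise sd / seed replace the spec
    values when given.  The input lattice is untouched and the truth
    record of the result reflects the perturbed geometry.
    """
    spec = lat.spec
    new_offsets = spec.offsets.copy()
    if pf_radial_offsets is not None:
        extra = np.asarray(pf_radial_offsets, dtype=float)
        if extra.shape != (spec.n_pf,):
            raise ValueError("pf_radial_offsets must have length n_pf")
        new_offsets = new_offsets + extra
    new_spec = replace(
        spec,
        pf_radial_offsets=tuple(new_offsets),
        lateral_compression=spec.lateral_compression + lateral_compression,
        coord_noise_sd=spec.coord_noise_sd if coord_noise_sd is None else coord_noise_sd,
        seed=spec.seed if seed is None else seed,
    )
    return build_lattice(new_spec)
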