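"""Seam-position / alpha-beta register hypotheses and CKK binding sites.

A pseudo-helical MT with N protofilaments admits 2N reference
hypotheses during alignment: N possible seam positions, each with two
alpha/beta registers (the register counterpart is translated one
monomer, a Angstrom, along the helical axis).  Hypothesis (k, rho) is
the pseudo-helical symmetry operator applied k times -- rotation by
k*360/N degrees about the axis plus axial rise k*h -- composed with an
optional one-monomer shift rho*a.

CKK domains decorate the wall at the intradimer interprotofilament
junctions every dimer repeat (~8 nm), at every lateral junction except
the seam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .lattice_synth import Lattice, LatticeSpec, accommodation_solve

__all__ = [
    "SeamHypothesis",
    "BindingSite",
    "enumerate_seam_hypotheses",
    "apply_hypothesis",
    "enumerate_binding_sites",
]


@dataclass(frozen=True)
class SeamHypothesis:
    """One of the 2N seam/register reference transforms."""

    seam_pos: int  # k in [0, N)
    register: int  # rho in {0, 1}
    rotation_deg: float  # k * 360/N about the helical axis
    rise: float  # k*h + rho*a along the axis, Angstrom

    def transform(self, axis_point: np.ndarray, axis_dir: np.ndarray):
        """Rigid transform (R, t) about the given helical axis."""
        axis_dir = np.asarray(axis_dir, dtype=float)
        axis_dir = axis_dir / np.linalg.norm(axis_dir)
        R = Rotation.from_rotvec(np.radians(self.rotation_deg) * axis_dir).as_matrix()
        p = np.asarray(axis_point, dtype=float)
        t = p - R @ p + self.rise * axis_dir
        return R, t


@dataclass(frozen=True)
class BindingSite:
    junction: int  # lateral junction index (pf k | pf k+1)
    ring: int  # axial dimer ring
    position: np.ndarray  # (3,) intradimer interprotofilament midpoint


def enumerate_seam_hypotheses(n_pf: int, spec: LatticeSpec) -> list[SeamHypothesis]:
    """All distinct (seam position, register) reference transforms.

    For generic lattice parameters this is exactly 2N (e.g. 26 for a
    13-protofilament MT).  Transforms are deduplicated on (rotation mod
    360 deg, rise mod dimer repeat) at 1e-6 tolerance -- two references
    differing by a whole dimer repeat act identically on the periodic
    wall; pathological parameter coincidences collapse with a warning.
    """
    if n_pf < 8:
        raise ValueError("n_pf must be at least 8")
    _, h, _ = accommodation_solve(spec)
    a = spec.monomer_repeat
    period = 2.0 * a
    hyps: list[SeamHypothesis] = []
    seen: list[tuple[float, float]] = []
    for k in range(n_pf):
        for rho in (0, 1):
            rot = (k * 360.0 / n_pf) % 360.0
            rise = k * h + rho * a
            key = (rot, rise % period)
            dup = any(
                min(abs(key[0] - s[0]), 360.0 - abs(key[0] - s[0])) < 1e-6
                and min(abs(key[1] - s[1]), period - abs(key[1] - s[1])) < 1e-6
                for s in seen
            )
            if dup:
                warnings.warn(
                    "degenerate lattice parameters: seam/register hypotheses "
                    f"coincide at (k={k}, register={rho})",
                    stacklevel=2,
                )
                continue
            seen.append(key)
            hyps.append(SeamHypothesis(k, rho, rot, rise))
    return hyps


def apply_hypothesis(lat: Lattice, hyp: SeamHypothesis) -> Lattice:
    """Rigidly transform a reference lattice to hypothesis (k, rho).

    The lattice is rotated/translated about its own helical axis.
    Protofilament labels are kept azimuth-ordered: rotating by k slots
    relabels pf j as (j + k) mod N, so the seam junction index in the
    truth record advances by k and stays consistent with the labels.
    """
    N = lat.n_pf
    k = hyp.seam_pos
    R, t = hyp.transform(lat.truth.axis_point, lat.truth.axis_direction)
    moved = lat.transformed(R, t)
    # reorder so monomer(pf, axial) indexing matches the new labels
    block = 2 * lat.spec.n_dimers
    monomers: list = []
    for new_pf in range(N):
        old_pf = (new_pf - k) % N
        for j in range(block):
            m = moved.monomers[old_pf * block + j]
            monomers.append(replace(m, pf_index=new_pf))
    truth = replace(
        moved.truth,
        seam_index=(lat.truth.seam_index + k) % N,
        register=(lat.truth.register + hyp.register) % 2,
        # the axis itself is invariant under a screw motion about it
        axis_point=lat.truth.axis_point,
        axis_direction=lat.truth.axis_direction,
    )
    return Lattice(moved.spec, tuple(monomers), truth)


def enumerate_binding_sites(lat: Lattice) -> list[BindingSite]:
    """CKK sites: one per non-seam lateral junction per dimer ring.

    Each site sits at the intradimer interprotofilament midpoint, the
    mean of the two adjacent dimers' centres of mass (between the alpha
    and beta monomers of laterally adjacent dimers).  Successive sites
    on a junction are one dimer repeat (~82 A = 8 nm) apart axially.
    """
    N = lat.n_pf
    seam = lat.truth.seam_index
    coms = lat.dimer_coms()
    axis_p, axis_d = lat.truth.axis_point, lat.truth.axis_direction
    z = (coms - axis_p) @ axis_d
    sites: list[BindingSite] = []
    for d in range(lat.n_dimers):
        for k in range(N):
            if k == seam:
                continue
            k2 = (k + 1) % N
            j = int(np.argmin(np.abs(z[k2] - z[k, d])))
            sites.append(
                BindingSite(junction=k, ring=d, position=(coms[k, d] + coms[k2, j]) / 2.0)
            )
    return sites
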