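"""Coordinate-model I/O, contact footprints and per-region RMSD.

Models (PDB or mmCIF, parsed with gemmi) are reduced to a light
chain/residue/atom container with a per-chain *role* annotation: "CKK"
for the bound domain, tubulin subunit labels ("alpha1", "beta1",
"alpha2", "beta2" for the dimer pair at a binding site) or "unknown".
Synthetic lattices are written with one chain per protofilament and
the 5 body pseudo-atoms as C-alpha-style records.

The binding footprint is a plain distance criterion -- every tubulin
residue with any atom within 5.0 A (inclusive) of any CKK atom --
reported as per-subunit residue lists and counts.  Counts are a proxy
for interface size, not buried surface areas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .decomposition import superpose_rigid
from .lattice_synth import Lattice

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "FootprintResult",
    "read_model",
    "model_from_lattice",
    "write_lattice_pdb",
    "write_lattice_cif",
    "contact_footprint",
    "region_rmsd",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
_BODY_ATOM_NAMES = ("CA", "C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Angstrom


@dataclass(frozen=True)
class Residue:
    seqid: int
    icode: str  # insertion code, "" if none
    name: str
    atoms: tuple[Atom, ...]


@dataclass(frozen=True)
class StructureModel:
    chains: dict[str, tuple[Residue, ...]]
    roles: dict[str, str] = field(default_factory=dict)

    def role(self, chain: str) -> str:
        return self.roles.get(chain, "unknown")

    def chain_coords(self, chain: str) -> np.ndarray:
        return np.array(
            [a.position for res in self.chains[chain] for a in res.atoms]
        )


@dataclass(frozen=True)
class FootprintResult:
    cutoff: float
    residues: dict[str, tuple[tuple[int, str], ...]]  # role -> ((seqid, resname), ...)
    counts: dict[str, int]  # role -> number of contacting residues


def _load_roles(roles) -> dict[str, str]:
    if roles is None:
        return {}
    if isinstance(roles, (str, Path)):
        with open(roles) as fh:
            return dict(json.load(fh))
    return dict(roles)


def read_model(path, roles=None) -> StructureModel:
    """Read a PDB/mmCIF coordinate file into a StructureModel.

    ``roles`` maps chain names to role annotations, either as a dict or
    the path of a JSON sidecar (deposited chain IDs are not portable
    across entries, so the mapping is supplied, not guessed).  Parse
    errors are reported with the offending location; insertion codes
    are preserved on the residue, never dropped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"no coordinate model found in {path}")
    st.setup_entities()
    chains: dict[str, tuple[Residue, ...]] = {}
    for chain in st[0]:
        residues = []
        for res in chain:
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in res
            )
            icode = res.seqid.icode.strip()
            residues.append(Residue(res.seqid.num, icode, res.name, atoms))
        chains[chain.name] = tuple(residues)
    return StructureModel(chains=chains, roles=_load_roles(roles))


def _chain_name(i: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return alphabet[i % 26]


def model_from_lattice(lat: Lattice) -> StructureModel:
    """One chain per protofilament; residues ALP/BET per monomer."""
    chains: dict[str, tuple[Residue, ...]] = {}
    block = 2 * lat.spec.n_dimers
    for k in range(lat.n_pf):
        residues = []
        for j in range(block):
            m = lat.monomer(k, j)
            atoms = tuple(
                Atom(name=_BODY_ATOM_NAMES[i], element="C", position=m.body_atoms[i].copy())
                for i in range(5)
            )
            residues.append(
                Residue(j + 1, "", "ALP" if m.kind == "alpha" else "BET", atoms)
            )
        chains[_chain_name(k)] = tuple(residues)
    return StructureModel(chains=chains, roles={})


def _lattice_to_gemmi(lat: Lattice) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic-mt-lattice"
    model = gemmi.Model("1")
    src = model_from_lattice(lat)
    for cname, residues in src.chains.items():
        chain = gemmi.Chain(cname)
        for res in residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.seqid, " ")
            for a in res.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = 1.0
                atom.b_iso = 0.0
                r.add_atom(atom)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_lattice_pdb(lat: Lattice, path) -> None:
    """Write a lattice as PDB (coordinates to format precision, 1e-3 A)."""
    _lattice_to_gemmi(lat).write_pdb(str(path))


def write_lattice_cif(lat: Lattice, path) -> None:
    """Write a lattice as mmCIF."""
    st = _lattice_to_gemmi(lat)
    st.make_mmcif_document().write_file(str(path))


def contact_footprint(model: StructureModel, cutoff: float = 5.0) -> FootprintResult:
    """Tubulin residues within ``cutoff`` of any CKK atom, per subunit.

    Requires role annotations with at least one "CKK" chain; every
    other annotated chain is reported under its role.  The distance
    test is any-atom against any-atom, inclusive at the cutoff.
    """
    ckk_chains = [c for c in model.chains if model.role(c) == "CKK"]
    if not ckk_chains:
        raise ValueError("no chain annotated with role 'CKK'")
    others = [c for c in model.chains if model.role(c) not in ("CKK", "unknown")]
    if not others:
        raise ValueError("no tubulin chains with role annotations")
    ckk_xyz = np.concatenate([model.chain_coords(c) for c in ckk_chains])
    residues: dict[str, list] = {}
    counts: dict[str, int] = {}
    if cutoff > 0:
        tree = cKDTree(ckk_xyz)
    for c in others:
        role = model.role(c)
        residues.setdefault(role, [])
        counts.setdefault(role, 0)
        for res in model.chains[c]:
            if cutoff <= 0:
                continue
            xyz = np.array([a.position for a in res.atoms])
            if np.any(tree.query(xyz, k=1)[0] <= cutoff):
                residues[role].append((res.seqid, res.name))
                counts[role] += 1
    return FootprintResult(
        cutoff=cutoff,
        residues={k: tuple(v) for k, v in residues.items()},
        counts=counts,
    )


def _parse_selection(model: StructureModel, sel: str) -> list[Residue]:
    """Residues for a "chain:first-last" (inclusive) selection string."""
    chain, _, rng = sel.partition(":")
    if chain not in model.chains:
        raise ValueError(f"chain {chain!r} not in model")
    residues = model.chains[chain]
    if not rng:
        return list(residues)
    lo_s, _, hi_s = rng.partition("-")
    lo, hi = int(lo_s), int(hi_s or lo_s)
    return [r for r in residues if lo <= r.seqid <= hi]


def _paired_backbone(res_a: Residue, res_b: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    a_atoms = {a.name: a.position for a in res_a.atoms}
    b_atoms = {a.name: a.position for a in res_b.atoms}
    names = [n for n in BACKBONE_ATOMS if n in a_atoms and n in b_atoms]
    if len(names) < 3:  # e.g. pseudo-atom models: use all shared atoms
        names = [n for n in a_atoms if n in b_atoms]
    return [(a_atoms[n], b_atoms[n]) for n in names]


def _selection_pairs(model_a, model_b, sel: str) -> tuple[np.ndarray, np.ndarray]:
    res_a = _parse_selection(model_a, sel)
    res_b = _parse_selection(model_b, sel)
    if len(res_a) != len(res_b):
        raise ValueError(f"selection {sel!r} has unequal residue counts")
    pa, pb = [], []
    for ra, rb in zip(res_a, res_b):
        for xa, xb in _paired_backbone(ra, rb):
            pa.append(xa)
            pb.append(xb)
    if not pa:
        raise ValueError(f"selection {sel!r} yields no corresponded atoms")
    return np.array(pa), np.array(pb)


def region_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    core_selection: str,
    region_selections: dict[str, str],
) -> dict[str, float]:
    """Backbone RMSD per region after superposition on a core selection.

    Residues are corresponded positionally within each selection; the
    RMSD is over backbone atoms (N, CA, C, O) present in both models.
    """
    core_a, core_b = _selection_pairs(model_a, model_b, core_selection)
    R, t, _ = superpose_rigid(core_b, core_a)
    out: dict[str, float] = {}
    for name, sel in region_selections.items():
        pa, pb = _selection_pairs(model_a, model_b, sel)
        pb = pb @ R.T + t
        out[name] = float(np.sqrt(np.mean(np.sum((pb - pa) ** 2, axis=1))))
    return out
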