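"""Model I/O round trips, contact footprint, region RMSD."""

import numpy as np
import pytest

from mtlattice import build_lattice
from mtlattice.lattice_synth import MONOMER_TEMPLATE, LatticeSpec
from mtlattice.structure_io import (
    Atom,
    Residue,
    StructureModel,
    contact_footprint,
    model_from_lattice,
    read_model,
    region_rmsd,
    write_lattice_cif,
    write_lattice_pdb,
)


@pytest.fixture(scope="module")
def small_lattice():
    return build_lattice(LatticeSpec(n_pf=13, n_dimers=3))


def _all_coords(model):
    return np.concatenate([model.chain_coords(c) for c in sorted(model.chains)])


class TestRoundTrip:
    def test_pdb_round_trip(self, small_lattice, tmp_path):
        path = tmp_path / "lat.pdb"
        write_lattice_pdb(small_lattice, path)
        model = read_model(path)
        assert len(model.chains) == 13
        orig = small_lattice.atom_coords().reshape(-1, 3)
        assert np.abs(_all_coords(model) - orig).max() < 1e-3

    def test_pdb_and_cif_agree(self, small_lattice, tmp_path):
        p_pdb, p_cif = tmp_path / "lat.pdb", tmp_path / "lat.cif"
        write_lattice_pdb(small_lattice, p_pdb)
        write_lattice_cif(small_lattice, p_cif)
        m1, m2 = read_model(p_pdb), read_model(p_cif)
        assert sorted(m1.chains) == sorted(m2.chains)
        for c in m1.chains:
            assert [r.name for r in m1.chains[c]] == [r.name for r in m2.chains[c]]
            assert [r.seqid for r in m1.chains[c]] == [r.seqid for r in m2.chains[c]]
        assert np.abs(_all_coords(m1) - _all_coords(m2)).max() < 1e-3

    def test_insertion_codes_preserved(self, tmp_path):
        pdb = tmp_path / "ins.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A  10      1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A  10A     2.000   3.000   4.000  1.00  0.00           C\n"
            "END\n"
        )
        model = read_model(pdb)
        residues = model.chains["A"]
        assert [(r.seqid, r.icode) for r in residues] == [(10, ""), (10, "A")]

    def test_malformed_file_reported(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nloop_\n_atom_site.oops\nnonsense")
        with pytest.raises(ValueError):
            read_model(bad)


def _junction_model(lat):
    """4 tubulin monomers around a junction plus a synthetic CKK wedge.

    The CKK body is synthetic: a star of pseudo-atoms reaching from the
    junction midpoint toward each adjacent monomer, as a stand-in for a
    real bound domain.
    """
    labels = [("alpha1", (0, 2)), ("beta1", (0, 3)), ("alpha2", (1, 2)), ("beta2", (1, 3))]
    chains, roles = {}, {}
    centres = []
    for i, (role, (pf, j)) in enumerate(labels):
        c = lat.monomer(pf, j).position
        centres.append(c)
        atoms = tuple(Atom("CA", "C", c + 0.2 * t) for t in MONOMER_TEMPLATE)
        chains[chr(ord("a") + i)] = (Residue(1, "", "TUB", atoms),)
        roles[chr(ord("a") + i)] = role
    # a distant subunit that must stay outside the footprint
    far = lat.monomer(6, 2).position
    chains["x"] = (Residue(1, "", "TUB", (Atom("CA", "C", far),)),)
    roles["x"] = "alpha_far"
    mid = np.mean(centres, axis=0)
    ckk = tuple(
        Atom(f"C{i+1}", "C", mid + f * (c - mid))
        for i, c in enumerate(centres)
        for f in (0.5, 0.85)
    )
    chains["Z"] = (Residue(1, "", "CKK", ckk),)
    roles["Z"] = "CKK"
    return StructureModel(chains=chains, roles=roles)


class TestFootprint:
    def test_cutoff_contract(self):
        chains = {
            "A": (Residue(1, "", "CKK", (Atom("C1", "C", np.zeros(3)),)),),
            "B": (Residue(1, "", "TUB", (Atom("CA", "C", np.array([4.9, 0, 0])),)),),
            "C": (Residue(1, "", "TUB", (Atom("CA", "C", np.array([5.1, 0, 0])),)),),
        }
        roles = {"A": "CKK", "B": "beta1", "C": "beta2"}
        fp = contact_footprint(StructureModel(chains, roles), cutoff=5.0)
        assert fp.counts == {"beta1": 1, "beta2": 0}

    def test_wedge_spans_four_subunits(self, small_lattice):
        model = _junction_model(small_lattice)
        fp = contact_footprint(model, cutoff=9.0)
        contacted = {role for role, n in fp.counts.items() if n > 0}
        assert contacted == {"alpha1", "beta1", "alpha2", "beta2"}

    def test_zero_cutoff_empty(self, small_lattice):
        fp = contact_footprint(_junction_model(small_lattice), cutoff=0.0)
        assert all(n == 0 for n in fp.counts.values())

    def test_missing_roles_rejected(self, small_lattice):
        model = model_from_lattice(small_lattice)
        with pytest.raises(ValueError):
            contact_footprint(model)

    def test_rigid_motion_invariance(self, small_lattice, rng):
        from conftest import random_rotation

        model = _junction_model(small_lattice)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        moved = StructureModel(
            chains={
                c: tuple(
                    Residue(r.seqid, r.icode, r.name,
                            tuple(Atom(a.name, a.element, R @ a.position + t) for a in r.atoms))
                    for r in residues
                )
                for c, residues in model.chains.items()
            },
            roles=model.roles,
        )
        assert contact_footprint(moved, 9.0).counts == contact_footprint(model, 9.0).counts


class TestRegionRMSD:
    def test_self_comparison_zero(self, small_lattice):
        m = model_from_lattice(small_lattice)
        out = region_rmsd(m, m, "A", {"r1": "B:1-4", "r2": "C:2-5"})
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in out.values())

    def test_displaced_region_read_back(self, small_lattice, rng):
        m = model_from_lattice(small_lattice)
        shift = np.array([3.0, 0.0, 0.0])
        chains = dict(m.chains)
        moved_b = tuple(
            Residue(r.seqid, r.icode, r.name,
                    tuple(Atom(a.name, a.element,
                               a.position + (shift if 2 <= r.seqid <= 4 else 0))
                          for a in r.atoms))
            for r in m.chains["B"]
        )
        chains["B"] = moved_b
        m2 = StructureModel(chains=chains, roles=m.roles)
        out = region_rmsd(m, m2, "A", {"moved": "B:2-4", "still": "B:5-6", "other": "C:1-6"})
        assert out["moved"] == pytest.approx(3.0, abs=1e-9)
        assert out["still"] == pytest.approx(0.0, abs=1e-9)
        assert out["other"] == pytest.approx(0.0, abs=1e-9)

    def test_triangle_inequality_on_perturbed_copies(self, small_lattice, rng):
        m = model_from_lattice(small_lattice)

        def jitter(model, sd, seed):
            r = np.random.default_rng(seed)
            return StructureModel(
                chains={
                    c: tuple(
                        Residue(res.seqid, res.icode, res.name,
                                tuple(Atom(a.name, a.element,
                                           a.position + r.normal(0, sd, 3)) for a in res.atoms))
                        for res in residues
                    )
                    for c, residues in model.chains.items()
                },
                roles=model.roles,
            )

        a, b, c = jitter(m, 0.3, 1), jitter(m, 0.3, 2), jitter(m, 0.3, 3)
        sel = {"r": "B:1-6"}
        ab = region_rmsd(a, b, "A", sel)["r"]
        bc = region_rmsd(b, c, "A", sel)["r"]
        ac = region_rmsd(a, c, "A", sel)["r"]
        assert ac <= ab + bc + 1e-9

    def test_empty_selection_rejected(self, small_lattice):
        m = model_from_lattice(small_lattice)
        with pytest.raises(ValueError):
            region_rmsd(m, m, "A:100-200", {"r": "B:1-2"})
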