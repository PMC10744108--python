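"""PAE scoring, pLDDT extraction and VDW contact detection."""

import json

import gemmi
import numpy as np
import pytest

from fretab import structconf as sc
from fretab.structconf import (
    AtomSet,
    PaeMatrix,
    ResidueInterval,
    find_contacts,
    interface_residues,
    pae_region_mean,
    plddt_track,
    read_pae,
)

TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 90.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 70.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.040  1.00 60.00           C
ATOM      4  N   GLY A   2      10.877   5.446  -4.212  1.00 90.00           N
ATOM      5  CA  GLY A   2      11.280   5.291  -2.822  1.00 90.00           C
ATOM      6  N   SER B   1      11.639   6.071  -0.500  1.00 40.00           N
ATOM      7  CA  SER B   1      12.000   6.000   0.800  1.00 42.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def _atomset(xyz, elements=None, chains=None, res_nums=None):
    n = len(xyz)
    return AtomSet(
        elements=np.asarray(elements or ["C"] * n, dtype=object),
        xyz=np.asarray(xyz, dtype=float),
        chains=np.asarray(chains or ["A"] * n, dtype=object),
        res_nums=np.asarray(res_nums or list(range(1, n + 1)), dtype=int),
        atom_names=np.asarray([f"C{i}" for i in range(n)], dtype=object),
    )


class TestReadPae:
    def test_flat_list_dialect(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({"pae": list(range(16))}))
        pae = read_pae(path)
        assert pae.values.shape == (4, 4)
        assert pae.values[1, 2] == 6

    def test_nested_and_triplet_dialects_agree(self, tmp_path, rng):
        mat = rng.uniform(0, 30, (4, 4)).round(2)
        nested = tmp_path / "nested.json"
        nested.write_text(json.dumps([{"predicted_aligned_error": mat.tolist()}]))
        r1, r2 = np.indices(mat.shape)
        flat = tmp_path / "flat.json"
        flat.write_text(
            json.dumps(
                {
                    "residue1": (r1.ravel() + 1).tolist(),
                    "residue2": (r2.ravel() + 1).tolist(),
                    "distance": mat.ravel().tolist(),
                }
            )
        )
        assert np.array_equal(read_pae(nested).values, read_pae(flat).values)

    def test_non_square_matrix_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"pae": [[1, 2, 3, 4, 5]] * 4}))
        with pytest.raises(ValueError, match="square"):
            read_pae(path)

    def test_chain_ranges_from_model(self, tmp_path, toy_pdb):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({"pae": np.zeros((3, 3)).tolist()}))
        pae = read_pae(path, model=toy_pdb)
        assert pae.chain_ranges == {"A": (1, 2), "B": (3, 3)}

    def test_chain_ranges_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            PaeMatrix(np.zeros((4, 4)), {"A": (1, 2)})


class TestPaeRegionMean:
    def test_constant_matrix(self):
        pae = PaeMatrix(np.full((6, 6), 4.2), {"A": (1, 3), "B": (4, 6)})
        assert pae_region_mean(pae, ResidueInterval("A", 1, 2), ResidueInterval("B", 2, 3)) == 4.2

    def test_hand_block_mean(self):
        values = np.zeros((4, 4))
        values[0:2, 2:4] = [[10, 12], [8, 10]]
        pae = PaeMatrix(values, {"A": (1, 2), "B": (3, 4)})
        assert pae_region_mean(pae, ResidueInterval("A", 1, 2), ResidueInterval("B", 1, 2)) == 10.0

    def test_symmetric_mode_averages_both_rectangles(self):
        values = np.zeros((4, 4))
        values[0:2, 2:4] = [[10, 12], [8, 10]]
        values[2:4, 0:2] = [[6, 6], [6, 6]]
        pae = PaeMatrix(values, {"A": (1, 2), "B": (3, 4)})
        a, b = ResidueInterval("A", 1, 2), ResidueInterval("B", 1, 2)
        assert pae_region_mean(pae, a, b, symmetric=True) == 8.0

    def test_full_matrix_region_equals_global_mean(self, rng):
        values = rng.uniform(0, 35, (10, 10))
        pae = PaeMatrix(values, {"A": (1, 10)})
        full = ResidueInterval("A", 1, 10)
        assert pae_region_mean(pae, full, full) == pytest.approx(values.mean())

    def test_matches_brute_force_on_random_blocks(self, rng):
        values = rng.uniform(0, 35, (12, 12))
        pae = PaeMatrix(values, {"A": (1, 5), "B": (6, 12)})
        for _ in range(50):
            a0, a1 = sorted(rng.integers(1, 6, 2))
            b0, b1 = sorted(rng.integers(1, 8, 2))
            got = pae_region_mean(
                pae, ResidueInterval("A", a0, a1), ResidueInterval("B", b0, b1)
            )
            acc = []
            for i in range(a0, a1 + 1):
                for j in range(b0, b1 + 1):
                    acc.append(values[i - 1, 5 + j - 1])
            assert got == pytest.approx(sum(acc) / len(acc))

    def test_union_mean_lies_between_block_means(self, rng):
        values = rng.uniform(0, 35, (12, 12))
        pae = PaeMatrix(values, {"A": (1, 12)})
        b = ResidueInterval("A", 1, 12)
        m1 = pae_region_mean(pae, ResidueInterval("A", 1, 4), b)
        m2 = pae_region_mean(pae, ResidueInterval("A", 5, 12), b)
        mu = pae_region_mean(pae, ResidueInterval("A", 1, 12), b)
        assert min(m1, m2) <= mu <= max(m1, m2)

    def test_out_of_range_interval_rejected(self):
        pae = PaeMatrix(np.zeros((4, 4)), {"A": (1, 4)})
        with pytest.raises(ValueError, match="exceeds"):
            pae_region_mean(pae, ResidueInterval("A", 1, 5), ResidueInterval("A", 1, 2))


class TestPlddt:
    def test_ca_convention_per_residue(self, toy_pdb):
        tracks = plddt_track(toy_pdb)
        # residue A1 has CA at 70 despite sidechain at 60; A2 uniform 90
        assert tracks["A"].tolist() == [70.0, 90.0]
        assert tracks["B"].tolist() == [42.0]

    def test_mmcif_and_pdb_agree(self, toy_pdb, tmp_path):
        st = gemmi.read_structure(str(toy_pdb))
        st.setup_entities()
        cif_path = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        t1, t2 = plddt_track(toy_pdb), plddt_track(cif_path)
        assert set(t1) == set(t2)
        for chain in t1:
            assert np.allclose(t1[chain], t2[chain])

    def test_empty_model_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            plddt_track(path)


class TestContacts:
    def test_far_apart_carbons_no_contact(self):
        atoms = _atomset([[0, 0, 0], [10, 0, 0]])
        assert find_contacts(atoms) == []

    def test_overlap_arithmetic(self):
        atoms = _atomset([[0, 0, 0], [3.0, 0, 0]])
        (c,) = find_contacts(atoms)
        assert c.distance == pytest.approx(3.0)
        assert c.overlap == pytest.approx(1.7 + 1.7 - 3.0)

    def test_boundary_pair_retained_inclusively(self):
        atoms = _atomset([[0, 0, 0], [3.8, 0, 0]])
        (c,) = find_contacts(atoms, overlap_cutoff=-0.4)
        assert c.overlap == pytest.approx(-0.4)
        assert find_contacts(atoms, overlap_cutoff=-0.3) == []

    def test_same_residue_pairs_excluded(self):
        atoms = _atomset([[0, 0, 0], [3.0, 0, 0]], res_nums=[1, 1])
        assert find_contacts(atoms) == []

    def test_bonded_pairs_excluded(self):
        atoms = _atomset([[0, 0, 0], [1.5, 0, 0]])
        assert find_contacts(atoms) == []

    def test_unknown_element_errors(self):
        atoms = _atomset([[0, 0, 0], [3, 0, 0]], elements=["C", "XX"])
        with pytest.raises(KeyError, match="XX"):
            find_contacts(atoms)

    def test_matches_all_pairs_oracle_on_random_sets(self, rng):
        elements = np.array(["C", "N", "O", "S"], dtype=object)
        for trial in range(10):
            n = 300
            xyz = rng.uniform(0, 25, (n, 3))
            atoms = _atomset(
                xyz,
                elements=list(rng.choice(elements, n)),
                chains=list(rng.choice(["A", "B"], n)),
                res_nums=list(rng.integers(1, 60, n)),
            )
            got = {(c.i, c.j) for c in find_contacts(atoms)}

            # independent all-pairs oracle
            r = np.array([sc.VDW_RADII[e] for e in atoms.elements])
            diff = xyz[:, None, :] - xyz[None, :, :]
            d = np.sqrt((diff**2).sum(axis=2))
            overlap = r[:, None] + r[None, :] - d
            same_res = (atoms.res_nums[:, None] == atoms.res_nums[None, :]) & (
                atoms.chains[:, None] == atoms.chains[None, :]
            )
            bonded = d < sc.BOND_DISTANCE
            keep = (overlap >= -0.4 - 1e-9) & ~same_res & ~bonded
            expected = {
                (min(i, j), max(i, j))
                for i, j in zip(*np.where(np.triu(keep, k=1)))
            }
            assert got == expected


class TestInterfaceResidues:
    def test_no_interchain_contacts(self):
        atoms = _atomset([[0, 0, 0], [3.0, 0, 0]], chains=["A", "A"])
        summary = interface_residues(find_contacts(atoms), "A", "B")
        assert summary["A"]["residues"] == [] and summary["B"]["interval"] is None

    def test_covering_interval_and_residue_list(self):
        contacts = []
        for res_a in (140, 141, 165):
            atoms = _atomset(
                [[0, 0, 0], [3.0, 0, 0]], chains=["A", "B"], res_nums=[res_a, 7]
            )
            contacts.extend(find_contacts(atoms))
        summary = interface_residues(contacts, "A", "B")
        assert summary["A"]["residues"] == [140, 141, 165]
        assert summary["A"]["interval"] == (140, 165)
        assert summary["B"]["residues"] == [7]

    def test_intra_chain_contacts_ignored(self, toy_pdb):
        atoms = AtomSet.from_file(toy_pdb)
        contacts = find_contacts(atoms)
        summary = interface_residues(
            [c for c in contacts if c.chain_i == c.chain_j], "A", "B"
        )
        assert summary["A"]["residues"] == []
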