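"""Backbone H-bond detection, wrapping counts and per-gene nu."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import brute_force_zeta, transform_structure
from subwrap import simulate, structure
from subwrap.errors import (
    DataError,
    FormatError,
    StructureError,
    UndefinedStatisticError,
)


def _helix_lines(n_res, residue_type="ALA", seed=0, **kw):
    return simulate.gen_helix_fixture(max(n_res, 6), residue_type, seed, **kw)


class TestParseStructure:
    def test_poly_alanine_five_residues(self):
        # keep only the first 5 residues of a 6-residue helix
        text = "\n".join(
            line
            for line in _helix_lines(6).splitlines()
            if not (line.startswith("ATOM") and int(line[22:26]) == 6)
        )
        s = structure.parse_structure(text)
        residues = list(s.iter_residues())
        assert len(residues) == 5
        assert sum("CA" in r.atoms for r in residues) == 5

    def test_empty_input_is_format_error(self):
        with pytest.raises(FormatError):
            structure.parse_structure("")

    def test_hetatm_only_is_structure_error(self):
        text = (
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(StructureError):
            structure.parse_structure(text)

    def test_altloc_keeps_highest_occupancy(self):
        def atom(serial, name, altloc, x, occ, resseq=1):
            field = f" {name:<3s}"
            return (
                f"ATOM  {serial:5d} {field}{altloc}ALA A{resseq:4d} "
                f"   {x:8.3f}{0.0:8.3f}{0.0:8.3f}{occ:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}"
            )

        lines = [
            atom(1, "N", " ", 0.0, 1.0),
            atom(2, "CA", " ", 1.5, 1.0),
            atom(3, "C", " ", 2.5, 1.0),
            atom(4, "O", " ", 3.5, 1.0),
            atom(5, "CB", "A", 9.0, 0.6),
            atom(6, "CB", "B", -9.0, 0.4),
            "END",
        ]
        s = structure.parse_structure("\n".join(lines))
        res = next(s.iter_residues())
        assert res.atoms["CB"].coords[0] == pytest.approx(9.0)

    def test_hydrogens_ignored(self):
        text = _helix_lines(6) + (
            "ATOM   9999  H   ALA A   1       0.000   0.000   0.000  1.00  0.00           H\n"
        )
        s = structure.parse_structure(text)
        assert all("H" not in r.atoms for r in s.iter_residues())


class TestDetectBackboneHbonds:
    def test_ideal_helix_has_i_to_i_minus_4_bonds(self, ala_helix):
        bonds = structure.detect_backbone_hbonds(ala_helix)
        pairs = {(b.donor[1], b.acceptor[1]) for b in bonds}
        assert pairs == {(str(i), str(i - 4)) for i in range(5, 13)}
        assert len(bonds) == 8

    def test_matches_exhaustive_scan_oracle(self, ala_helix):
        # independent oracle: exhaustive N-O distance/angle scan with the
        # same geometric criterion, shortest-distance winner per donor
        complete = [r for r in ala_helix.iter_residues() if r.is_complete]
        expected = set()
        for donor in complete:
            candidates = []
            for acceptor in complete:
                if abs(acceptor.seqpos - donor.seqpos) < 2:
                    continue
                n = np.array(donor.atoms["N"].coords)
                o = np.array(acceptor.atoms["O"].coords)
                c = np.array(acceptor.atoms["C"].coords)
                d = np.linalg.norm(n - o)
                cosang = (c - o) @ (n - o) / (np.linalg.norm(c - o) * np.linalg.norm(n - o))
                if d <= 3.5 and np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 120.0:
                    candidates.append((d, acceptor.index))
            if candidates:
                expected.add((donor.index, min(candidates)[1]))
        got = {
            (b.donor[1], b.acceptor[1])
            for b in structure.detect_backbone_hbonds(ala_helix)
        }
        assert got == expected

    def test_extended_chain_has_no_bonds(self):
        # beta-strand-like fully extended backbone: phi = psi = 180
        from subwrap.simulate import _place_atom

        residues = []
        n = np.zeros(3)
        ca = np.array([1.458, 0.0, 0.0])
        theta = np.radians(111.2)
        c = ca + 1.525 * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
        backbone = [{"N": n, "CA": ca, "C": c}]
        for _ in range(11):
            p = backbone[-1]
            n = _place_atom(p["N"], p["CA"], p["C"], 1.329, 116.2, 180.0)
            ca = _place_atom(p["CA"], p["C"], n, 1.458, 121.7, 180.0)
            c = _place_atom(p["C"], n, ca, 1.525, 111.2, 180.0)
            backbone.append({"N": n, "CA": ca, "C": c})
        for r in backbone:
            r["O"] = _place_atom(r["N"], r["CA"], r["C"], 1.231, 120.8, 0.0)
        chains = {"A": []}
        for i, r in enumerate(backbone):
            res = structure.Residue(chain_id="A", index=str(i + 1), seqpos=i + 1, name="GLY")
            for serial, (name, xyz) in enumerate(r.items()):
                res.atoms[name] = structure.AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_index=i + 1,
                    residue_name="GLY",
                    chain_id="A",
                    coords=tuple(map(float, xyz)),
                )
            chains["A"].append(res)
        s = structure.ProteinStructure("extended", chains)
        assert structure.detect_backbone_hbonds(s) == []

    def test_two_distant_copies_duplicate_bonds_per_chain(self, ala_helix):
        shifted = transform_structure(ala_helix, translation=[50.0, 0.0, 0.0])
        chains = dict(ala_helix.chains)
        renamed = []
        for res in shifted.chains["A"]:
            res.chain_id = "B"
            for name, atom in list(res.atoms.items()):
                res.atoms[name] = structure.AtomRecord(
                    serial=atom.serial, name=atom.name, element=atom.element,
                    residue_index=atom.residue_index, residue_name=atom.residue_name,
                    chain_id="B", coords=atom.coords,
                )
            renamed.append(res)
        chains["B"] = renamed
        both = structure.ProteinStructure("dimer", chains)
        bonds = structure.detect_backbone_hbonds(both)
        by_chain = {}
        for b in bonds:
            by_chain.setdefault(b.donor[0], set()).add((b.donor[1], b.acceptor[1]))
        assert by_chain["A"] == by_chain["B"]
        assert len(bonds) == 16

    def test_too_few_residues_returns_empty(self):
        text = "\n".join(
            line
            for line in _helix_lines(6).splitlines()
            if not (line.startswith("ATOM") and int(line[22:26]) > 3)
        )
        s = structure.parse_structure(text)
        assert structure.detect_backbone_hbonds(s) == []


class TestComputeWrapping:
    def test_poly_glycine_zeta_zero(self):
        s = structure.parse_structure(_helix_lines(12, "GLY"))
        for bond in structure.detect_backbone_hbonds(s):
            assert structure.compute_wrapping(s, bond) == 0

    def test_poly_leucine_matches_brute_force(self, leu_helix):
        bonds = structure.detect_backbone_hbonds(leu_helix)
        central = bonds[len(bonds) // 2]
        assert structure.compute_wrapping(leu_helix, central) == brute_force_zeta(
            leu_helix, central
        )

    def test_radius_zero_gives_zero(self, leu_helix):
        bond = structure.detect_backbone_hbonds(leu_helix)[0]
        assert structure.compute_wrapping(leu_helix, bond, radius=0.0) == 0

    def test_zeta_monotone_in_radius(self, leu_helix):
        bond = structure.detect_backbone_hbonds(leu_helix)[3]
        zetas = [
            structure.compute_wrapping(leu_helix, bond, radius=r)
            for r in (0.0, 2.0, 4.0, 6.0, 8.0, 12.0)
        ]
        assert zetas == sorted(zetas)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixture_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rtype = ["GLY", "ALA", "LEU"][seed % 3]
        n = int(rng.integers(8, 20))
        s = structure.parse_structure(
            simulate.gen_helix_fixture(n, rtype, seed=seed, jitter_sd=0.08)
        )
        for bond in structure.detect_backbone_hbonds(s):
            assert structure.compute_wrapping(s, bond) == brute_force_zeta(s, bond)

    def test_rigid_motion_leaves_bonds_and_zeta_unchanged(self, leu_helix):
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = transform_structure(leu_helix, rotation=rot, translation=[5.0, -3.0, 12.0])
        ref = structure.annotate_structure(leu_helix)
        got = structure.annotate_structure(moved)
        assert [(b.donor, b.acceptor, b.zeta) for b in ref] == [
            (b.donor, b.acceptor, b.zeta) for b in got
        ]

    def test_missing_ca_is_data_error(self, ala_helix):
        bond = structure.detect_backbone_hbonds(ala_helix)[0]
        stripped = transform_structure(ala_helix)
        del stripped.residue(*bond.donor).atoms["CA"]
        with pytest.raises(DataError):
            structure.compute_wrapping(stripped, bond)


class TestClassifyAndNu:
    @pytest.mark.parametrize(
        "zeta,expected", [(19, True), (20, False), (0, True), (7, True)]
    )
    def test_dehydron_threshold(self, zeta, expected):
        assert structure.classify_dehydron(zeta) is expected

    def test_negative_zeta_rejected(self):
        with pytest.raises(DataError):
            structure.classify_dehydron(-1)

    @pytest.mark.parametrize(
        "profiles,expected",
        [([(3, 10)], 0.3), ([(2, 8), (1, 12)], 0.15), ([(0, 5)], 0.0)],
    )
    def test_gene_nu_pooled(self, profiles, expected):
        assert structure.compute_gene_nu("g", profiles).nu == pytest.approx(expected)

    def test_zero_bhbs_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            structure.compute_gene_nu("g", [(0, 0)])

    def test_more_dehydrons_than_bonds_rejected(self):
        with pytest.raises(DataError):
            structure.compute_gene_nu("g", [(5, 3)])

    def test_threshold_monotonicity_on_helix(self, leu_helix):
        bonds = structure.annotate_structure(leu_helix)
        nus = []
        for thr in (0, 10, 19, 25, 40):
            nd = sum(structure.classify_dehydron(b.zeta, thr) for b in bonds)
            nus.append(nd / len(bonds))
        assert nus == sorted(nus)
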