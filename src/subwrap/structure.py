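"""Backbone hydrogen-bond detection, wrapping (zeta) and per-gene under-wrapping (nu).

A backbone hydrogen bond (BHB) pairs the amide N of one residue with the
carbonyl O of another.  Its *wrapping* zeta counts the nonpolar side-chain
carbons inside the desolvation domain: the union of two spheres of fixed
radius centred at the two alpha-carbons.  Bonds with zeta at or below the
dehydron threshold are *dehydrons* — under-wrapped bonds poorly shielded
from water.  The per-gene under-wrapping ratio is

    nu = (# dehydrons) / (# BHBs),

with counts pooled over every solved product of the gene.  nu is the
structural proxy for dosage sensitivity used throughout the pipeline.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import DataError, FormatError, StructureError, UndefinedStatisticError

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: The 20 standard amino acids, three-letter codes.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Side-chain carbons with no covalent bond to N, O or S in the standard
#: residue topology.  These are the "nonpolar groups" counted by zeta.
#: Carbons bonded to a heteroatom (Ser CB-OG, carboxylate/amide/guanidinium
#: carbons, ring carbons flanking ring nitrogens, ...) are excluded.
NONPOLAR_SIDECHAIN_CARBONS: dict[str, frozenset[str]] = {
    "GLY": frozenset(),
    "ALA": frozenset({"CB"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "PRO": frozenset({"CB", "CG"}),  # CD bonded to backbone N
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ3", "CH2", "CZ2"}),
    "MET": frozenset({"CB"}),  # CG and CE bonded to SD
    "SER": frozenset(),  # CB bonded to OG
    "THR": frozenset({"CG2"}),  # CB bonded to OG1
    "CYS": frozenset(),  # CB bonded to SG
    "ASN": frozenset({"CB"}),  # CG is the amide carbon
    "GLN": frozenset({"CB", "CG"}),
    "ASP": frozenset({"CB"}),  # CG is the carboxylate carbon
    "GLU": frozenset({"CB", "CG"}),
    "LYS": frozenset({"CB", "CG", "CD"}),  # CE bonded to NZ
    "ARG": frozenset({"CB", "CG"}),  # CD bonded to NE; CZ guanidinium
    "HIS": frozenset({"CB"}),  # ring carbons flank ND1/NE2
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),  # CZ bonded to OH
}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: tuple[float, float, float]


@dataclass
class Residue:
    """One amino-acid residue; ``index`` keeps the file's 1-based numbering
    with any insertion code appended (e.g. ``"52A"``)."""

    chain_id: str
    index: str
    seqpos: int  # numeric part of index, for sequence-separation tests
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def is_complete(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def coord(self, atom_name: str) -> np.ndarray:
        try:
            return np.asarray(self.atoms[atom_name].coords, dtype=float)
        except KeyError:
            raise DataError(
                f"residue {self.chain_id}:{self.index} ({self.name}) lacks atom {atom_name}"
            ) from None


@dataclass
class ProteinStructure:
    structure_id: str
    chains: dict[str, list[Residue]]

    def iter_residues(self) -> Iterable[Residue]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain_id: str, index: str) -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.index == index:
                return res
        raise DataError(f"no residue {chain_id}:{index} in {self.structure_id}")


@dataclass
class BackboneHBond:
    donor: tuple[str, str]  # (chain_id, residue index key)
    acceptor: tuple[str, str]
    n_o_distance: float
    zeta: int | None = None


@dataclass(frozen=True)
class GeneWrapping:
    gene_id: str
    n_dehydrons: int
    n_bhbs: int

    @property
    def nu(self) -> float:
        if self.n_bhbs == 0:
            raise UndefinedStatisticError(
                f"gene {self.gene_id}: nu undefined with zero backbone hydrogen bonds"
            )
        return self.n_dehydrons / self.n_bhbs


def parse_structure(pdb_text: str, structure_id: str = "structure") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only ATOM records of the 20 standard amino acids are retained; hydrogens
    and HETATM records are ignored.  For alternate locations the
    highest-occupancy conformer is kept (ties: the first one encountered).
    Residues missing any backbone atom are kept (their side chains still
    wrap neighbouring bonds) but flagged incomplete and skipped during bond
    detection.
    """
    if not pdb_text or not pdb_text.strip():
        raise FormatError("empty PDB input")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio_structure = parser.get_structure(structure_id, _io.StringIO(pdb_text))
        except Exception as exc:  # Bio.PDB raises assorted exception types
            raise FormatError(f"unparseable PDB input: {exc}") from exc

    try:
        model = next(bio_structure.get_models())
    except StopIteration:
        raise FormatError("PDB input contains no model") from None

    chains: dict[str, list[Residue]] = {}
    serial = 0
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            resname = bio_res.get_resname().strip()
            if resname not in STANDARD_RESIDUES:
                continue
            index = f"{resseq}{icode.strip()}"
            res = Residue(
                chain_id=bio_chain.id, index=index, seqpos=resseq, name=resname
            )
            for atom in bio_res:  # DisorderedAtom yields its selected altloc
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                serial += 1
                name = atom.get_name().strip()
                res.atoms[name] = AtomRecord(
                    serial=serial,
                    name=name,
                    element=element or name[0],
                    residue_index=resseq,
                    residue_name=resname,
                    chain_id=bio_chain.id,
                    coords=tuple(float(x) for x in atom.get_coord()),
                )
            if res.atoms:
                residues.append(res)
        if residues:
            chains[bio_chain.id] = residues

    if not chains:
        raise StructureError(f"{structure_id}: no standard amino-acid content")
    for chain_id, residues in chains.items():
        if not any(r.is_complete for r in residues):
            raise StructureError(
                f"{structure_id}: chain {chain_id} has zero complete residues"
            )
    return ProteinStructure(structure_id=structure_id, chains=chains)


def detect_backbone_hbonds(
    structure: ProteinStructure,
    max_distance: float = 3.5,
    min_separation: int = 2,
    min_angle_deg: float = 120.0,
    include_interchain: bool = False,
) -> list[BackboneHBond]:
    """Detect backbone amide-to-carbonyl hydrogen bonds geometrically.

    Criterion: donor backbone N of residue i, acceptor backbone O of
    residue j, N-O distance <= ``max_distance`` angstroms, in-chain
    sequence separation |i-j| >= ``min_separation``, and angle
    C(j)-O(j)...N(i) >= ``min_angle_deg`` (120 degrees, the standard
    carbonyl-side angular criterion; it rejects the spurious N-terminal
    i->i-3 contact of an ideal helix).  A donor N participates in at
    most one bond: the shortest N-O distance wins.  Proline contributes no
    donor (its backbone N carries no amide hydrogen).  Inter-chain bonds
    are only considered when ``include_interchain`` is set.

    Returns an empty list (not an error) when fewer than 4 complete
    residues are available.
    """
    complete = [r for r in structure.iter_residues() if r.is_complete]
    if len(complete) < 4:
        return []
    cos_max = math.cos(math.radians(min_angle_deg))

    bonds: list[BackboneHBond] = []
    for donor in complete:
        if donor.name == "PRO":
            continue
        n_xyz = donor.coord("N")
        best: tuple[float, Residue] | None = None
        for acceptor in complete:
            if acceptor is donor:
                continue
            same_chain = acceptor.chain_id == donor.chain_id
            if same_chain:
                if abs(acceptor.seqpos - donor.seqpos) < min_separation:
                    continue
            elif not include_interchain:
                continue
            o_xyz = acceptor.coord("O")
            d = float(np.linalg.norm(n_xyz - o_xyz))
            if d > max_distance:
                continue
            # angle at O between the O->C bond and the O->N direction;
            # >= 90 deg means N sits on the lone-pair side of the carbonyl
            v_c = acceptor.coord("C") - o_xyz
            v_n = n_xyz - o_xyz
            cos_angle = float(
                np.dot(v_c, v_n) / (np.linalg.norm(v_c) * np.linalg.norm(v_n))
            )
            if cos_angle > cos_max:
                continue
            if best is None or d < best[0]:
                best = (d, acceptor)
        if best is not None:
            d, acceptor = best
            bonds.append(
                BackboneHBond(
                    donor=(donor.chain_id, donor.index),
                    acceptor=(acceptor.chain_id, acceptor.index),
                    n_o_distance=d,
                )
            )
    bonds.sort(key=lambda b: (b.donor[0], _sort_key(b.donor[1])))
    return bonds


def _sort_key(index: str) -> tuple[int, str]:
    digits = "".join(ch for ch in index if ch.isdigit() or ch == "-")
    return (int(digits), index)


def compute_wrapping(
    structure: ProteinStructure, bond: BackboneHBond, radius: float = 6.0
) -> int:
    """Count nonpolar side-chain carbons inside the bond's desolvation domain.

    The domain is the union of two spheres of ``radius`` angstroms centred
    at the alpha-carbons of the bonded residues; a group lying in the
    intersection counts once.  Side chains of incomplete residues still
    contribute.  Raises :class:`DataError` if either residue lacks a CA.
    """
    if radius < 0:
        raise DataError("desolvation radius must be non-negative")
    ca1 = structure.residue(*bond.donor).coord("CA")
    ca2 = structure.residue(*bond.acceptor).coord("CA")
    zeta = 0
    r2 = radius * radius
    for res in structure.iter_residues():
        nonpolar = NONPOLAR_SIDECHAIN_CARBONS.get(res.name)
        if not nonpolar:
            continue
        for atom_name in nonpolar:
            atom = res.atoms.get(atom_name)
            if atom is None:
                continue
            xyz = np.asarray(atom.coords)
            d1 = xyz - ca1
            d2 = xyz - ca2
            if float(d1 @ d1) <= r2 or float(d2 @ d2) <= r2:
                zeta += 1
    return zeta


def classify_dehydron(zeta: int, threshold: int = 19) -> bool:
    """A bond is a dehydron iff its wrapping is at or below ``threshold``."""
    if zeta < 0:
        raise DataError(f"zeta must be non-negative, got {zeta}")
    return zeta <= threshold


def annotate_structure(
    structure: ProteinStructure,
    radius: float = 6.0,
    threshold: int = 19,
    include_interchain: bool = False,
) -> list[BackboneHBond]:
    """Detect bonds and fill in zeta for each; returns the annotated bonds."""
    bonds = detect_backbone_hbonds(structure, include_interchain=include_interchain)
    for bond in bonds:
        bond.zeta = compute_wrapping(structure, bond, radius=radius)
    return bonds


def structure_profile(
    structure: ProteinStructure, radius: float = 6.0, threshold: int = 19
) -> tuple[int, int]:
    """(n_dehydrons, n_bhbs) for one structure."""
    bonds = annotate_structure(structure, radius=radius, threshold=threshold)
    n_dehydrons = sum(classify_dehydron(b.zeta, threshold) for b in bonds)
    return n_dehydrons, len(bonds)


def compute_gene_nu(
    gene_id: str, profiles: Sequence[tuple[int, int]]
) -> GeneWrapping:
    """Pool (n_dehydrons, n_bhbs) across a gene's products and form nu.

    Counts are summed over all structures, then divided — the quotient
    extends over all gene products, it is not a mean of per-structure
    ratios.
    """
    if not profiles:
        raise DataError(f"gene {gene_id}: no structure profiles supplied")
    n_dehydrons = 0
    n_bhbs = 0
    for d, b in profiles:
        if d < 0 or b < 0 or d > b:
            raise DataError(
                f"gene {gene_id}: invalid profile (dehydrons={d}, bhbs={b})"
            )
        n_dehydrons += d
        n_bhbs += b
    gw = GeneWrapping(gene_id=gene_id, n_dehydrons=n_dehydrons, n_bhbs=n_bhbs)
    if n_bhbs == 0:
        raise UndefinedStatisticError(
            f"gene {gene_id}: nu undefined with zero backbone hydrogen bonds"
        )
    return gw
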