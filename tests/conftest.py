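import numpy as np
import pandas as pd
import pytest

from subwrap import analysis, divergence, expression, simulate
from subwrap.structure import (
    NONPOLAR_SIDECHAIN_CARBONS,
    ProteinStructure,
    Residue,
    AtomRecord,
)


def brute_force_zeta(structure, bond, radius=6.0):
    """Independent all-atom oracle: plain-python distance scan counting
    nonpolar side-chain carbons within ``radius`` of either alpha-carbon."""
    ca1 = structure.residue(*bond.donor).atoms["CA"].coords
    ca2 = structure.residue(*bond.acceptor).atoms["CA"].coords
    count = 0
    for res in structure.iter_residues():
        for atom_name in NONPOLAR_SIDECHAIN_CARBONS.get(res.name, ()):
            atom = res.atoms.get(atom_name)
            if atom is None:
                continue
            x, y, z = atom.coords
            for cx, cy, cz in (ca1, ca2):
                if ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) ** 0.5 <= radius:
                    count += 1
                    break
    return count


def transform_structure(structure, rotation=None, translation=None):
    """Rigid-body copy of a ProteinStructure (for invariance tests)."""
    rotation = np.eye(3) if rotation is None else np.asarray(rotation)
    translation = np.zeros(3) if translation is None else np.asarray(translation)
    chains = {}
    for chain_id, residues in structure.chains.items():
        new_residues = []
        for res in residues:
            atoms = {}
            for name, atom in res.atoms.items():
                xyz = rotation @ np.asarray(atom.coords) + translation
                atoms[name] = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element,
                    residue_index=atom.residue_index,
                    residue_name=atom.residue_name,
                    chain_id=atom.chain_id,
                    coords=tuple(float(v) for v in xyz),
                )
            new_residues.append(
                Residue(
                    chain_id=res.chain_id,
                    index=res.index,
                    seqpos=res.seqpos,
                    name=res.name,
                    atoms=atoms,
                )
            )
        chains[chain_id] = new_residues
    return ProteinStructure(structure_id=structure.structure_id, chains=chains)


def cohort_records(bundle):
    """Run a generated bundle through the in-memory pipeline stages up to
    the assembled family-record table."""
    fam_eta, fam_ks = [], []
    for fid, grp in bundle.family_map.groupby("family_id"):
        fe = expression.family_eta(bundle.expression, str(fid), list(grp["gene_id"]))
        fam_eta.append({"family_id": fe.family_id, "eta_bar": fe.eta_bar, "s": fe.s})
    tagged = bundle.ks_pairs.assign(fam=bundle.ks_pairs["gene_a"].str.split(".").str[0])
    for fid, grp in tagged.groupby("fam"):
        fk = divergence.family_ks(str(fid), list(grp["ks"]))
        fam_ks.append(
            {
                "family_id": fk.family_id,
                "ks": fk.ks,
                "passes_saturation_filter": fk.passes_saturation_filter,
            }
        )
    records, _ = analysis.assemble_table(
        bundle.gene_nu,
        pd.DataFrame(fam_eta),
        pd.DataFrame(fam_ks),
        bundle.family_map,
        bundle.wgd_pairs,
    )
    return records


@pytest.fixture(scope="session")
def ala_helix():
    from subwrap import structure as st

    return st.parse_structure(simulate.gen_helix_fixture(12, "ALA", seed=1), "ala12")


@pytest.fixture(scope="session")
def leu_helix():
    from subwrap import structure as st

    return st.parse_structure(simulate.gen_helix_fixture(12, "LEU", seed=1), "leu12")


@pytest.fixture(scope="session")
def small_noiseless_bundle():
    spec = simulate.CohortSpec(n_families=40, noise_sd=0.0, wgd_fraction=0.0, seed=11)
    return simulate.gen_cohort(spec)
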