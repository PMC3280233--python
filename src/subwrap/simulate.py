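"""Seed-deterministic generators for every input the pipeline consumes.

Four generators cover the pipeline's input surface: idealized alpha-helix
structures with controllable side-chain wrapping (PDB text), codon pairs
evolved to a specified synonymous divergence, expression families with a
specified pairwise Pearson correlation, and full analysis cohorts with a
planted linear Ks<nu> = a + b*<eta> relation plus a <nu>-independent
WGD subgroup.  Every planted parameter is recorded in the bundle's
ground-truth dictionary so downstream recovery can be checked exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence, expression
from .errors import SpecError

# ---------------------------------------------------------------------------
# helix fixtures

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_SUPPORTED_RESIDUES = ("GLY", "ALA", "LEU")


def _place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d bonded to c,
    with bond angle b-c-d and dihedral a-b-c-d."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helix_atoms(n_residues: int, residue_type: str) -> list[tuple[str, np.ndarray]]:
    """Idealised helix backbone plus side-chain atoms; returns
    (atom_name, coords) per residue in order."""
    backbone: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([1.458, 0.0, 0.0])
    theta = math.radians(111.2)
    c0 = ca0 + 1.525 * np.array([math.cos(math.pi - theta), math.sin(math.pi - theta), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = backbone[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, _PSI)
        ca = _place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, _OMEGA)
        c = _place_atom(prev["C"], n, ca, 1.525, 111.2, _PHI)
        backbone.append({"N": n, "CA": ca, "C": c})
    for res in backbone:
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], 1.231, 120.8, _PSI + 180.0)

    def side_chain(res: dict[str, np.ndarray]) -> list[tuple[str, np.ndarray]]:
        if residue_type == "GLY":
            return []
        # CB with L-chirality: det[N-CA, C-CA, CB-CA] > 0
        cb = _place_atom(res["N"], res["C"], res["CA"], 1.521, 110.6, 122.6)
        det = float(
            np.dot(
                np.cross(res["N"] - res["CA"], res["C"] - res["CA"]),
                cb - res["CA"],
            )
        )
        if det < 0:
            cb = _place_atom(res["N"], res["C"], res["CA"], 1.521, 110.6, -122.6)
        atoms = [("CB", cb)]
        if residue_type == "LEU":
            cg = _place_atom(res["N"], res["CA"], cb, 1.530, 116.3, -60.0)
            cd1 = _place_atom(res["CA"], cb, cg, 1.521, 110.7, 175.0)
            cd2 = _place_atom(res["CA"], cb, cg, 1.521, 110.7, -65.0)
            atoms += [("CG", cg), ("CD1", cd1), ("CD2", cd2)]
        return atoms

    out: list[tuple[str, np.ndarray]] = []
    for i, res in enumerate(backbone):
        per_res: list[tuple[str, np.ndarray]] = [
            ("N", res["N"]),
            ("CA", res["CA"]),
            ("C", res["C"]),
            ("O", res["O"]),
        ] + side_chain(res)
        for name, xyz in per_res:
            out.append((f"{i + 1}:{name}", xyz))
    return out


def gen_helix_fixture(
    n_residues: int,
    residue_type: str,
    seed: int,
    jitter_sd: float = 0.0,
    chain_id: str = "A",
) -> str:
    """PDB text for an ideal alpha-helix (phi = -57, psi = -47) of one
    residue type (GLY, ALA or LEU) with idealised side chains.

    ``jitter_sd`` adds isotropic Gaussian displacement (angstroms) to every
    atom, seed-deterministically; the default 0 keeps the exact ideal
    geometry.  Output is byte-identical for identical arguments.
    """
    if n_residues < 6:
        raise SpecError(f"helix fixture needs >= 6 residues, got {n_residues}")
    residue_type = residue_type.upper()
    if residue_type not in _SUPPORTED_RESIDUES:
        raise SpecError(
            f"unsupported residue type {residue_type!r}; choose from {_SUPPORTED_RESIDUES}"
        )
    if jitter_sd < 0:
        raise SpecError("jitter_sd must be non-negative")
    atoms = _helix_atoms(n_residues, residue_type)
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_sd, size=(len(atoms), 3)) if jitter_sd > 0 else None

    lines = [
        f"HEADER    SYNTHETIC HELIX FIXTURE ({residue_type} X {n_residues}, SEED {seed})"
    ]
    for serial, (key, xyz) in enumerate(atoms, start=1):
        res_index_str, name = key.split(":")
        res_index = int(res_index_str)
        if jitter is not None:
            xyz = xyz + jitter[serial - 1]
        element = name[0]
        atom_field = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {serial:5d} {atom_field}{'':1s}{residue_type:>3s} {chain_id}"
            f"{res_index:4d}{'':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# expression families

_EXPR_MEAN = 8.0
_EXPR_SD = 2.0


def gen_expression_family(
    n_members: int,
    n_conditions: int,
    target_eta: float,
    seed: int,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Expression matrix (members x conditions) whose member vectors share
    an exchangeable pairwise correlation ``target_eta``.

    Vectors are multivariate normal with correlation matrix
    (1 - rho) I + rho J, then globally shifted to non-negativity (a global
    shift leaves every pairwise Pearson coefficient unchanged).  The
    realised mean pairwise sample correlation converges to ``target_eta``
    as ``n_conditions`` grows.
    """
    if n_members < 2:
        raise SpecError("need at least 2 members")
    if n_conditions < 10:
        raise SpecError(f"need at least 10 conditions, got {n_conditions}")
    pd_bound = -1.0 / (n_members - 1)
    if not (pd_bound < target_eta < 1.0):
        raise SpecError(
            f"target_eta {target_eta} outside the positive-definiteness bound "
            f"({pd_bound:.3f}, 1) for {n_members} members"
        )
    rho = float(target_eta)
    corr = np.full((n_members, n_members), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_members, n_conditions))
    values = _EXPR_MEAN + _EXPR_SD * (chol @ z)
    low = values.min()
    if low < 0:
        values = values - low
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(n_members)]
    if len(gene_ids) != n_members:
        raise SpecError("gene_ids length must equal n_members")
    columns = [f"c{i + 1:02d}" for i in range(n_conditions)]
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns)


# ---------------------------------------------------------------------------
# codon pairs

def gen_codon_pair(
    n_codons: int, true_ks: float, seed: int, table_id: int = 1
) -> tuple[str, str]:
    """Two coding sequences descended from a random ancestor, each having
    accumulated synonymous-only substitutions.

    Per lineage the number of events is Poisson with mean
    ``true_ks / 2 * S`` where S is the ancestor's synonymous site count
    (NG86 counting); each event replaces one codon by a uniformly chosen
    synonymous single-nucleotide neighbour, with codons picked
    proportionally to their number of synonymous neighbours.  Stop codons
    can never arise (synonymous changes preserve the amino acid), so the
    true synonymous divergence between the two tips is exactly
    ``true_ks`` in expectation.
    """
    if n_codons < 50:
        raise SpecError(f"need >= 50 codons, got {n_codons}")
    if true_ks < 0:
        raise SpecError(f"true_ks must be non-negative, got {true_ks}")
    rng = np.random.default_rng(seed)
    codons = list(divergence.sense_codons(table_id))
    ancestor = [codons[i] for i in rng.integers(0, len(codons), size=n_codons)]
    total_syn_sites = sum(
        divergence.synonymous_site_fraction(c, table_id) for c in ancestor
    )

    def evolve(start: list[str]) -> list[str]:
        seq = list(start)
        n_events = rng.poisson(0.5 * true_ks * total_syn_sites)
        for _ in range(n_events):
            weights = np.array(
                [len(divergence.synonymous_neighbors(c, table_id)) for c in seq],
                dtype=float,
            )
            total = weights.sum()
            if total == 0:
                break
            idx = int(rng.choice(n_codons, p=weights / total))
            neighbors = divergence.synonymous_neighbors(seq[idx], table_id)
            seq[idx] = neighbors[int(rng.integers(0, len(neighbors)))]
        return seq

    tip_a = evolve(ancestor)
    tip_b = evolve(ancestor)
    return "".join(tip_a), "".join(tip_b)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSpec:
    """Parameters of a planted analysis cohort.

    ``relation`` = (a, b) of the planted Ks<nu> = a + b*<eta> + noise for
    small-scale-duplication (SSD) families; WGD-flagged families instead
    draw <nu> independently of everything else, so their S/Ks carries no
    <nu> trend.  Defaults describe a mid-sized multi-tissue cohort: 500
    families of 3 paralogs over a 20-condition panel, divergence-time
    proxy Ks in (1.2, 1.9) (inside the Ks < 2 saturation filter), and a
    negative slope b (more dosage-sensitive families segregate more).
    """

    n_families: int = 500
    members_per_family: int = 3
    n_conditions: int = 20
    eta_range: tuple[float, float] = (-0.3, 0.8)
    relation: tuple[float, float] = (0.55, -0.35)
    noise_sd: float = 0.05
    wgd_fraction: float = 0.2
    ks_range: tuple[float, float] = (1.2, 1.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise SpecError("n_families must be >= 1")
        if self.members_per_family < 2:
            raise SpecError("members_per_family must be >= 2")
        lo, hi = self.eta_range
        if not (-1.0 <= lo < hi <= 1.0):
            raise SpecError(f"eta_range {self.eta_range} invalid")
        if lo <= -1.0 / (self.members_per_family - 1):
            raise SpecError(
                "eta_range lower bound violates positive-definiteness for "
                f"{self.members_per_family} members"
            )
        klo, khi = self.ks_range
        if not (0.0 < klo < khi < 2.0):
            raise SpecError(f"ks_range {self.ks_range} must lie inside (0, 2)")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        if not 0.0 <= self.wgd_fraction <= 1.0:
            raise SpecError("wgd_fraction must lie in [0, 1]")


@dataclass
class CohortBundle:
    """Everything a pipeline run consumes, plus the planted ground truth."""

    family_map: pd.DataFrame  # family_id, gene_id
    gene_nu: pd.DataFrame  # gene_id, nu
    expression: pd.DataFrame  # genes x conditions
    ks_pairs: pd.DataFrame  # gene_a, gene_b, ks
    wgd_pairs: pd.DataFrame  # gene_a, gene_b
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import io as swio  # local import to avoid a cycle

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "family_map": outdir / "families.tsv",
            "gene_nu": outdir / "gene_nu.tsv",
            "expression": outdir / "expression.tsv",
            "ks_pairs": outdir / "ks_pairs.tsv",
            "wgd_pairs": outdir / "wgd_pairs.tsv",
            "truth": outdir / "truth.json",
        }
        swio.write_tsv(self.family_map, paths["family_map"])
        swio.write_tsv(self.gene_nu, paths["gene_nu"])
        swio.write_expression_matrix(self.expression, paths["expression"])
        swio.write_tsv(self.ks_pairs, paths["ks_pairs"])
        swio.write_tsv(self.wgd_pairs, paths["wgd_pairs"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


def gen_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate a full cohort with the planted SSD relation and WGD subgroup.

    The relation is planted against the REALISED family <eta> (recomputed
    from the generated expression matrix by the same operation the pipeline
    uses), so with ``noise_sd = 0`` the downstream fit recovers (a, b) with
    R^2 = 1 exactly.  An infeasible relation (forcing <nu> outside [0, 1])
    raises :class:`SpecError` rather than clipping.
    """
    a, b = spec.relation
    rng = np.random.default_rng(spec.seed)
    n_wgd = int(round(spec.n_families * spec.wgd_fraction))
    flags = np.zeros(spec.n_families, dtype=bool)
    flags[:n_wgd] = True
    rng.shuffle(flags)

    fam_rows, nu_rows, ks_rows, wgd_rows, truth_rows = [], [], [], [], []
    expr_frames = []
    for i in range(spec.n_families):
        family_id = f"F{i:04d}"
        genes = [f"{family_id}.g{j + 1}" for j in range(spec.members_per_family)]
        is_wgd = bool(flags[i])
        target_eta = float(rng.uniform(*spec.eta_range))
        expr = gen_expression_family(
            spec.members_per_family,
            spec.n_conditions,
            target_eta,
            seed=int(rng.integers(0, 2**31 - 1)),
            gene_ids=genes,
        )
        realized = expression.family_eta(expr, family_id, genes)
        ks = float(rng.uniform(*spec.ks_range))
        if is_wgd:
            nu = float(rng.uniform(0.05, 0.95))
        else:
            y0 = a + b * realized.eta_bar
            if not 0.0 <= y0 / ks <= 1.0:
                raise SpecError(
                    f"family {family_id}: relation forces <nu> = {y0 / ks:.3f} "
                    "outside [0, 1]; adjust relation/ks_range, no silent clipping"
                )
            nu = None
            for _ in range(100):
                candidate = (y0 + rng.normal(0.0, spec.noise_sd)) / ks
                if 0.0 <= candidate <= 1.0:
                    nu = float(candidate)
                    break
            if nu is None:
                raise SpecError(
                    f"family {family_id}: noise repeatedly forces <nu> outside [0, 1]"
                )
        for g in genes:
            fam_rows.append({"family_id": family_id, "gene_id": g})
            nu_rows.append({"gene_id": g, "nu": nu})
        for ga, gb in combinations(genes, 2):
            ks_rows.append({"gene_a": ga, "gene_b": gb, "ks": ks})
            if is_wgd:
                wgd_rows.append({"gene_a": ga, "gene_b": gb})
        expr_frames.append(expr)
        truth_rows.append(
            {
                "family_id": family_id,
                "is_wgd": is_wgd,
                "target_eta": target_eta,
                "realized_eta": realized.eta_bar,
                "ks": ks,
                "nu": nu,
            }
        )

    truth = {"spec": asdict(spec), "families": truth_rows}
    return CohortBundle(
        family_map=pd.DataFrame(fam_rows),
        gene_nu=pd.DataFrame(nu_rows),
        expression=pd.concat(expr_frames),
        ks_pairs=pd.DataFrame(ks_rows),
        wgd_pairs=pd.DataFrame(wgd_rows, columns=["gene_a", "gene_b"]),
        truth=truth,
    )
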