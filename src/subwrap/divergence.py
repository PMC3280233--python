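"""Pairwise synonymous divergence (Ks) from in-frame coding sequences.

Ks — synonymous substitutions per synonymous site — serves the pipeline as
a monotone proxy for the time since a duplication event.  It is estimated
with Nei–Gojobori (1986) counting: per-codon synonymous site fractions,
pathway-averaged synonymous differences for codons differing at more than
one position, and a Jukes–Cantor multiple-hit correction

    Ks = -(3/4) * ln(1 - (4/3) * p_s),   p_s = syn_diffs / syn_sites.

Conventions: a single-nucleotide change that would create a stop codon is
never counted as synonymous (it stays in the denominator of the per-site
fraction); substitution pathways passing through a stop codon are dropped
before averaging, with equal weights over the survivors.  The standard
nuclear code is the default; any NCBI table id may be supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable

from .errors import (
    AnalysisError,
    SaturationError,
    SequenceError,
    UndefinedStatisticError,
)

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"


@lru_cache(maxsize=None)
def _code(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 1) -> tuple[str, ...]:
    return tuple(sorted(_code(table_id).forward_table))


def translate_codon(codon: str, table_id: int = 1) -> str | None:
    """Amino acid for a codon, or ``None`` for a stop."""
    return _code(table_id).forward_table.get(codon)


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str, table_id: int = 1) -> float:
    """Number of synonymous sites in a codon (0..3).

    At each position the fraction of the three single-nucleotide changes
    that are synonymous; changes to stop codons are counted as
    non-synonymous.
    """
    aa = translate_codon(codon, table_id)
    if aa is None:
        raise SequenceError(f"stop codon {codon} has no synonymous sites")
    sites = 0.0
    for pos in range(3):
        n_syn = 0
        for nuc in NUCLEOTIDES:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if translate_codon(alt, table_id) == aa:
                n_syn += 1
        sites += n_syn / 3.0
    return sites


@lru_cache(maxsize=None)
def synonymous_neighbors(codon: str, table_id: int = 1) -> tuple[str, ...]:
    """All codons one substitution away that encode the same amino acid."""
    aa = translate_codon(codon, table_id)
    out = []
    for pos in range(3):
        for nuc in NUCLEOTIDES:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if translate_codon(alt, table_id) == aa:
                out.append(alt)
    return tuple(out)


@lru_cache(maxsize=None)
def codon_pair_differences(
    codon_a: str, codon_b: str, table_id: int = 1
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at k positions are resolved by averaging over the k!
    single-step substitution pathways; pathways crossing a stop codon are
    excluded (all pathways are used if every one crosses a stop).
    """
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        syn = nonsyn = 0.0
        current = codon_a
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from = translate_codon(current, table_id)
            aa_to = translate_codon(nxt, table_id)
            if aa_from is None or aa_to is None:
                through_stop = True
                nonsyn += 1.0
            elif aa_from == aa_to:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn, through_stop

    results = [walk(order) for order in permutations(diff_pos)]
    clean = [(s, n) for s, n, stop in results if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    codon_pairs: list[tuple[str, str]]

    def ungapped(self) -> list[tuple[str, str]]:
        return [
            (a, b) for a, b in self.codon_pairs if GAP_CODON not in (a, b)
        ]


@dataclass(frozen=True)
class PairDivergence:
    gene_a: str
    gene_b: str
    syn_sites: float
    syn_diffs: float
    p_s: float
    ks: float


@dataclass(frozen=True)
class FamilyKs:
    family_id: str
    ks: float
    passes_saturation_filter: bool
    n_pairs: int = 1


def _validate_cds(seq: str, name: str, table_id: int) -> list[str]:
    seq = seq.strip().upper().replace("U", "T")
    if not seq:
        raise SequenceError(f"{name}: empty coding sequence")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise SequenceError(f"{name}: invalid nucleotides {sorted(bad)}")
    if len(seq) % 3:
        raise SequenceError(f"{name}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stops = _code(table_id).stop_codons
    if codons and codons[-1] in stops:
        codons = codons[:-1]  # terminal stop removed
    if not codons:
        raise SequenceError(f"{name}: no codons left after stop removal")
    for i, codon in enumerate(codons):
        if codon in stops:
            raise SequenceError(f"{name}: internal stop codon {codon} at codon {i + 1}")
    return codons


def align_codon_pair(
    cds_a: str,
    cds_b: str,
    gene_a: str = "gene_a",
    gene_b: str = "gene_b",
    table_id: int = 1,
) -> CodonAlignment:
    """Globally align two coding sequences at the protein level and
    back-thread the alignment onto codons.

    Scoring: match +1, mismatch 0, gap -1.  Gap columns carry ``---`` and
    are excluded from downstream counting.
    """
    codons_a = _validate_cds(cds_a, gene_a, table_id)
    codons_b = _validate_cds(cds_b, gene_b, table_id)
    prot_a = "".join(translate_codon(c, table_id) for c in codons_a)
    prot_b = "".join(translate_codon(c, table_id) for c in codons_b)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    alignment = aligner.align(prot_a, prot_b)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])

    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-":
            pairs.append((GAP_CODON, codons_b[ib]))
            ib += 1
        elif cb == "-":
            pairs.append((codons_a[ia], GAP_CODON))
            ia += 1
        else:
            pairs.append((codons_a[ia], codons_b[ib]))
            ia += 1
            ib += 1
    return CodonAlignment(gene_a=gene_a, gene_b=gene_b, codon_pairs=pairs)


def ng86_ks(aln: CodonAlignment, table_id: int = 1) -> PairDivergence:
    """NG86 synonymous divergence with Jukes–Cantor correction.

    Raises :class:`SaturationError` when p_s >= 3/4 (the correction is
    undefined; the pair must be excluded, never reported as a number).
    """
    columns = aln.ungapped()
    if not columns:
        raise SequenceError(
            f"{aln.gene_a}/{aln.gene_b}: no ungapped codon columns"
        )
    syn_sites = 0.0
    syn_diffs = 0.0
    for ca, cb in columns:
        syn_sites += 0.5 * (
            synonymous_site_fraction(ca, table_id)
            + synonymous_site_fraction(cb, table_id)
        )
        sd, _ = codon_pair_differences(ca, cb, table_id)
        syn_diffs += sd
    if syn_sites == 0:
        raise UndefinedStatisticError(
            f"{aln.gene_a}/{aln.gene_b}: zero synonymous sites"
        )
    p_s = syn_diffs / syn_sites
    if p_s >= 0.75:
        raise SaturationError(
            f"{aln.gene_a}/{aln.gene_b}: p_s = {p_s:.3f} >= 3/4, "
            "Jukes-Cantor correction undefined (saturated pair)"
        )
    ks = -0.75 * math.log1p(-4.0 * p_s / 3.0)
    return PairDivergence(
        gene_a=aln.gene_a,
        gene_b=aln.gene_b,
        syn_sites=syn_sites,
        syn_diffs=syn_diffs,
        p_s=p_s,
        ks=ks,
    )


def pair_ks(
    cds_a: str,
    cds_b: str,
    gene_a: str = "gene_a",
    gene_b: str = "gene_b",
    table_id: int = 1,
) -> PairDivergence:
    """Convenience: align then estimate in one call."""
    return ng86_ks(align_codon_pair(cds_a, cds_b, gene_a, gene_b, table_id), table_id)


def family_ks(
    family_id: str, pair_values: list[float], ks_cutoff: float = 2.0
) -> FamilyKs:
    """Family Ks = arithmetic mean of finite pairwise values.

    Saturated pairs are dropped by the caller before this point; the
    saturation filter flags families whose mean reaches ``ks_cutoff``.
    """
    finite = [v for v in pair_values if math.isfinite(v)]
    if not finite:
        raise AnalysisError(f"family {family_id}: no finite pairwise Ks values")
    if any(v < 0 for v in finite):
        raise AnalysisError(f"family {family_id}: negative Ks value")
    ks = sum(finite) / len(finite)
    return FamilyKs(
        family_id=family_id,
        ks=ks,
        passes_saturation_filter=ks < ks_cutoff,
        n_pairs=len(finite),
    )
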