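"""Readers and writers for the pipeline's tabular formats, pipeline
configuration, and the end-to-end orchestrator.

All tabular interchange is UTF-8 TSV with a header row; lines starting
with ``#`` are comments.  Summary reports are JSON.  Floats are written in
shortest round-trip representation so a write/read cycle is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, disorder, divergence, expression
from .disorder import DisorderTrack
from .errors import FormatError, PipelineError, SubwrapError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Expression TSV: header row of condition ids, then one row per gene
    (gene id + one value per condition).  Empty cells and ``NA`` denote
    missing values.  Ragged rows, non-numeric cells and duplicate gene ids
    raise :class:`FormatError` naming the offending line."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        if header is None:
            header = [f.strip() for f in fields[1:] if f.strip()]
            if not header:
                raise FormatError(f"{path}:{lineno}: header row lists no conditions")
            continue
        if len(fields) != len(header) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(header) + 1} columns, got {len(fields)}"
            )
        gene = fields[0].strip()
        if gene in genes:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        values = []
        for col, cell in zip(header, fields[1:]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                ) from None
        genes.append(gene)
        rows.append(values)
    if header is None or not genes:
        raise FormatError(f"{path}: no expression data found")
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=header)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for gene, row in matrix.iterrows():
            cells = ["NA" if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# generic tidy TSVs

def read_tsv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={})
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_family_map(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=["family_id", "gene_id"])
    return df.astype({"family_id": str, "gene_id": str})


def read_gene_nu(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=["gene_id", "nu"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    bad = df[(df["nu"] < 0) | (df["nu"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: nu outside [0, 1] for {bad['gene_id'].iloc[0]!r}")
    return df.astype({"gene_id": str})


def read_ks_pairs(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=["gene_a", "gene_b", "ks"])
    return df.astype({"gene_a": str, "gene_b": str})


def read_wgd_pairs(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=["gene_a", "gene_b"])
    return df.astype({"gene_a": str, "gene_b": str})


def read_disorder_tracks(path: str | Path) -> dict[str, DisorderTrack]:
    """Per-residue score TSV (gene_id, residue_index, f_d) -> tracks."""
    df = read_tsv(path, required=["gene_id", "residue_index", "f_d"])
    tracks: dict[str, DisorderTrack] = {}
    for gene_id, group in df.groupby("gene_id", sort=True):
        ordered = group.sort_values("residue_index")
        tracks[str(gene_id)] = DisorderTrack(
            gene_id=str(gene_id), scores=ordered["f_d"].to_numpy(dtype=float)
        )
    return tracks


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


# ---------------------------------------------------------------------------
# configuration and orchestration

@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the analysis constants: 6 angstrom desolvation radius,
    dehydron threshold zeta <= 19, disorder band [0.35, 0.95), 30-residue
    disorder-run exclusion, Ks < 2 saturation cutoff.
    """

    expression_path: str | None = None
    family_map_path: str | None = None
    gene_nu_path: str | None = None
    disorder_path: str | None = None
    cds_path: str | None = None
    pairs_path: str | None = None
    ks_pairs_path: str | None = None
    wgd_pairs_path: str | None = None
    output_dir: str = "subwrap_out"

    desolvation_radius: float = 6.0
    dehydron_threshold: int = 19
    band: tuple[float, float] = (0.35, 0.95)
    max_disorder_run: int = 30
    ks_cutoff: float = 2.0
    degree: int = 1
    permutations: int = 10_000
    seed: int = 0
    log2: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(**data)


def _require(config: PipelineConfig, attr: str, stage: str) -> Path:
    value = getattr(config, attr)
    if not value:
        raise PipelineError(f"stage {stage}: config field {attr!r} not set")
    path = Path(value)
    if not path.exists():
        raise PipelineError(f"stage {stage}: missing input file {path}")
    return path


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except SubwrapError as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return inner

    return wrap


@_stage("eta")
def _stage_eta(config: PipelineConfig, matrix, family_map) -> pd.DataFrame:
    rows = []
    for family_id, group in family_map.groupby("family_id", sort=True):
        try:
            fe = expression.family_eta(
                matrix, str(family_id), list(group["gene_id"]), log2=config.log2
            )
        except SubwrapError as exc:
            logger.info("eta: %s", exc)
            continue
        rows.append(
            {
                "family_id": fe.family_id,
                "n_members": fe.n_members,
                "n_pairs": fe.n_pairs,
                "eta_bar": fe.eta_bar,
                "s": fe.s,
            }
        )
    if not rows:
        raise PipelineError("stage eta: no family with a defined <eta>")
    return pd.DataFrame(rows)


@_stage("ks")
def _stage_ks(config: PipelineConfig, family_map) -> pd.DataFrame:
    """Family Ks either from a precomputed pairwise table or from CDS."""
    if config.ks_pairs_path:
        pair_df = read_ks_pairs(_require(config, "ks_pairs_path", "ks"))
    else:
        cds = read_fasta(_require(config, "cds_path", "ks"))
        pairs = read_tsv(
            _require(config, "pairs_path", "ks"), required=["gene_a", "gene_b"]
        )
        rows = []
        for _, row in pairs.iterrows():
            ga, gb = str(row["gene_a"]), str(row["gene_b"])
            if ga not in cds or gb not in cds:
                logger.info("ks: missing CDS for pair %s/%s", ga, gb)
                continue
            try:
                pdiv = divergence.pair_ks(cds[ga], cds[gb], ga, gb)
            except SubwrapError as exc:
                logger.info("ks: pair %s/%s excluded: %s", ga, gb, exc)
                continue
            rows.append({"gene_a": ga, "gene_b": gb, "ks": pdiv.ks})
        pair_df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "ks"])
    gene_to_family = family_map.set_index("gene_id")["family_id"]
    rows = []
    grouped: dict[str, list[float]] = {}
    for _, row in pair_df.iterrows():
        fam_a = gene_to_family.get(row["gene_a"])
        fam_b = gene_to_family.get(row["gene_b"])
        if fam_a is None or fam_a != fam_b:
            continue
        grouped.setdefault(str(fam_a), []).append(float(row["ks"]))
    for family_id, values in sorted(grouped.items()):
        fk = divergence.family_ks(family_id, values, ks_cutoff=config.ks_cutoff)
        rows.append(
            {
                "family_id": fk.family_id,
                "ks": fk.ks,
                "n_pairs": fk.n_pairs,
                "passes_saturation_filter": fk.passes_saturation_filter,
            }
        )
    if not rows:
        raise PipelineError("stage ks: no within-family Ks pairs")
    return pd.DataFrame(rows)


@_stage("nu")
def _stage_nu(config: PipelineConfig) -> pd.DataFrame:
    if config.gene_nu_path:
        return read_gene_nu(_require(config, "gene_nu_path", "nu"))
    tracks = read_disorder_tracks(_require(config, "disorder_path", "nu"))
    rows = []
    for gene_id, track in tracks.items():
        if not disorder.sustainable_order_filter(track, config.max_disorder_run):
            logger.info("nu: gene %s excluded (unsustainable order)", gene_id)
            continue
        try:
            nu_seq = disorder.estimate_nu_from_sequence(track, config.band)
        except SubwrapError as exc:
            logger.info("nu: gene %s excluded: %s", gene_id, exc)
            continue
        rows.append({"gene_id": gene_id, "nu": nu_seq})
    if not rows:
        raise PipelineError("stage nu: no gene with a defined nu")
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute nu -> eta -> ks -> assemble -> analyze and write the report.

    Returns the report dictionary (also written as JSON, with the record
    table as TSV, under ``config.output_dir``).  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    logger.info("pipeline config: %s", asdict(config))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    family_map = read_family_map(_require(config, "family_map_path", "load"))
    matrix = read_expression_matrix(_require(config, "expression_path", "load"))
    gene_nu = _stage_nu(config)
    fam_eta = _stage_eta(config, matrix, family_map)
    fam_ks = _stage_ks(config, family_map)
    wgd_pairs = (
        read_wgd_pairs(_require(config, "wgd_pairs_path", "load"))
        if config.wgd_pairs_path
        else None
    )

    try:
        records, drops = analysis.assemble_table(
            gene_nu, fam_eta, fam_ks, family_map, wgd_pairs
        )
    except SubwrapError as exc:
        raise PipelineError(f"stage assemble: {exc}") from exc

    report: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "n_families": int(len(records)),
        "n_dropped": int(len(drops)),
        "drop_reasons": {
            str(k): int(v) for k, v in drops["reason"].value_counts().items()
        },
        "fits": {},
    }
    try:
        for degree in (1, 2):
            fit = analysis.fit_ksnu_vs_eta(records, degree=degree)
            report["fits"][f"degree_{degree}"] = {
                "coefficients": list(fit.coefficients),
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
            }
    except SubwrapError as exc:
        raise PipelineError(f"stage analyze: {exc}") from exc

    binned = analysis.bin_segregation(records)
    report["binned_segregation"] = [
        {
            "bin_low": float(r.bin_low),
            "bin_high": float(r.bin_high),
            "n_families": int(r.n_families),
            "mean_s_over_ks": None
            if pd.isna(r.mean_s_over_ks)
            else float(r.mean_s_over_ks),
        }
        for r in binned.itertuples()
    ]
    if records["is_wgd"].any():
        try:
            slope, p_value = analysis.wgd_flatness_test(
                records, n_permutations=config.permutations, seed=config.seed
            )
            report["wgd_flatness"] = {"slope": slope, "p_value": p_value}
        except SubwrapError as exc:
            logger.info("wgd flatness test skipped: %s", exc)
            report["wgd_flatness"] = None
    else:
        report["wgd_flatness"] = None

    write_tsv(records, outdir / "family_records.tsv")
    write_tsv(drops, outdir / "dropped_families.tsv")
    write_tsv(binned, outdir / "binned_segregation.tsv")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info(
        "pipeline complete: %d families analysed, %d dropped",
        len(records),
        len(drops),
    )
    return report
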