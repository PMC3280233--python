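"""Sequence-based under-wrapping inference from per-residue disorder scores.

Dehydrons sit in a twilight zone between order and disorder, so for genes
without solved structures they can be inferred from a disorder predictor's
per-residue score f_d in [0, 1]: residues with 0.35 <= f_d < 0.95 are
dehydron-prone, while long fully-disordered stretches (f_d >= 0.95) mean
no sustainable structure exists and wrapping cannot be assessed at all.
The predictor itself is not bundled; score tracks are consumed as input.

The per-gene sequence-based ratio nu_seq is the band fraction among
ordered residues — an explicit stand-in for the structural nu, labelled as
such in every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, UndefinedStatisticError

DEFAULT_BAND = (0.35, 0.95)
DEFAULT_MAX_DISORDER_RUN = 30


@dataclass
class DisorderTrack:
    gene_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise DataError(f"{self.gene_id}: disorder track must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.scores)):
            raise DataError(f"{self.gene_id}: non-finite disorder score")
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            raise DataError(f"{self.gene_id}: disorder scores must lie in [0, 1]")


def band_filter(
    track: DisorderTrack, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    """Boolean mask of dehydron-prone residues: lower <= f_d < upper."""
    lower, upper = band
    return (track.scores >= lower) & (track.scores < upper)


def sustainable_order_filter(
    track: DisorderTrack,
    max_disorder_run: int = DEFAULT_MAX_DISORDER_RUN,
    disorder_threshold: float = 0.95,
) -> bool:
    """False (exclude the gene) iff the track contains a run of at least
    ``max_disorder_run`` consecutive residues with f_d >= threshold."""
    disordered = track.scores >= disorder_threshold
    run = 0
    for flag in disordered:
        run = run + 1 if flag else 0
        if run >= max_disorder_run:
            return False
    return True


def estimate_nu_from_sequence(
    track: DisorderTrack,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """nu_seq: fraction of ordered residues (f_d < band upper bound) that
    fall inside the dehydron-prone band."""
    upper = band[1]
    ordered = track.scores < upper
    n_ordered = int(ordered.sum())
    if n_ordered == 0:
        raise UndefinedStatisticError(
            f"{track.gene_id}: nu_seq undefined, no residues below f_d = {upper}"
        )
    flagged = band_filter(track, band)
    return int(flagged.sum()) / n_ordered
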