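"""Paralog expression diversification (eta) and segregation (S).

For two paralogs with expression vectors X, Y over a panel of tissues or
developmental conditions, the diversification

    eta(X, Y) = <(X - <X>)(Y - <Y>)> / sqrt(<X^2> - <X>^2) sqrt(<Y^2> - <Y>^2)

is the Pearson product-moment coefficient, the mean < > running over
conditions.  The family value <eta> is the unweighted mean over all
unordered member pairs with a defined coefficient, and the segregation
parameter

    S = (1 - <eta>) / 2,   0 <= S <= 1,

maps perfect co-expression to 0 and perfect anti-correlated partitioning
of the ancestral expression pattern to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedStatisticError

MIN_CONDITIONS = 3


@dataclass(frozen=True)
class FamilyExpression:
    family_id: str
    eta_bar: float
    s: float
    n_members: int
    n_pairs: int


def pearson_eta(x: np.ndarray, y: np.ndarray) -> float:
    """Exact Pearson coefficient over conditions.

    Requires equal lengths of at least 3 and nonzero variance in both
    vectors; an undefined correlation raises rather than returning a
    placeholder value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise DataError("expression vectors must be 1-d and of equal length")
    if x.size < MIN_CONDITIONS:
        raise DataError(f"need at least {MIN_CONDITIONS} conditions, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("expression vectors must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("zero-variance expression vector")
    return float((xc @ yc) / np.sqrt(sx * sy))


def segregation(eta_bar: float) -> float:
    """S = (1 - <eta>) / 2."""
    if not np.isfinite(eta_bar) or not -1.0 <= eta_bar <= 1.0:
        raise DataError(f"<eta> must lie in [-1, 1], got {eta_bar}")
    return (1.0 - eta_bar) / 2.0


def _usable_pair(x: pd.Series, y: pd.Series, log2: bool) -> float | None:
    # pair computed over the intersection of observed conditions
    mask = x.notna() & y.notna()
    if int(mask.sum()) < MIN_CONDITIONS:
        return None
    xv = x[mask].to_numpy(dtype=float)
    yv = y[mask].to_numpy(dtype=float)
    if log2:
        xv = np.log2(xv + 1.0)
        yv = np.log2(yv + 1.0)
    try:
        return pearson_eta(xv, yv)
    except UndefinedStatisticError:
        return None


def family_eta(
    matrix: pd.DataFrame,
    family_id: str,
    members: list[str],
    log2: bool = False,
) -> FamilyExpression:
    """Mean pairwise eta over a family's members present in the matrix.

    Pairs with fewer than 3 shared observed conditions or a zero-variance
    vector are excluded from the mean; a family with no usable pair raises
    :class:`DataError` (the caller logs and drops it).
    """
    present = [m for m in members if m in matrix.index]
    if len(present) < 2:
        raise DataError(
            f"family {family_id}: fewer than 2 members with expression data"
        )
    etas = []
    for a, b in combinations(present, 2):
        value = _usable_pair(matrix.loc[a], matrix.loc[b], log2)
        if value is not None:
            etas.append(value)
    if not etas:
        raise DataError(f"family {family_id}: no member pair with defined eta")
    eta_bar = float(np.mean(etas))
    # guard against roundoff pushing the mean a ulp outside [-1, 1]
    eta_bar = min(1.0, max(-1.0, eta_bar))
    return FamilyExpression(
        family_id=family_id,
        eta_bar=eta_bar,
        s=segregation(eta_bar),
        n_members=len(present),
        n_pairs=len(etas),
    )
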