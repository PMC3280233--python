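"""Family-level statistics: the Ks<nu>-vs-<eta> regression, <nu>-binned
segregation, and the whole-genome-duplication (WGD) flatness control.

Each gene family contributes one record: its mean under-wrapping <nu>
(dosage sensitivity), mean pairwise expression diversification <eta>,
synonymous divergence Ks (divergence-time proxy) and segregation
S = (1 - <eta>)/2.  The central statistical surface is the ordinary
least-squares fit of the time-normalised dosage sensitivity Ks*<nu> on a
polynomial in <eta>; a buffering effect of subfunctionalization appears as
a significant dependence.  Duplicates born in a WGD incur no relative
dosage imbalance, so within the WGD subset S/Ks should be flat in <nu>;
flatness is assessed with a seeded permutation test on the OLS slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AnalysisError, PipelineError

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["family_id", "nu_bar", "eta_bar", "ks", "s", "is_wgd"]

#: Reason codes attached to families dropped during assembly.
DROP_REASONS = (
    "no_members",
    "missing_nu",
    "missing_expression",
    "missing_ks",
    "ks_saturated",
    "ks_zero",
)


@dataclass(frozen=True)
class RegressionResult:
    degree: int
    coefficients: tuple[float, ...]  # ascending powers of <eta>
    r_squared: float
    p_value: float
    n: int


def assemble_table(
    gene_nu: pd.DataFrame,
    family_expression: pd.DataFrame,
    family_ks: pd.DataFrame,
    family_map: pd.DataFrame,
    wgd_pairs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-gene wrapping, per-family expression and Ks into records.

    Parameters hold tidy frames: ``gene_nu`` (gene_id, nu),
    ``family_expression`` (family_id, eta_bar, s), ``family_ks``
    (family_id, ks, passes_saturation_filter), ``family_map``
    (family_id, gene_id) and optional ``wgd_pairs`` (gene_a, gene_b).

    Returns ``(records, drops)``; ``drops`` carries one row per excluded
    family with a reason code.  Raises :class:`PipelineError` when no
    family survives.
    """
    nu_by_gene = gene_nu.set_index("gene_id")["nu"]
    eta_by_family = family_expression.set_index("family_id")
    ks_by_family = family_ks.set_index("family_id")
    wgd_genes: set[str] = set()
    if wgd_pairs is not None and len(wgd_pairs):
        wgd_genes = set(wgd_pairs["gene_a"]) | set(wgd_pairs["gene_b"])

    records: list[dict] = []
    drops: list[dict] = []
    for family_id, group in family_map.groupby("family_id", sort=True):
        members = list(group["gene_id"])

        def drop(reason: str) -> None:
            drops.append({"family_id": family_id, "reason": reason})
            logger.info("family %s dropped: %s", family_id, reason)

        if not members:
            drop("no_members")
            continue
        member_nu = nu_by_gene.reindex(members).dropna()
        if member_nu.empty:
            drop("missing_nu")
            continue
        if family_id not in eta_by_family.index:
            drop("missing_expression")
            continue
        if family_id not in ks_by_family.index:
            drop("missing_ks")
            continue
        ks_row = ks_by_family.loc[family_id]
        if "passes_saturation_filter" in ks_row and not bool(
            ks_row["passes_saturation_filter"]
        ):
            drop("ks_saturated")
            continue
        ks = float(ks_row["ks"])
        if ks <= 0:
            drop("ks_zero")
            continue
        eta_row = eta_by_family.loc[family_id]
        eta_bar = float(eta_row["eta_bar"])
        s = float(eta_row["s"]) if "s" in eta_row else (1.0 - eta_bar) / 2.0
        records.append(
            {
                "family_id": family_id,
                "nu_bar": float(member_nu.mean()),
                "eta_bar": eta_bar,
                "ks": ks,
                "s": s,
                "is_wgd": any(g in wgd_genes for g in members),
            }
        )
    if not records:
        raise PipelineError("assemble_table: zero families survived all filters")
    records_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    drops_df = pd.DataFrame(drops, columns=["family_id", "reason"])
    if len(drops_df):
        counts = drops_df["reason"].value_counts().to_dict()
        logger.info("assemble_table drop counts: %s", counts)
    return records_df, drops_df


def fit_ksnu_vs_eta(records: pd.DataFrame, degree: int = 1) -> RegressionResult:
    """OLS fit of y = Ks * <nu> on a polynomial in <eta>.

    Coefficients are returned in ascending powers (intercept first); the
    p-value is the F-test of the overall fit.
    """
    if degree not in (1, 2):
        raise AnalysisError(f"degree must be 1 or 2, got {degree}")
    n = len(records)
    if n < degree + 2:
        raise AnalysisError(f"need at least {degree + 2} records, got {n}")
    eta = records["eta_bar"].to_numpy(dtype=float)
    y = (records["ks"] * records["nu_bar"]).to_numpy(dtype=float)
    if np.ptp(eta) == 0.0:
        raise AnalysisError("degenerate design: all <eta> values identical")
    design = np.vander(eta, degree + 1, increasing=True)
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        degree=degree,
        coefficients=tuple(float(c) for c in fit.params),
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        n=n,
    )


def bin_segregation(records: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Mean S/Ks in fixed-width <nu> bins over [0, 1].

    Bins are half-open [lo, hi) with the final bin closed at 1.0.  Empty
    bins are reported with NaN mean (missing, never zero).
    """
    if records.empty:
        raise AnalysisError("bin_segregation: empty record table")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    nu = records["nu_bar"].to_numpy(dtype=float)
    ratio = (records["s"] / records["ks"]).to_numpy(dtype=float)
    idx = np.digitize(nu, edges, right=False) - 1
    idx[nu >= 1.0] = n_bins - 1  # close the last bin
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_families": int(mask.sum()),
                "mean_s_over_ks": float(ratio[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_overview(records: pd.DataFrame, path: str) -> None:
    """Two-panel figure: Ks*<nu> vs <eta> scatter with the linear fit, and
    the binned mean S/Ks profile over <nu>."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    eta = records["eta_bar"].to_numpy(dtype=float)
    y = (records["ks"] * records["nu_bar"]).to_numpy(dtype=float)
    wgd = records["is_wgd"].astype(bool).to_numpy()
    ax1.scatter(eta[~wgd], y[~wgd], s=8, alpha=0.5, label="SSD")
    if wgd.any():
        ax1.scatter(eta[wgd], y[wgd], s=8, alpha=0.5, color="tab:red", label="WGD")
    fit = fit_ksnu_vs_eta(records, degree=1)
    grid = np.linspace(eta.min(), eta.max(), 50)
    ax1.plot(grid, fit.coefficients[0] + fit.coefficients[1] * grid, "k-",
             label=f"$R^2$ = {fit.r_squared:.2f}")
    ax1.set_xlabel(r"$\langle\eta\rangle$")
    ax1.set_ylabel(r"$K_s\,\langle\nu\rangle$")
    ax1.legend(fontsize=8)

    binned = bin_segregation(records)
    centers = (binned["bin_low"] + binned["bin_high"]) / 2
    ax2.plot(centers, binned["mean_s_over_ks"], "o-")
    ax2.set_xlabel(r"$\langle\nu\rangle$ bin")
    ax2.set_ylabel(r"mean $S/K_s$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise AnalysisError("degenerate design: all <nu> values identical")
    return float(xc @ (y - y.mean())) / denom


def wgd_flatness_test(
    records: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_records: int = 10,
) -> tuple[float, float]:
    """Slope of S/Ks on <nu> within the WGD subset, with a two-sided
    permutation p-value (shuffling <nu> across records, seeded).

    A flat slope with a non-significant p is the expected signature of
    duplicates that never produced a dosage imbalance.
    """
    wgd = records[records["is_wgd"].astype(bool)]
    if len(wgd) < min_records:
        raise AnalysisError(
            f"wgd_flatness_test: need >= {min_records} WGD records, got {len(wgd)}"
        )
    x = wgd["nu_bar"].to_numpy(dtype=float)
    y = (wgd["s"] / wgd["ks"]).to_numpy(dtype=float)
    slope = _ols_slope(x, y)

    rng = np.random.default_rng(seed)
    n = x.size
    # vectorised permutation slopes: argsort of iid uniforms gives
    # independent uniform permutations row-wise
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    xp = x[order]
    xc = xp - xp.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    perm_slopes = (xc @ yc) / np.einsum("ij,ij->i", xc, xc)
    p_value = (1.0 + np.count_nonzero(np.abs(perm_slopes) >= abs(slope))) / (
        n_permutations + 1.0
    )
    return slope, float(p_value)
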