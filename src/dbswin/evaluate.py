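"""Performance statistics for therapeutic-window predictions.

Two complementary views: correlation between predicted and actual
normalized windows (Pearson, plus a linear mixed-effects slope with a
random intercept per electrode, since contacts of one electrode are
repeated measures), and a ranking view -- order contacts within each
electrode by predicted window and ask how quickly a sequential search
guided by that order finds the clinician-chosen contact (cumulative hit
ratio), compared against an empirical null of 10,000 random rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformanceSummary",
    "HitRatioCurve",
    "pearson_performance",
    "lme_performance",
    "rank_contacts",
    "cumulative_hit_ratio",
    "permutation_null",
    "importance_report",
]


@dataclass
class PerformanceSummary:
    r: float
    p: float
    beta: float | None = None
    beta_ci: tuple | None = None
    beta_p: float | None = None
    n_contacts: int = 0
    n_electrodes: int = 0
    converged: bool = True


@dataclass
class HitRatioCurve:
    """Cumulative hit ratio per rank with permutation-null percentiles."""

    ranks: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    null_p95: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_electrodes: int = 0
    n_permutations: int = 0


def pearson_performance(y_true, y_pred) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(y_true, y_pred)
    return float(res.statistic), float(res.pvalue)


def lme_performance(y_true, y_pred, electrodes) -> PerformanceSummary:
    """Mixed-effects slope of actual on predicted windows.

    Fits ``y_true ~ y_pred`` with a random intercept per electrode by
    restricted maximum likelihood; reports the fixed slope with a Wald 95%
    CI and p-value.  A singular random-effect fit is reported with
    ``converged=False`` rather than raised.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y_true": np.asarray(y_true, dtype=float),
        "y_pred": np.asarray(y_pred, dtype=float),
        "electrode": list(electrodes),
    })
    counts = df.groupby("electrode").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >=2 electrodes with >=2 contacts")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("y_true ~ y_pred", df, groups=df["electrode"])
        try:
            fit = md.fit(reml=True)
            converged = bool(fit.converged)
        except np.linalg.LinAlgError:
            fit = md.fit(reml=True, method="powell")
            converged = False
    beta = float(fit.params["y_pred"])
    se = float(fit.bse["y_pred"])
    if np.isfinite(se) and se > 0:
        ci = (beta - 1.96 * se, beta + 1.96 * se)
        p = float(2 * stats.norm.sf(abs(beta / se)))
    else:
        # zero residual variance (e.g. exact predictions): CI collapses
        ci = (beta, beta)
        p = 0.0 if beta != 0 else float("nan")
    r, rp = pearson_performance(df.y_true, df.y_pred)
    return PerformanceSummary(
        r=r, p=rp, beta=beta, beta_ci=ci, beta_p=p,
        n_contacts=len(df), n_electrodes=df["electrode"].nunique(),
        converged=converged,
    )


def rank_contacts(predictions: pd.DataFrame) -> dict:
    """Per-electrode contact order, best predicted window first.

    ``predictions`` needs columns patient_id, side, contact_id, y_pred.
    Ties are broken by ascending contact id (stable, documented).
    Returns {(patient_id, side): [contact_id, ...]}.
    """
    out = {}
    for (pid, side), grp in predictions.groupby(["patient_id", "side"], sort=True):
        ordered = grp.sort_values(
            ["y_pred", "contact_id"], ascending=[False, True], kind="stable"
        )
        out[(pid, side)] = list(ordered["contact_id"])
    return out


def _optimal_positions(rankings: dict, optimal: dict, min_contacts: int):
    """1-based rank of the optimal contact per included electrode."""
    positions, counts = [], []
    for elec, order in sorted(rankings.items()):
        if len(order) < min_contacts:
            continue
        opt = optimal[elec]
        if opt not in order:
            raise ValueError(f"optimal contact {opt!r} absent from ranking of {elec}")
        positions.append(order.index(opt) + 1)
        counts.append(len(order))
    return np.asarray(positions), np.asarray(counts)


def cumulative_hit_ratio(
    rankings: dict, optimal: dict, min_contacts: int = 4
) -> HitRatioCurve:
    """Fraction of electrodes whose chosen contact is within the top i ranks.

    Electrodes with fewer than ``min_contacts`` tested contacts are
    excluded.  For ranks beyond an electrode's contact count the electrode
    counts as a hit (its chosen contact is certainly within its own list).
    The curve is nondecreasing and reaches 1 at the maximum contact count.
    """
    positions, counts = _optimal_positions(rankings, optimal, min_contacts)
    if positions.size == 0:
        raise ValueError("no electrode meets the minimum contact count")
    max_k = int(counts.max())
    ranks = np.arange(1, max_k + 1)
    observed = np.array([np.mean(positions <= i) for i in ranks])
    return HitRatioCurve(
        ranks=ranks, observed=observed, n_electrodes=positions.size
    )


def permutation_null(
    rankings: dict,
    optimal: dict,
    min_contacts: int = 4,
    n_perm: int = 10_000,
    seed: int = 0,
) -> HitRatioCurve:
    """Empirical null of the hit-ratio curve under random contact ranking.

    Each permutation draws an independent uniform random ordering per
    electrode (so the chosen contact's position is uniform on 1..K) and
    recomputes the curve; per rank, the null mean, sd and 95th percentile
    are returned, with observed ratios flagged significant where they
    exceed the 95th percentile.
    """
    curve = cumulative_hit_ratio(rankings, optimal, min_contacts)
    _, counts = _optimal_positions(rankings, optimal, min_contacts)
    rng = np.random.default_rng(seed)
    # random ordering => optimal position uniform on 1..K per electrode
    null_pos = rng.integers(1, counts + 1, size=(n_perm, counts.size))
    null_curves = (null_pos[:, :, None] <= curve.ranks[None, None, :]).mean(axis=1)
    null_mean = null_curves.mean(axis=0)
    null_sd = null_curves.std(axis=0, ddof=1)
    null_p95 = np.percentile(null_curves, 95, axis=0)
    return HitRatioCurve(
        ranks=curve.ranks, observed=curve.observed,
        null_mean=null_mean, null_sd=null_sd, null_p95=null_p95,
        significant=curve.observed > null_p95,
        n_electrodes=curve.n_electrodes, n_permutations=n_perm,
    )


def importance_report(
    frequency: pd.Series, parcel_lobes: dict | None = None
) -> pd.DataFrame:
    """Lobe x band importance from per-feature selection frequencies.

    For each (region group, band), importance is the sum of member-feature
    selection frequencies divided by the number of areas in the group; the
    STN is its own single-area group.  Feature names follow the table
    convention ``stn_<band>`` / ``coh_<parcel>_<band>``.
    """
    from .connectivity import PARCEL_LOBES

    lobes = parcel_lobes or PARCEL_LOBES

    def _parcel_of(column: str) -> str:
        body = column[len("coh_"):]
        for p in lobes:
            if body.startswith(p + "_"):
                return p
        raise ValueError(f"parcel of column {column!r} has no lobe assignment")

    lobe_sizes: dict[str, int] = {}
    for parcel, lobe in lobes.items():
        lobe_sizes[lobe] = lobe_sizes.get(lobe, 0) + 1

    rows: dict[tuple, float] = {}
    for feat, f in frequency.items():
        if feat.startswith("stn_"):
            group, band, size = "stn", feat[len("stn_"):], 1
        elif feat.startswith("coh_"):
            parcel = _parcel_of(feat)
            band = feat[len("coh_") + len(parcel) + 1:]
            if parcel not in lobes:
                raise ValueError(f"parcel {parcel!r} has no lobe assignment")
            group, size = lobes[parcel], lobe_sizes[lobes[parcel]]
        else:
            continue
        rows[(group, band)] = rows.get((group, band), 0.0) + float(f) / size

    table = pd.Series(rows).unstack(fill_value=0.0)
    table.index.name = "region_group"
    table.columns.name = "band"
    return table
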