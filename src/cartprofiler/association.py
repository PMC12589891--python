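"""Post-treatment correlate analysis.

Cytokines are pooled into functional category scores per patient and
timepoint, differenced between nominal timepoint pairs (pre -> week 1,
pre -> week 4, week 1 -> week 4), and rank-correlated (Spearman, midranks)
against response-associated cluster abundances.  Transgene persistence
curves are summarized by trapezoidal AUC over the measurement grid in days,
and the relationship between composite scorecard polygon area and
persistence AUC is assessed by Pearson correlation with an OLS fit and 95%
confidence interval on the slope.  Correlations are exploratory: no
multiple-testing correction by default (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cartprofiler.datasets import CorrelateSet

__all__ = [
    "DEFAULT_DELTA_PAIRS",
    "cytokine_group_scores",
    "timepoint_deltas",
    "spearman_assoc",
    "persistence_auc",
    "RegressionResult",
    "pearson_regression",
]

DEFAULT_DELTA_PAIRS: tuple[tuple[str, str], ...] = (("pre", "wk1"), ("pre", "wk4"), ("wk1", "wk4"))


def cytokine_group_scores(cset: CorrelateSet, log: bool = False) -> pd.DataFrame:
    """Functional cytokine scores: mean of member cytokines per patient/timepoint.

    Returns a long table (patient, group, timepoint, score).  With
    ``log=True`` the mean is taken over log1p concentrations.  Empty groups
    (declared in the grouping but with no measured member) are an error.
    """
    df = cset.cytokines.copy()
    df["group"] = df["cytokine"].map(cset.grouping)
    measured = set(df["group"].unique())
    declared = set(cset.grouping.values())
    empty = declared - measured
    if empty:
        raise ValueError(f"cytokine group(s) with no measured members: {sorted(empty)}")
    value = np.log1p(df["concentration"]) if log else df["concentration"]
    df = df.assign(value=value)
    scores = (
        df.groupby(["patient", "group", "timepoint"], sort=False)["value"]
        .mean()
        .rename("score")
        .reset_index()
    )
    return scores


def timepoint_deltas(
    scores: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_DELTA_PAIRS,
) -> pd.DataFrame:
    """Score changes between timepoint pairs: delta = later - earlier.

    Input is the long score table from :func:`cytokine_group_scores`.  A
    missing timepoint yields a NaN delta with a warning.  Deltas telescope:
    (pre -> wk4) = (pre -> wk1) + (wk1 -> wk4).
    """
    wide = scores.pivot_table(index=["patient", "group"], columns="timepoint", values="score")
    rows = []
    for earlier, later in pairs:
        name = f"{earlier}->{later}"
        if earlier not in wide.columns or later not in wide.columns:
            warnings.warn(f"timepoint missing for delta {name}; NaN emitted", stacklevel=2)
            delta = pd.Series(np.nan, index=wide.index)
        else:
            delta = wide[later] - wide[earlier]
        rows.append(delta.rename(name))
    return pd.concat(rows, axis=1)


def spearman_assoc(
    cluster_metrics: pd.DataFrame,
    deltas: pd.DataFrame,
    with_p: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Spearman rho between cluster metrics and cytokine-group deltas.

    ``cluster_metrics``: patients x metrics (e.g. response-associated cluster
    abundances); ``deltas``: the (patient, group) x pair table from
    :func:`timepoint_deltas`.  Ties are midranked (scipy).  Constant vectors
    give NaN.  Results are exploratory; ``bh_correct`` applies
    Benjamini-Hochberg across the matrix when p-values are requested.
    """
    flat = deltas.stack(future_stack=True).rename("delta").reset_index()
    delta_cols = flat.pivot_table(index="patient", columns=["group", "level_2"], values="delta")
    patients = cluster_metrics.index.intersection(delta_cols.index)
    if len(patients) < 3:
        raise ValueError("need at least 3 paired observations")
    rho = pd.DataFrame(index=cluster_metrics.columns, columns=delta_cols.columns, dtype=float)
    pvals = rho.copy()
    for m in cluster_metrics.columns:
        x = cluster_metrics.loc[patients, m].to_numpy(dtype=float)
        for c in delta_cols.columns:
            y = delta_cols.loc[patients, c].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                rho.loc[m, c] = np.nan
                pvals.loc[m, c] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = stats.spearmanr(x[ok], y[ok])
            rho.loc[m, c] = r
            pvals.loc[m, c] = p
    rho.attrs["note"] = "exploratory correlations; no multiplicity correction" if not bh_correct else "BH-adjusted"
    if not with_p:
        return rho
    if bh_correct:
        flat_p = pvals.to_numpy().ravel()
        ok = ~np.isnan(flat_p)
        adj = np.full_like(flat_p, np.nan)
        if ok.sum():
            adj[ok] = stats.false_discovery_control(flat_p[ok], method="bh")
        pvals = pd.DataFrame(adj.reshape(pvals.shape), index=pvals.index, columns=pvals.columns)
    return pd.concat({"rho": rho, "p": pvals}, axis=1)


def persistence_auc(curve: pd.DataFrame, time_col: str = "day", value_col: str = "level") -> pd.Series:
    """Trapezoidal AUC of transgene persistence per patient.

    ``curve``: long table (patient, day, level) on the measurement grid
    ({pre, 3 h, wk1, wk2, wk4} = {0, 0.125, 7, 14, 28} days).  Timepoints
    must be strictly increasing within each patient; fewer than 2 points is
    an error.
    """
    out = {}
    for patient, grp in curve.groupby("patient", sort=False):
        t = grp[time_col].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"patient {patient!r}: need at least 2 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"patient {patient!r}: timepoints must be strictly increasing")
        out[patient] = float(np.trapezoid(y, t))
    return pd.Series(out, name="persistence_auc")


@dataclass
class RegressionResult:
    """Pearson correlation with OLS line and 95% CI on the slope."""

    r: float
    p: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    n: int
    significant: bool  # at the conventional p < 0.05

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "n": self.n,
            "significant": self.significant,
        }


def pearson_regression(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> RegressionResult:
    """Pearson r (t-based p) with ordinary least squares and slope CI.

    Used for composite polygon area vs persistence AUC.  Zero variance in
    either variable is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.linregress(x, y)
    # exact linear relation: scipy reports p = 0 with zero residual variance
    tcrit = stats.t.ppf(1 - alpha / 2, len(x) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(ci[0]), float(ci[1])),
        n=len(x),
        significant=bool(res.pvalue < 0.05),
    )
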