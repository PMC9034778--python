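"""Neural-behavioral linkage: join LBA estimates with pause-locked dF/F.

One row per (subject, zone) carries the mean pause dF/F, the approach
drift (reward salience), the avoid drift (danger salience), and the
response caution; these support per-parameter correlations and a
standardized multiple regression of dF/F on the two drifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "build_linkage_table",
    "correlate_params",
    "regress_dff",
    "bh_qvalues",
]

PARAM_COLUMNS = ("v_approach", "v_avoid", "caution")


@dataclass
class RegressionResult:
    beta: dict[str, float]  # standardized coefficients
    r2: float
    adj_r2: float
    f_stat: float
    p_value: float
    n: int
    flags: list[str]


def build_linkage_table(lba_fits: dict, pause_dff_means) -> pd.DataFrame:
    """Inner join of per-(subject, zone) LBA posterior means and pause dF/F.

    ``lba_fits`` maps (subject, zone) -> PosteriorSamples (or a mapping of
    posterior means); ``pause_dff_means`` is a DataFrame with columns
    subject, zone, dff (or a Series indexed by (subject, zone)). Rows
    missing either side are dropped and logged.
    """
    rows = []
    for (subject, zone), fit in lba_fits.items():
        means = fit.posterior_mean() if hasattr(fit, "posterior_mean") else dict(fit)
        rows.append(
            {
                "subject": subject,
                "zone": zone,
                "v_approach": means["v_0"],
                "v_avoid": means["v_1"],
                "caution": means["caution"],
            }
        )
    lba = pd.DataFrame(rows)
    if isinstance(pause_dff_means, pd.Series):
        dff = pause_dff_means.rename("dff").reset_index()
        dff.columns = ["subject", "zone", "dff"]
    else:
        dff = pd.DataFrame(pause_dff_means)[["subject", "zone", "dff"]]
    if lba.empty or dff.empty:
        raise ValueError("empty join: no LBA fits or no dF/F aggregates")
    table = lba.merge(dff, on=["subject", "zone"], how="inner")
    n_dropped = len(lba) + len(dff) - 2 * len(table)
    if n_dropped:
        log.info("linkage join dropped %d one-sided rows", n_dropped)
    if table.empty:
        raise ValueError("empty join: no (subject, zone) overlap")
    return table.sort_values(["subject", "zone"]).reset_index(drop=True)


def correlate_params(table: pd.DataFrame, parameter: str) -> dict:
    """Pearson correlation of dF/F with one LBA parameter.

    Overall across all rows, plus descriptive per-subject coefficients
    over that subject's zone-level points (no inference on 3 points).
    """
    if parameter not in table.columns:
        raise KeyError(parameter)
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    x = table[parameter].to_numpy(float)
    y = table["dff"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"flag": "zero_variance", "r": None, "r2": None, "F": None, "p": None}
    r, p = stats.pearsonr(x, y)
    n = len(table)
    r2 = r**2
    f = r2 / (1 - r2) * (n - 2) if r2 < 1 else np.inf
    per_subject = {}
    for subject, grp in table.groupby("subject"):
        if len(grp) >= 3 and grp[parameter].std() > 0 and grp["dff"].std() > 0:
            per_subject[subject] = float(
                np.corrcoef(grp[parameter], grp["dff"])[0, 1]
            )
    return {
        "r": float(r),
        "r2": float(r2),
        "F": float(f),
        "p": float(p),
        "n": n,
        "per_subject": per_subject,
    }


def bh_qvalues(pvals: dict[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg adjusted p-values across a small family of tests."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    qs = {}
    prev = 1.0
    for rank, (name, p) in reversed(list(enumerate(items, start=1))):
        q = min(prev, p * m / rank)
        qs[name] = q
        prev = q
    return qs


def regress_dff(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = ("v_approach", "v_avoid"),
) -> RegressionResult:
    """OLS of z-scored dF/F on z-scored predictors: standardized betas,
    adjusted R^2, and the overall F test."""
    n = len(table)
    if n < len(predictors) + 2:
        raise ValueError("too few rows for regression")
    flags = []

    def z(col):
        v = table[col].to_numpy(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in {col}")
        return (v - v.mean()) / sd

    X = np.column_stack([z(p) for p in predictors])
    cond = np.linalg.cond(X.T @ X)
    if cond > 1e6:
        flags.append("collinear_predictors")
        log.warning("predictor condition number %.2g > 1e6", cond)
    y = z("dff")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    beta = {p: float(model.params[i + 1]) for i, p in enumerate(predictors)}
    return RegressionResult(
        beta=beta,
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=n,
        flags=flags,
    )
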