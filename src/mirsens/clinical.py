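"""Clinical association of miRNA expression: correlation, stage, survival.

Three analyses on a patient cohort table:

* Spearman correlation of each miRNA against all measured mRNAs, with
  Benjamini-Hochberg control (by default within each miRNA's family of
  tests) at adjusted p < 0.05.
* Pairwise two-sided Wilcoxon rank-sum tests of miRNA expression between
  tumor stages, excluding stages with too few patients; raw p-values are
  reported unadjusted.
* Median-split survival: patients are dichotomized at the cohort median of a
  miRNA (high = strictly above), Kaplan-Meier curves estimated per arm, and
  the two-group log-rank test applied. Supports overall survival (OS; any
  death is an event) and breast-cancer-specific survival (BCSS; non-disease
  deaths are censored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simulate import Cohort

logger = logging.getLogger("mirsens")

__all__ = [
    "mirna_mrna_correlation",
    "stage_comparison",
    "median_split_survival",
    "SurvivalResult",
]


def mirna_mrna_correlation(
    cohort: Cohort,
    mirna_ids: Sequence[str] | None = None,
    bh_scope: str = "per_mirna",
    alpha: float = 0.05,
    min_patients: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of each miRNA with every mRNA, BH-adjusted.

    Average ranks are used for ties; two-sided p-values come from the
    t-distribution approximation. ``bh_scope`` controls the adjustment
    family: ``"per_mirna"`` (default) adjusts across mRNAs separately for
    each miRNA; ``"global"`` adjusts across all pairs at once. Pairs with a
    constant vector get missing rho/p and are never significant.
    """
    if bh_scope not in ("per_mirna", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(cohort.mirna.columns)
    common = cohort.mirna.index.intersection(cohort.mrna.index)
    if len(common) < min_patients:
        raise ValueError(
            f"only {len(common)} patients with both measurements (< {min_patients})"
        )
    mrna = cohort.mrna.loc[common]
    n = len(common)
    mrna_ranks = mrna.rank(axis=0)
    mrna_const = (mrna.nunique() <= 1).to_numpy()

    frames = []
    for mir in mirna_ids:
        x = cohort.mirna.loc[common, mir]
        if x.nunique() <= 1:
            logger.warning("miRNA %r constant across patients; correlations undefined", mir)
            rho = np.full(mrna.shape[1], np.nan)
            p = np.full(mrna.shape[1], np.nan)
        else:
            xr = x.rank().to_numpy()
            xr = (xr - xr.mean()) / xr.std()
            yr = mrna_ranks.to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                yr = (yr - yr.mean(axis=0)) / yr.std(axis=0)
            rho = (xr @ yr) / n
            rho = np.clip(rho, -1.0, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
            p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
            rho = np.where(mrna_const, np.nan, rho)
            p = np.where(mrna_const, np.nan, p)
        frames.append(
            pd.DataFrame(
                {
                    "mirna": mir,
                    "mrna": mrna.columns,
                    "rho": rho,
                    "p": p,
                    "sign": np.sign(rho),
                }
            )
        )
    result = pd.concat(frames, ignore_index=True)
    result["p_adj"] = np.nan
    if bh_scope == "per_mirna":
        for mir in mirna_ids:
            mask = (result["mirna"] == mir) & result["p"].notna()
            if mask.any():
                result.loc[mask, "p_adj"] = multipletests(
                    result.loc[mask, "p"], method="fdr_bh"
                )[1]
    else:
        mask = result["p"].notna()
        if mask.any():
            result.loc[mask, "p_adj"] = multipletests(
                result.loc[mask, "p"], method="fdr_bh"
            )[1]
    result["significant"] = result["p_adj"] < alpha
    return result


def stage_comparison(
    cohort: Cohort,
    mirna_ids: Sequence[str] | None = None,
    min_group: int = 5,
) -> pd.DataFrame:
    """Pairwise rank-sum tests of miRNA expression between tumor stages.

    Stages with fewer than ``min_group`` patients are excluded (as is done
    for sparsely populated extreme stages); every remaining pair of stages is
    compared with a two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact
    where sample sizes permit. Raw p-values are reported without adjustment.
    Returns an empty table (with a logged reason) when fewer than two stages
    remain.
    """
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(cohort.mirna.columns)
    counts = cohort.patients["stage"].value_counts()
    eligible = sorted(counts.index[counts >= min_group])
    columns = ["mirna", "stage_a", "stage_b", "n_a", "n_b", "W", "p"]
    if len(eligible) < 2:
        logger.warning(
            "fewer than two stages with >= %d patients; stage comparison skipped",
            min_group,
        )
        return pd.DataFrame(columns=columns)
    records = []
    for mir in mirna_ids:
        expr = cohort.mirna[mir]
        for a, b in combinations(eligible, 2):
            xa = expr[cohort.patients["stage"] == a].to_numpy()
            xb = expr[cohort.patients["stage"] == b].to_numpy()
            if np.all(np.concatenate([xa, xb]) == xa[0]):
                w, p = float(len(xa) * len(xb)) / 2.0, 1.0
            else:
                w, p = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
            records.append(
                {"mirna": mir, "stage_a": a, "stage_b": b, "n_a": len(xa),
                 "n_b": len(xb), "W": float(w), "p": float(p)}
            )
    return pd.DataFrame.from_records(records, columns=columns)


@dataclass
class SurvivalResult:
    """Median-split survival analysis output for one miRNA and endpoint."""

    mirna: str
    endpoint: str
    n_high: int
    n_low: int
    chi2: float
    p: float
    km_high: pd.DataFrame
    km_low: pd.DataFrame


def _endpoint_events(patients: pd.DataFrame, endpoint: str) -> pd.Series:
    if endpoint == "os":
        return patients["event"].astype(int)
    if endpoint == "bcss":
        return ((patients["event"] == 1) & (patients["cause"] == "disease")).astype(int)
    raise ValueError(f"unknown endpoint {endpoint!r} (expected 'os' or 'bcss')")


def median_split_survival(
    cohort: Cohort,
    mirna: str,
    endpoint: str = "os",
    min_per_arm: int = 10,
) -> SurvivalResult:
    """Kaplan-Meier + log-rank comparison of high vs low miRNA expression.

    The high arm is expression *strictly above* the cohort median (ties at
    the median go to the low arm); patients missing expression or survival
    data are dropped first. The log-rank test uses the standard
    hypergeometric-variance form with 1 df.
    """
    expr = cohort.mirna[mirna]
    patients = cohort.patients.loc[expr.index.intersection(cohort.patients.index)]
    expr = expr.loc[patients.index]
    keep = expr.notna() & patients["time_months"].notna()
    expr, patients = expr[keep], patients[keep]
    events = _endpoint_events(patients, endpoint)
    median = expr.median()
    high = expr > median
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(f"degenerate median split for {mirna!r}: one arm is empty")
    if min(n_high, n_low) < min_per_arm:
        logger.warning(
            "median split for %r leaves %d/%d patients per arm (< %d)",
            mirna, n_high, n_low, min_per_arm,
        )
    t_high, e_high = patients.loc[high, "time_months"], events[high]
    t_low, e_low = patients.loc[~high, "time_months"], events[~high]
    lr = logrank_test(t_high, t_low, event_observed_A=e_high, event_observed_B=e_low)
    kms = []
    for label, t, e in (("high", t_high, e_high), ("low", t_low, e_low)):
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e, label=label)
        km = kmf.survival_function_.reset_index()
        km.columns = ["time", "survival"]
        kms.append(km)
    return SurvivalResult(
        mirna=mirna,
        endpoint=endpoint,
        n_high=n_high,
        n_low=n_low,
        chi2=float(lr.test_statistic),
        p=float(lr.p_value),
        km_high=kms[0],
        km_low=kms[1],
    )
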