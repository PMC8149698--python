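"""Sensitizer calling from normalized screen viability.

The hit definition is the screen's outlier rule: within each treatment group
(one cell line x one treatment arm), a library reagent is *sensitizing* when
its normalized viability falls more than ``k`` (default 3) standard deviations
below the median of all library reagents in that group, in a drug-containing
arm. Two exclusion criteria then apply: (1) reagents with a comparable
viability effect in the no-drug arm of the same cell line are removed (they
are toxic on their own, not drug sensitizers), and (2) miRNA inhibitors whose
target miRNA is not endogenously expressed in the untreated cells are removed
(inhibiting an absent miRNA cannot be a real effect). Candidates are reagents
that remain sensitizing in at least two distinct (cell line, arm) contexts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .normalize import LIBRARY_CLASSES
from .simulate import ExpressionPanel

logger = logging.getLogger("mirsens")

__all__ = [
    "group_stats",
    "call_sensitizers",
    "expressed_mirnas",
    "apply_exclusions",
    "select_candidates",
    "validation_ttest",
    "significance_stars",
    "EXCLUSION_NO_DRUG_EFFECT",
    "EXCLUSION_TARGET_NOT_EXPRESSED",
]

EXCLUSION_NO_DRUG_EFFECT = "no_drug_effect"
EXCLUSION_TARGET_NOT_EXPRESSED = "target_not_expressed"

_MAD_SCALE = 1.4826  # consistency factor to the Gaussian SD


def group_stats(
    table: pd.DataFrame,
    robust: bool = False,
    min_reagents: int = 10,
) -> pd.DataFrame:
    """Per-(cell line, arm) median and spread of library-reagent viability.

    Controls and empty wells are excluded by contract. Spread is the classical
    sample SD (ddof 1) including outliers, or the scaled MAD when
    ``robust=True``. Groups with fewer than ``min_reagents`` reagents are
    flagged ``low_n``; zero-spread groups are flagged ``degenerate`` and
    produce no hits downstream.
    """
    lib = table[table["reagent_class"].isin(LIBRARY_CLASSES)]
    if lib["normalized_viability"].isna().any():
        raise ValueError("normalized_viability missing: normalize the table first")
    records = []
    for (line, arm), grp in lib.groupby(["cell_line", "arm"], sort=True):
        values = grp["normalized_viability"].to_numpy()
        median = float(np.median(values))
        if robust:
            sd = float(_MAD_SCALE * np.median(np.abs(values - median)))
        else:
            sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        low_n = len(values) < min_reagents
        if low_n:
            logger.warning(
                "treatment group (%s, %s) has only %d reagents", line, arm, len(values)
            )
        records.append(
            {
                "cell_line": line,
                "arm": arm,
                "n_reagents": len(values),
                "median": median,
                "sd": sd,
                "low_n": low_n,
                "degenerate": sd == 0.0,
            }
        )
    return pd.DataFrame.from_records(records)


def call_sensitizers(
    table: pd.DataFrame,
    stats: pd.DataFrame,
    k: float = 3.0,
    no_drug_arm: str = "vehicle",
) -> pd.DataFrame:
    """Flag sensitizing library reagents per (cell line, arm).

    A reagent is flagged when its normalized viability is *strictly* below
    ``median - k * SD`` of its treatment group (ties at the threshold are not
    hits) and the arm contains drug. Only the low-viability tail is called.
    Degenerate (zero-SD) groups yield no flags. Replicate wells are averaged
    before the call.
    """
    lib = table[table["reagent_class"].isin(LIBRARY_CLASSES)]
    hits = (
        lib.groupby(
            ["reagent_id", "reagent_class", "cell_line", "arm"], sort=True, as_index=False
        )["normalized_viability"].mean()
    )
    keyed = stats.set_index(["cell_line", "arm"])
    missing = set(map(tuple, hits[["cell_line", "arm"]].drop_duplicates().to_numpy())) - set(
        keyed.index
    )
    if missing:
        raise KeyError(f"group stats missing for treatment groups: {sorted(missing)}")
    med = keyed["median"]
    sd = keyed["sd"]
    idx = pd.MultiIndex.from_frame(hits[["cell_line", "arm"]])
    group_median = med.reindex(idx).to_numpy()
    group_sd = sd.reindex(idx).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = np.where(
            group_sd > 0,
            (hits["normalized_viability"].to_numpy() - group_median) / group_sd,
            np.nan,
        )
    hits["deviation_sd"] = deviation
    hits["sensitizer"] = (
        (group_sd > 0)
        & (deviation < -k)
        & (hits["arm"] != no_drug_arm).to_numpy()
    )
    hits["excluded_no_drug_effect"] = False
    hits["excluded_not_expressed"] = False
    hits["exclusion_reason"] = ""
    hits["candidate"] = False
    return hits


def expressed_mirnas(
    panel: ExpressionPanel,
    untreated_arm: str = "vehicle",
    floor: float | None = None,
) -> dict[str, set[str]]:
    """Per cell line, the set of probes endogenously expressed when untreated.

    A probe counts as expressed in a cell line when, in at least one untreated
    sample of that line, its detection flag is true or (if ``floor`` is given)
    its value exceeds ``floor``.
    """
    result: dict[str, set[str]] = {}
    meta = panel.samples
    for line in meta["cell_line"].unique():
        cols = meta.index[(meta["cell_line"] == line) & (meta["arm"] == untreated_arm)]
        if not len(cols):
            result[line] = set()
            continue
        detected = panel.detected[cols].any(axis=1)
        if floor is not None:
            detected = detected | (panel.values[cols] > floor).any(axis=1)
        result[line] = set(detected.index[detected])
    return result


def apply_exclusions(
    hits: pd.DataFrame,
    expressed: Mapping[str, set[str]] | None = None,
    inhibitor_targets: Mapping[str, str] | None = None,
    k: float = 3.0,
    no_drug_arm: str = "vehicle",
) -> pd.DataFrame:
    """Apply the two sensitizer exclusion criteria.

    Criterion 1 (no-drug toxicity): a reagent at or below ``-k`` SD in the
    no-drug arm of a cell line loses all sensitizer flags in that cell line.
    Criterion 2 (target not expressed): an inhibitor whose target miRNA is not
    in the ``expressed`` set of the untreated cell line loses all flags there;
    mimics are never excluded by this criterion. ``inhibitor_targets`` maps
    inhibitor reagent ids to miRNA probe ids (identity mapping by default);
    inhibitors with no mappable target are retained with a warning.
    Exclusion reasons are recorded per row.
    """
    out = hits.copy()
    toxic = out[
        (out["arm"] == no_drug_arm) & (out["deviation_sd"] <= -k)
    ][["reagent_id", "cell_line"]]
    toxic_keys = set(map(tuple, toxic.to_numpy()))
    if toxic_keys:
        mask = [
            (rid, line) in toxic_keys
            for rid, line in zip(out["reagent_id"], out["cell_line"])
        ]
        mask = np.asarray(mask)
        out.loc[mask, "excluded_no_drug_effect"] = True
        lost = mask & out["sensitizer"].to_numpy()
        out.loc[lost, "exclusion_reason"] = EXCLUSION_NO_DRUG_EFFECT
        out.loc[mask, "sensitizer"] = False

    if expressed is not None:
        inhib = out["reagent_class"] == "inhibitor"
        excl_rows = np.zeros(len(out), dtype=bool)
        for i, (is_inhib, rid, line) in enumerate(
            zip(inhib, out["reagent_id"], out["cell_line"])
        ):
            if not is_inhib:
                continue
            if inhibitor_targets is not None:
                target = inhibitor_targets.get(rid)
                if target is None:
                    logger.warning(
                        "inhibitor %r has no mappable target miRNA; retained", rid
                    )
                    continue
            else:
                target = rid
            if target not in expressed.get(line, set()):
                excl_rows[i] = True
        out.loc[excl_rows, "excluded_not_expressed"] = True
        lost = excl_rows & out["sensitizer"].to_numpy()
        out.loc[lost, "exclusion_reason"] = EXCLUSION_TARGET_NOT_EXPRESSED
        out.loc[excl_rows, "sensitizer"] = False
    return out


def select_candidates(hits: pd.DataFrame) -> pd.DataFrame:
    """Flag candidate reagents: sensitizers in >= 2 (cell line, arm) contexts.

    Two distinct contexts necessarily mean either two cell lines (any arms) or
    one cell line under two treatment settings, the multi-context evidence
    required before validation.
    """
    out = hits.copy()
    sens = out.loc[out["sensitizer"], ["reagent_id", "cell_line", "arm"]]
    contexts = sens.drop_duplicates().groupby("reagent_id").size()
    candidates = set(contexts.index[contexts >= 2])
    out["candidate"] = out["reagent_id"].isin(candidates)
    return out


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional significance tiers."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def validation_ttest(
    norm_table: pd.DataFrame,
    candidate_ids: Sequence[str] | Iterable[str],
    control_id: str,
) -> pd.DataFrame:
    """Two-sided Student's t-test of each candidate vs the scrambled control.

    Operates on negative-control-median normalized viability (validation
    plates), comparing the replicate wells of each candidate reagent against
    the replicate wells of ``control_id`` within each treatment arm. Groups
    with fewer than two replicates on either side yield a missing p-value.
    """
    candidate_ids = list(candidate_ids)
    records = []
    for arm, arm_table in norm_table.groupby("arm", sort=True):
        control = arm_table.loc[
            arm_table["reagent_id"] == control_id, "normalized_viability"
        ].to_numpy()
        for rid in candidate_ids:
            values = arm_table.loc[
                arm_table["reagent_id"] == rid, "normalized_viability"
            ].to_numpy()
            if len(values) < 2 or len(control) < 2:
                p = np.nan
            else:
                t, p = sps.ttest_ind(values, control, equal_var=True)
                if np.isnan(p) and np.isclose(values.mean(), control.mean()):
                    p = 1.0  # zero variance on both sides, identical means
            records.append(
                {
                    "reagent_id": rid,
                    "arm": arm,
                    "n": len(values),
                    "mean_viability": values.mean() if len(values) else np.nan,
                    "control_mean": control.mean() if len(control) else np.nan,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame.from_records(records)
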