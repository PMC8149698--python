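"""miRNA microarray preprocessing and treatment-group differential testing.

Preprocessing follows the array convention: per sample, median-centre on the
*detected* (expressed) probes only, then set probes undetected in every
sample to one common floor value, so absent features share a single minimum
rather than contributing noise. Differential testing is a Kruskal-Wallis test
per probe across the treatment arms, run within three cell-line sets
(all lines combined, responsive lines, poorly responding lines), with
significance at a nominal p < 0.05 (no multiple-testing correction).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import ExpressionPanel

__all__ = ["preprocess", "kruskal_wallis_groups", "CELL_LINE_SETS"]

#: Named cell-line sets: all four lines, drug-responsive, poorly responding.
CELL_LINE_SETS = ("all_four", "responsive", "poor")


def preprocess(panel: ExpressionPanel, floor: float | None = None) -> ExpressionPanel:
    """Median-centre each sample on detected probes and floor absent probes.

    After centring, the median of detected probes is 0 in every sample.
    Probes undetected in all samples are set to ``floor`` in every sample;
    when ``floor`` is None it defaults to one less than the minimum centred
    value over detected probes (a common minimum below the measured range).
    """
    values = panel.values.copy()
    detected = panel.detected
    for sample in values.columns:
        det = detected[sample]
        if not det.any():
            raise ValueError(f"sample {sample!r} has no detected probes")
        values[sample] = values[sample] - values.loc[det, sample].median()
    never_detected = ~detected.any(axis=1)
    if floor is None:
        floor = float(values.to_numpy()[detected.to_numpy()].min()) - 1.0
    values.loc[never_detected, :] = floor
    return ExpressionPanel(values=values, detected=detected, samples=panel.samples)


def _set_mask(samples: pd.DataFrame, cellline_set: str) -> pd.Series:
    if cellline_set == "all_four":
        return pd.Series(True, index=samples.index)
    if cellline_set in ("responsive", "poor"):
        return samples["responder_class"] == cellline_set
    raise ValueError(f"unknown cell-line set {cellline_set!r}")


def kruskal_wallis_groups(
    panel: ExpressionPanel,
    cellline_set: str = "all_four",
    mode: str = "arms",
    untreated_arm: str = "vehicle",
    alpha: float = 0.05,
    min_per_arm: int = 2,
) -> pd.DataFrame:
    """Kruskal-Wallis differential expression across treatment arms.

    ``mode="arms"`` (default) runs one tie-corrected Kruskal-Wallis per probe
    across all treatment arms, pooling samples of the selected cell-line set;
    ``mode="pairwise"`` instead tests each drug arm against the untreated arm
    (two-group Kruskal-Wallis, equivalent to a rank-sum test) and reports the
    smallest arm's p per probe. Probes undetected in every sample of the set
    are skipped, as are probes whose arms have fewer than ``min_per_arm``
    samples. Significance is nominal p < ``alpha``.
    """
    if mode not in ("arms", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = _set_mask(panel.samples, cellline_set)
    samples = panel.samples[mask]
    arms = list(dict.fromkeys(samples["arm"]))
    if len(arms) < 2:
        raise ValueError("need at least two treatment arms")
    arm_cols = {arm: samples.index[samples["arm"] == arm] for arm in arms}
    for arm, cols in arm_cols.items():
        if len(cols) < min_per_arm:
            raise ValueError(f"arm {arm!r} has fewer than {min_per_arm} samples")

    records = []
    for probe in panel.values.index:
        if not panel.detected.loc[probe, samples.index].any():
            records.append(
                {"probe": probe, "cellline_set": cellline_set, "H": np.nan,
                 "p": np.nan, "significant": False, "skipped": "not_expressed"}
            )
            continue
        groups = [panel.values.loc[probe, cols].to_numpy() for cols in arm_cols.values()]
        if mode == "arms":
            h, p = _kruskal(groups)
        else:
            ref = panel.values.loc[probe, arm_cols[untreated_arm]].to_numpy()
            best = (np.nan, np.nan)
            for arm in arms:
                if arm == untreated_arm:
                    continue
                h_a, p_a = _kruskal([ref, panel.values.loc[probe, arm_cols[arm]].to_numpy()])
                if np.isnan(best[1]) or (not np.isnan(p_a) and p_a < best[1]):
                    best = (h_a, p_a)
            h, p = best
        record = {
            "probe": probe,
            "cellline_set": cellline_set,
            "H": h,
            "p": p,
            "significant": bool(p < alpha) if np.isfinite(p) else False,
            "skipped": "",
        }
        for arm, cols in arm_cols.items():
            record[f"median_{arm}"] = float(panel.values.loc[probe, cols].median())
        records.append(record)
    return pd.DataFrame.from_records(records)


def _kruskal(groups: list[np.ndarray], exact_max_n: int = 12) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p; H=0, p=1 when all values are equal.

    For pooled sample sizes up to ``exact_max_n`` the p-value comes from the
    exact permutation distribution of H (the chi-squared approximation is
    unreliable with a handful of samples per arm); larger samples use the
    chi-squared approximation with len(groups)-1 degrees of freedom.
    """
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    if len(pooled) <= exact_max_n:
        sizes = tuple(len(g) for g in groups)
        ranks = sps.rankdata(pooled)
        null = _exact_kw_null(sizes, tuple(np.sort(ranks)))
        p = float(np.mean(null >= h - 1e-9))
    return float(h), float(p)


@lru_cache(maxsize=32)
def _exact_kw_null(sizes: tuple[int, ...], sorted_ranks: tuple[float, ...]) -> np.ndarray:
    """Exact permutation distribution of tie-corrected H for given group sizes.

    Depends only on the pooled rank multiset (identical for every untied
    sample of the same size), so the enumeration is cached and shared across
    probes. Enumerates every partition of the ranks into groups of the given
    sizes and returns the H value of each.
    """
    ranks = np.asarray(sorted_ranks)
    n = len(ranks)
    _, counts = np.unique(ranks, return_counts=True)
    tie = 1.0 - float((counts**3 - counts).sum()) / (n**3 - n)
    const = 12.0 / (n * (n + 1))
    values: list[float] = []

    def recurse(available: tuple[int, ...], remaining_sizes: tuple[int, ...],
                acc: float) -> None:
        if len(remaining_sizes) == 1:
            s = ranks[list(available)].sum()
            values.append(acc + s * s / remaining_sizes[0])
            return
        size = remaining_sizes[0]
        for chosen in combinations(available, size):
            s = ranks[list(chosen)].sum()
            rest = tuple(i for i in available if i not in chosen)
            recurse(rest, remaining_sizes[1:], acc + s * s / size)

    recurse(tuple(range(n)), sizes, 0.0)
    h = const * np.asarray(values) - 3.0 * (n + 1)
    if tie > 0:
        h = h / tie
    return np.sort(h)
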