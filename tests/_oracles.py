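"""Independent reference implementations used to cross-check the pipeline.

Deliberately naive: plain loops, exhaustive enumeration, and textbook
formulas, sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# -- hit calling -------------------------------------------------------------


def brute_force_hits(
    wells: list[dict],
    k: float = 3.0,
    no_drug_arm: str = "vehicle",
    expressed: dict[str, set[str]] | None = None,
    inhibitor_targets: dict[str, str] | None = None,
) -> dict[tuple[str, str, str], bool]:
    """Loop-based sensitizer + exclusion calls.

    ``wells`` is a list of dicts with keys reagent_id, reagent_class,
    cell_line, arm, normalized_viability. Returns the final sensitizer flag
    per (reagent_id, cell_line, arm) for library reagents.
    """
    library = [w for w in wells if w["reagent_class"] in ("mimic", "inhibitor")]
    # average replicates
    acc: dict[tuple[str, str, str], list] = {}
    classes: dict[str, str] = {}
    for w in library:
        key = (w["reagent_id"], w["cell_line"], w["arm"])
        acc.setdefault(key, []).append(w["normalized_viability"])
        classes[w["reagent_id"]] = w["reagent_class"]
    values = {key: sum(v) / len(v) for key, v in acc.items()}

    groups: dict[tuple[str, str], list] = {}
    for w in library:
        groups.setdefault((w["cell_line"], w["arm"]), []).append(
            w["normalized_viability"]
        )
    stats = {}
    for key, vals in groups.items():
        med = float(np.median(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        stats[key] = (med, sd)

    def deviation(key):
        med, sd = stats[(key[1], key[2])]
        if sd == 0:
            return None
        return (values[key] - med) / sd

    flags = {}
    for key in values:
        dev = deviation(key)
        flags[key] = dev is not None and dev < -k and key[2] != no_drug_arm

    # criterion 1: no-drug effect per (reagent, cell line)
    for (rid, line, arm) in list(values):
        if arm != no_drug_arm:
            continue
        dev = deviation((rid, line, arm))
        if dev is not None and dev <= -k:
            for key in flags:
                if key[0] == rid and key[1] == line:
                    flags[key] = False

    # criterion 2: inhibitors of unexpressed miRNAs
    if expressed is not None:
        for key in list(flags):
            rid, line, _ = key
            if classes[rid] != "inhibitor":
                continue
            if inhibitor_targets is not None:
                target = inhibitor_targets.get(rid)
                if target is None:
                    continue
            else:
                target = rid
            if target not in expressed.get(line, set()):
                flags[key] = False
    return flags


# -- rank statistics ---------------------------------------------------------


def _rank(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the definition."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _rank(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)
    return h / tie if tie > 0 else float("nan")


def kruskal_exact_perm_p(groups: list[np.ndarray]) -> float:
    """Exact permutation p-value of Kruskal-Wallis by exhaustive enumeration.

    Enumerates every partition of the pooled observations into groups of the
    observed sizes (feasible at total n around 12) and counts partitions with
    H at least as large as observed.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _rank(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)

    h_obs = kruskal_h(groups)

    def all_partitions(indices, sizes):
        # groups are labeled (treatment arms), so enumerate ordered partitions
        if len(sizes) == 1:
            yield (tuple(indices),)
            return
        for g in combinations(indices, sizes[0]):
            remaining = [i for i in indices if i not in g]
            for tail in all_partitions(remaining, sizes[1:]):
                yield (g,) + tail

    count = total = 0
    for part in all_partitions(list(range(n)), sizes):
        h = 0.0
        for g_idx, size in zip(part, sizes):
            h += ranks[list(g_idx)].sum() ** 2 / size
        h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
        if tie > 0:
            h /= tie
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = _rank(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


# -- multiple testing --------------------------------------------------------


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values via the step-up formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = value
        prev = value
    return adjusted


# -- survival ----------------------------------------------------------------


def logrank_chi2(times, events, groups) -> float:
    """Two-group log-rank chi-squared from the O-E / hypergeometric-V table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# -- enrichment --------------------------------------------------------------


def hypergeom_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, N), by direct summation."""
    total = math.comb(M, N)
    return sum(
        math.comb(K, i) * math.comb(M - K, N - i)
        for i in range(k, min(K, N) + 1)
    ) / total
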