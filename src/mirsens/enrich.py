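"""miRNA target collection and gene-set over-representation analysis.

miRNAs are joined to target genes through a user-supplied map (tab-separated
``mirna  gene  tier`` with evidence tiers ``experimentally_observed`` and
``high_prediction``), and the pooled target list is tested for
over-representation against GMT gene sets with a one-sided hypergeometric
(upper-tail) test, Benjamini-Hochberg adjusted across sets, significant at
adjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mirsens")

__all__ = [
    "GeneSetCollection",
    "TARGET_TIERS",
    "read_gmt",
    "read_target_map",
    "collect_targets",
    "overrepresentation",
]

TARGET_TIERS = ("experimentally_observed", "high_prediction")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe of symbols.

    By default the universe is the union of all set members; pass an explicit
    universe (e.g. all measured mRNAs) to override.
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name  description  gene...``.

    Symbols are upper-cased and duplicate members deduplicated. A line with
    fewer than three fields is a parse error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)"
                )
            name, description, *genes = fields
            members = {g.strip().upper() for g in genes if g.strip()}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_target_map(path) -> pd.DataFrame:
    """Read a tab-separated miRNA-to-target map (mirna, gene, tier)."""
    table = pd.read_csv(path, sep="\t")
    for column in ("mirna", "gene", "tier"):
        if column not in table.columns:
            raise ValueError(f"target map missing column {column!r}")
    bad = set(table["tier"].unique()) - set(TARGET_TIERS)
    if bad:
        raise ValueError(f"unknown evidence tiers: {sorted(bad)}")
    table = table.drop_duplicates(subset=["mirna", "gene"])
    table["gene"] = table["gene"].str.upper()
    return table

def collect_targets(
    mirnas: Iterable[str],
    target_map: pd.DataFrame,
    tiers: Sequence[str] = TARGET_TIERS,
) -> list[str]:
    """Union of target genes of the given miRNAs at the requested tiers.

    miRNAs absent from the map are skipped with a warning; genes shared by
    several miRNAs appear once. Result is sorted for determinism.
    """
    unknown_tiers = set(tiers) - set(TARGET_TIERS)
    if unknown_tiers:
        raise ValueError(f"unknown tiers {sorted(unknown_tiers)}")
    known = set(target_map["mirna"])
    genes: set[str] = set()
    for mir in mirnas:
        if mir not in known:
            logger.warning("miRNA %r absent from target map; skipped", mir)
            continue
        rows = target_map[(target_map["mirna"] == mir) & target_map["tier"].isin(tiers)]
        genes.update(rows["gene"])
    return sorted(genes)


def overrepresentation(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    universe: set[str] | Mapping | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    For a universe of M genes, a set of K members, and a query of N genes with
    k overlapping, the p-value is the upper tail P(X >= k) of the
    hypergeometric distribution. Query genes outside the universe are dropped
    (count reported in the log); p-values are BH-adjusted across sets.
    """
    columns_early = ["set", "set_size", "overlap", "p", "p_adj", "significant"]
    if not collection.sets:
        return pd.DataFrame(columns=columns_early)
    uni = set(universe) if universe is not None else set(collection.universe)
    query = {g.upper() for g in query_genes}
    dropped = query - uni
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    query &= uni
    columns = ["set", "set_size", "overlap", "p", "p_adj", "significant"]
    if not query:
        logger.warning("empty query after universe filtering; no enrichment computed")
        return pd.DataFrame(columns=columns)
    M, N = len(uni), len(query)
    records = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & uni
        k = len(query & members)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(sps.hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        records.append({"set": name, "set_size": K, "overlap": k, "p": min(p, 1.0)})
    result = pd.DataFrame.from_records(records)
    result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    result["significant"] = result["p_adj"] < alpha
    return result[columns]
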