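"""Lysate-microarray protein normalization and deregulation calls.

Each printed lysate spot carries an antibody signal and a total-protein
(Sypro) reference; the loading-corrected abundance is ``log2(raw / sypro)``.
Z-scores are computed within a stratum — by default all conditions of one
(protein, cell line) — and a condition is a deregulation hit when |z| >= 2
(inclusive), with direction given by the sign.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("mirsens")

__all__ = ["sypro_log2", "zscore_and_call"]


def sypro_log2(table: pd.DataFrame) -> pd.DataFrame:
    """Total-protein normalization: ``normalized = log2(raw / sypro)``.

    Rows with a non-positive antibody or Sypro intensity cannot be
    log-ratioed and are dropped with a log entry.
    """
    out = table.copy()
    bad = ~((out["raw"] > 0) & (out["sypro"] > 0))
    if bad.any():
        logger.warning("dropping %d spots with non-positive intensities", int(bad.sum()))
        out = out[~bad].copy()
    out["normalized"] = np.log2(out["raw"].to_numpy() / out["sypro"].to_numpy())
    return out


def zscore_and_call(
    table: pd.DataFrame,
    z_threshold: float = 2.0,
    stratify_by: tuple[str, ...] = ("protein", "cell_line"),
    min_conditions: int = 3,
) -> pd.DataFrame:
    """Z-score normalized log2 ratios per stratum and call |z| >= threshold hits.

    z uses the sample SD (ddof 1) of the stratum. Strata with zero spread (or
    fewer than ``min_conditions`` members) get undefined z and no hits, with a
    warning. The threshold is inclusive; ``direction`` is +1/-1 for hits,
    0 otherwise.
    """
    if "normalized" not in table.columns:
        table = sypro_log2(table)
    out = table.copy()
    z = np.full(len(out), np.nan)
    for key, idx in out.groupby(list(stratify_by), sort=False).groups.items():
        values = out.loc[idx, "normalized"].to_numpy()
        if len(values) < min_conditions:
            logger.warning("stratum %r has %d (< %d) conditions; z undefined",
                           key, len(values), min_conditions)
            continue
        sd = values.std(ddof=1)
        if sd == 0:
            logger.warning("stratum %r has zero spread; z undefined", key)
            continue
        z[out.index.get_indexer(idx)] = (values - values.mean()) / sd
    out["z"] = z
    with np.errstate(invalid="ignore"):
        hit = np.abs(z) >= z_threshold
    out["hit"] = np.where(np.isnan(z), False, hit)
    out["direction"] = np.where(out["hit"], np.sign(z), 0.0).astype(int)
    return out
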