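"""Screen-table I/O and viability normalization.

Two normalization modes, matching the two experimental phases:

* **screen mode** (:func:`loess_log2_normalize`) — per plate, fit a loess
  surface of log2 luminescence over well (row, col) and subtract it, then
  recentre to the plate median so plates are comparable. Removes smooth
  spatial artifacts (edge effects, dispensing gradients) before outlier hit
  calling.
* **validation mode** (:func:`negcontrol_normalize`) — divide each well's raw
  signal by the plate-wise median of the scrambled negative-control wells
  (linear scale, no log), as used for the replicate validation plates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loess import loess2d

logger = logging.getLogger("mirsens")

__all__ = [
    "LoessConfig",
    "ScreenFormatError",
    "REQUIRED_COLUMNS",
    "REAGENT_CLASSES",
    "LIBRARY_CLASSES",
    "read_screen_table",
    "write_screen_table",
    "loess_log2_normalize",
    "negcontrol_normalize",
]

REQUIRED_COLUMNS = (
    "plate_id",
    "row",
    "col",
    "reagent_id",
    "reagent_class",
    "cell_line",
    "arm",
    "raw_signal",
)

REAGENT_CLASSES = frozenset(
    {"mimic", "inhibitor", "neg_control", "pos_control", "empty"}
)
#: Classes counted as library reagents (controls and empty wells excluded).
LIBRARY_CLASSES = ("mimic", "inhibitor")


class ScreenFormatError(ValueError):
    """Malformed screen table (missing column, bad class, duplicate well)."""


@dataclass(frozen=True)
class LoessConfig:
    """Loess spatial-correction settings.

    span:
        Neighbourhood fraction in (0, 1]; default 0.5.
    degree:
        Local polynomial degree (1 or 2); default 1.
    fit_wells:
        Which wells the surface is fitted on: ``"library_only"`` (mimics and
        inhibitors; default, since control wells are spatially clustered) or
        ``"all_non_positive_control"``.
    robust_iters:
        Bisquare robustifying passes of the loess fit, so strong hits do not
        pull the surface toward themselves; default 1.
    """

    span: float = 0.5
    degree: int = 1
    fit_wells: str = "library_only"
    robust_iters: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.fit_wells not in ("library_only", "all_non_positive_control"):
            raise ValueError(f"unknown fit_wells mode {self.fit_wells!r}")


def validate_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, reagent classes, positivity and well uniqueness."""
    for column in REQUIRED_COLUMNS:
        if column not in table.columns:
            raise ScreenFormatError(f"screen table missing required column {column!r}")
    bad_class = set(table["reagent_class"].unique()) - REAGENT_CLASSES
    if bad_class:
        raise ScreenFormatError(
            f"unknown reagent_class values: {sorted(bad_class)}"
        )
    nonpos = table[~(table["raw_signal"] > 0)]
    if len(nonpos):
        first = nonpos.iloc[0]
        raise ValueError(
            "non-positive raw_signal at "
            f"plate {first['plate_id']!r} row {first['row']} col {first['col']} "
            f"({len(nonpos)} wells affected)"
        )
    dup = table.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        first = table[dup].iloc[0]
        raise ScreenFormatError(
            "duplicate well position: "
            f"plate {first['plate_id']!r} row {first['row']} col {first['col']}"
        )
    return table


def read_screen_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a delimited per-well screen table."""
    table = pd.read_csv(path, sep=sep)
    return validate_screen_table(table)


def write_screen_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False, float_format="%.6g")


def _fit_mask(plate: pd.DataFrame, cfg: LoessConfig) -> pd.Series:
    if cfg.fit_wells == "library_only":
        return plate["reagent_class"].isin(LIBRARY_CLASSES)
    return plate["reagent_class"] != "pos_control"


def loess_log2_normalize(
    table: pd.DataFrame,
    cfg: LoessConfig | None = None,
    min_fit_wells: int = 20,
) -> pd.DataFrame:
    """Loess-normalize and log2-transform well signals, plate by plate.

    For each plate a loess surface of ``log2(raw_signal)`` over (row, col) is
    fitted on the configured fit wells and evaluated at every well; the
    normalized viability is ``log2(raw) - fitted + plate median of log2(raw)
    over fit wells``, so a spatially flat plate is returned unchanged and the
    plate-level location is preserved. Plates with fewer than
    ``min_fit_wells`` fit wells are skipped (normalized value left missing)
    with a logged warning.
    """
    cfg = cfg or LoessConfig()
    validate_screen_table(table)
    out = table.copy()
    normalized = np.full(len(out), np.nan)
    for plate_id, idx in out.groupby("plate_id", sort=False).groups.items():
        plate = out.loc[idx]
        fit = plate[_fit_mask(plate, cfg)]
        if len(fit) < min_fit_wells:
            logger.warning(
                "plate %r skipped: only %d fit wells (< %d)",
                plate_id,
                len(fit),
                min_fit_wells,
            )
            continue
        log2_fit = np.log2(fit["raw_signal"].to_numpy())
        fitted = loess2d(
            fit["row"].to_numpy(),
            fit["col"].to_numpy(),
            log2_fit,
            plate["row"].to_numpy(),
            plate["col"].to_numpy(),
            span=cfg.span,
            degree=cfg.degree,
            robust_iters=cfg.robust_iters,
        )
        log2_all = np.log2(plate["raw_signal"].to_numpy())
        residual = log2_all - fitted
        # recentre so the fit-well median of normalized values equals the
        # fit-well median of log2(raw) exactly
        fit_pos = _fit_mask(plate, cfg).to_numpy()
        normalized[out.index.get_indexer(idx)] = (
            residual - np.median(residual[fit_pos]) + np.median(log2_fit)
        )
    out["normalized_viability"] = normalized
    return out


def negcontrol_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each well to the plate-wise negative-control median.

    Validation-plate convention: ``normalized_viability =
    raw_signal / median(raw_signal of neg_control wells on the same plate)``,
    on the linear scale. Raises if any plate has no negative-control wells,
    listing every offending plate id.
    """
    validate_screen_table(table)
    out = table.copy()
    neg = out[out["reagent_class"] == "neg_control"]
    medians = neg.groupby("plate_id")["raw_signal"].median()
    missing = sorted(set(out["plate_id"].unique()) - set(medians.index))
    if missing:
        raise ValueError(
            f"plates without negative-control wells: {missing}"
        )
    out["normalized_viability"] = (
        out["raw_signal"] / out["plate_id"].map(medians)
    ).to_numpy()
    return out
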