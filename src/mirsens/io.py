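"""Delimited-text I/O for expression panels and cohorts.

All artifacts are tab-separated UTF-8 text with a single header row, written
with a fixed float format so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import Cohort, ExpressionPanel

__all__ = [
    "FLOAT_FORMAT",
    "write_panel",
    "read_panel",
    "write_cohort",
    "read_cohort",
    "write_table",
]

FLOAT_FORMAT = "%.6g"


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_panel(panel: ExpressionPanel, prefix) -> list[Path]:
    """Write a panel as ``<prefix>.values.tsv``, ``.detected.tsv``, ``.samples.tsv``."""
    prefix = Path(prefix)
    paths = [
        prefix.with_suffix(".values.tsv"),
        prefix.with_suffix(".detected.tsv"),
        prefix.with_suffix(".samples.tsv"),
    ]
    panel.values.rename_axis("probe").to_csv(paths[0], sep="\t", float_format=FLOAT_FORMAT)
    panel.detected.rename_axis("probe").astype(int).to_csv(paths[1], sep="\t")
    panel.samples.to_csv(paths[2], sep="\t")
    return paths


def read_panel(prefix) -> ExpressionPanel:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".values.tsv"), sep="\t", index_col=0)
    detected = pd.read_csv(
        prefix.with_suffix(".detected.tsv"), sep="\t", index_col=0
    ).astype(bool)
    samples = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col=0)
    return ExpressionPanel(values=values, detected=detected, samples=samples)


def write_cohort(cohort: Cohort, prefix) -> list[Path]:
    """Write a cohort as ``<prefix>.patients.tsv``, ``.mirna.tsv``, ``.mrna.tsv``."""
    prefix = Path(prefix)
    paths = [
        prefix.with_suffix(".patients.tsv"),
        prefix.with_suffix(".mirna.tsv"),
        prefix.with_suffix(".mrna.tsv"),
    ]
    cohort.patients.to_csv(paths[0], sep="\t", float_format=FLOAT_FORMAT)
    cohort.mirna.rename_axis("patient_id").to_csv(paths[1], sep="\t", float_format=FLOAT_FORMAT)
    cohort.mrna.rename_axis("patient_id").to_csv(paths[2], sep="\t", float_format=FLOAT_FORMAT)
    return paths


def read_cohort(prefix) -> Cohort:
    prefix = Path(prefix)
    patients = pd.read_csv(prefix.with_suffix(".patients.tsv"), sep="\t", index_col=0)
    if "cause" in patients.columns:
        patients["cause"] = patients["cause"].fillna("")
    mirna = pd.read_csv(prefix.with_suffix(".mirna.tsv"), sep="\t", index_col=0)
    mrna = pd.read_csv(prefix.with_suffix(".mrna.tsv"), sep="\t", index_col=0)
    return Cohort(patients=patients, mirna=mirna, mrna=mrna)
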