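"""End-to-end workflows: screen -> hits -> validation, and cohort association.

Each workflow reads (or simulates) its inputs, runs the analysis stages in
order, writes every stage output as tab-separated text into an artifact
directory, and finishes with a JSON manifest recording the configuration
hash, seed, package version, per-stage row counts (the screen's selection
funnel), and a sha256 digest of every output so reruns can be verified
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clinical import median_split_survival, mirna_mrna_correlation, stage_comparison
from .diffexpr import CELL_LINE_SETS, kruskal_wallis_groups, preprocess
from .enrich import GeneSetCollection, overrepresentation, read_gmt
from .hits import (
    apply_exclusions,
    call_sensitizers,
    expressed_mirnas,
    group_stats,
    select_candidates,
    validation_ttest,
)
from .io import FLOAT_FORMAT, read_cohort, read_panel, write_cohort, write_panel
from .normalize import LoessConfig, loess_log2_normalize, negcontrol_normalize, read_screen_table
from .simulate import (
    CohortSimConfig,
    ScreenSimConfig,
    SpikeSpec,
    generate_cohort,
    generate_expression_panel,
    generate_screen,
)

logger = logging.getLogger("mirsens")

__all__ = ["load_config", "run_screen_workflow", "run_clinical_workflow"]


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write(table: pd.DataFrame, path: Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _finalize(out_dir: Path, config: dict, seed: int, outputs: dict[str, Path],
              counts: dict[str, int]) -> Path:
    manifest = {
        "config_sha256": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "outputs": {name: {"file": p.name, "sha256": _sha256(p)} for name, p in outputs.items()},
        "row_counts": counts,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _screen_sim_config(section: dict, seed: int) -> ScreenSimConfig:
    spikes = tuple(
        SpikeSpec(
            **{
                **s,
                "cell_lines": tuple(s["cell_lines"]) if s.get("cell_lines") else None,
                "arms": tuple(s["arms"]) if s.get("arms") else None,
            }
        )
        for s in section.pop("spikes", [])
    )
    for key in ("cell_lines", "arms"):
        if key in section:
            section[key] = tuple(section[key])
    return ScreenSimConfig(**section, spikes=spikes, seed=seed)


def run_screen_workflow(config: dict, out_dir) -> Path:
    """Run the screening workflow and return the artifact directory.

    Stages: loess+log2 normalization, treatment-group statistics, sensitizer
    calling with both exclusion criteria, multi-context candidate selection
    and (toggleable) the replicate validation t-test on negative-control-
    normalized plates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})
    k = float(config.get("k", 3.0))
    loess_cfg = LoessConfig(**config.get("loess", {}))

    screen_section = dict(config.get("screen", {}))
    if "path" in screen_section:
        table = read_screen_table(screen_section["path"])
        truth = None
        no_drug_arm = screen_section.get("no_drug_arm", "vehicle")
    else:
        sim_cfg = _screen_sim_config(dict(screen_section.get("simulate", {})), seed)
        table, truth = generate_screen(sim_cfg)
        no_drug_arm = sim_cfg.no_drug_arm

    expr_section = dict(config.get("expression", {}))
    if "path" in expr_section:
        panel = read_panel(expr_section["path"])
    else:
        sim = dict(expr_section.get("simulate", {}))
        sim.setdefault("seed", seed + 1)
        panel, _ = generate_expression_panel(**sim)

    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {"input_wells": len(table)}

    normalized = loess_log2_normalize(table, loess_cfg)
    _write(normalized, out_dir / "normalized.tsv")
    outputs["normalized"] = out_dir / "normalized.tsv"

    stats = group_stats(normalized)
    _write(stats, out_dir / "group_stats.tsv")
    outputs["group_stats"] = out_dir / "group_stats.tsv"

    hits = call_sensitizers(normalized, stats, k=k, no_drug_arm=no_drug_arm)
    counts["sensitizers_before_exclusion"] = int(hits["sensitizer"].sum())
    expressed = expressed_mirnas(panel, untreated_arm=no_drug_arm)
    hits = apply_exclusions(hits, expressed=expressed, k=k, no_drug_arm=no_drug_arm)
    counts["sensitizers_after_exclusion"] = int(hits["sensitizer"].sum())
    hits = select_candidates(hits)
    _write(hits, out_dir / "hits.tsv")
    outputs["hits"] = out_dir / "hits.tsv"

    candidates = sorted(hits.loc[hits["candidate"], "reagent_id"].unique())
    counts["candidates"] = len(candidates)
    pd.DataFrame({"reagent_id": candidates}).to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False
    )
    outputs["candidates"] = out_dir / "candidates.tsv"

    if stages.get("validation", True):
        val_section = dict(config.get("validation", {}))
        if "path" in val_section:
            val_table = read_screen_table(val_section["path"])
        elif truth is not None:
            sim_cfg_val = dataclasses.replace(
                sim_cfg, n_replicates=3, seed=seed + 2
            )
            val_table, _ = generate_screen(sim_cfg_val)
            keep = val_table["reagent_id"].isin(candidates) | (
                val_table["reagent_class"] == "neg_control"
            )
            val_table = val_table[keep].reset_index(drop=True)
        else:
            val_table = None
            logger.warning("no validation plates available; validation stage skipped")
        if val_table is not None and len(val_table):
            val_norm = negcontrol_normalize(val_table)
            report = validation_ttest(val_norm, candidates, control_id="neg-01")
            _write(report, out_dir / "validation.tsv")
            outputs["validation"] = out_dir / "validation.tsv"
            counts["validated"] = int(
                (report["p"] < 0.05).fillna(False).groupby(report["reagent_id"]).any().sum()
            )

    if truth is not None:
        truth.to_json(out_dir / "ground_truth.json")

    return _finalize(out_dir, config, seed, outputs, counts).parent


def _synthetic_gene_sets(genes: list[str], set_size: int = 25) -> GeneSetCollection:
    """Synthetic stand-in gene sets: deterministic chunks of the mRNA universe."""
    set_size = max(2, min(set_size, len(genes) // 2))
    sets = {}
    for i in range(0, len(genes) - set_size + 1, set_size):
        sets[f"SYNSET_{i // set_size + 1:03d}"] = set(genes[i : i + set_size])
    return GeneSetCollection(sets=sets, universe=set(genes))


def run_clinical_workflow(config: dict, out_dir) -> Path:
    """Run the cohort-association workflow and return the artifact directory.

    Stages: miRNA-mRNA Spearman correlation with BH control, pairwise stage
    comparison (skipped gracefully if stage data are absent), median-split
    Kaplan-Meier/log-rank survival per miRNA per endpoint, and gene-set
    over-representation of each miRNA's significantly correlated mRNAs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})

    cohort_section = dict(config.get("cohort", {}))
    if "path" in cohort_section:
        cohort = read_cohort(cohort_section["path"])
        truth = None
    else:
        sim = dict(cohort_section.get("simulate", {}))
        corr = tuple(tuple(c) for c in sim.pop("corr_structure", ()))
        sim_cfg = CohortSimConfig(**sim, corr_structure=corr, seed=seed)
        cohort, truth = generate_cohort(sim_cfg)

    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {"patients": len(cohort.patients)}

    correlations = mirna_mrna_correlation(
        cohort, bh_scope=config.get("bh_scope", "per_mirna")
    )
    _write(correlations, out_dir / "correlations.tsv")
    outputs["correlations"] = out_dir / "correlations.tsv"
    counts["significant_correlations"] = int(correlations["significant"].sum())

    if "stage" in cohort.patients.columns:
        stage_table = stage_comparison(cohort, min_group=int(config.get("min_stage_group", 5)))
        _write(stage_table, out_dir / "stage_tests.tsv")
        outputs["stage_tests"] = out_dir / "stage_tests.tsv"
    else:
        logger.warning("cohort has no stage column; stage comparison skipped")

    survival_rows = []
    for endpoint in config.get("endpoints", ["os", "bcss"]):
        for mir in cohort.mirna.columns:
            res = median_split_survival(cohort, mir, endpoint=endpoint)
            survival_rows.append(
                {"mirna": mir, "endpoint": endpoint, "n_high": res.n_high,
                 "n_low": res.n_low, "chi2": res.chi2, "p": res.p}
            )
    survival = pd.DataFrame.from_records(survival_rows)
    _write(survival, out_dir / "survival.tsv")
    outputs["survival"] = out_dir / "survival.tsv"

    if stages.get("enrichment", True):
        if "gmt" in config:
            collection = read_gmt(config["gmt"])
        else:
            collection = _synthetic_gene_sets(sorted(cohort.mrna.columns))
        enrich_rows = []
        for mir in cohort.mirna.columns:
            sig = correlations[
                (correlations["mirna"] == mir) & correlations["significant"]
            ]["mrna"].tolist()
            if not sig:
                continue
            table = overrepresentation(sig, collection, universe=set(cohort.mrna.columns))
            table.insert(0, "mirna", mir)
            enrich_rows.append(table)
        enrichment = (
            pd.concat(enrich_rows, ignore_index=True)
            if enrich_rows
            else pd.DataFrame(columns=["mirna", "set", "set_size", "overlap", "p", "p_adj", "significant"])
        )
        _write(enrichment, out_dir / "enrichment.tsv")
        outputs["enrichment"] = out_dir / "enrichment.tsv"

    if truth is not None:
        truth.to_json(out_dir / "ground_truth.json")

    return _finalize(out_dir, config, seed, outputs, counts).parent
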