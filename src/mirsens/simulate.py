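"""Synthetic data generators for the sensitization-screen pipeline.

Every downstream stage (plate normalization, outlier hit calling, lysate-array
protein hits, differential miRNA expression, clinical association) can be
exercised on data from this module, with a :class:`GroundTruth` record of the
effects that were spiked in, so recovery and calibration are testable without
any external dataset.

The screen generator emulates an arrayed viability screen: a library of miRNA
mimics and inhibitors printed across 384-well plates together with negative
(scrambled) and positive (cell-death) control wells, one plate set per
(cell line, treatment arm). Signal is CellTiter-Glo-style luminescence,
modeled multiplicatively: additive effects on the log2 scale for drug main
effects, smooth plate-position bias, spiked sensitizer effects, and Gaussian
noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeSpec",
    "ScreenSimConfig",
    "CohortSimConfig",
    "GroundTruth",
    "ExpressionPanel",
    "Cohort",
    "generate_screen",
    "generate_lma",
    "generate_expression_panel",
    "generate_cohort",
    "DEFAULT_ARMS",
    "DEFAULT_DRUG_EFFECTS",
    "LMA_MARKERS",
]

#: Treatment arms of the screen; "vehicle" is the no-drug arm.
DEFAULT_ARMS = ("vehicle", "trastuzumab", "lapatinib", "combination")

#: Default per-arm additive log2 viability shifts. The single-agent effects
#: correspond to 4% (trastuzumab), 17% (lapatinib) and 33% (combination)
#: viability reductions relative to vehicle.
DEFAULT_DRUG_EFFECTS = {
    "vehicle": 0.0,
    "trastuzumab": math.log2(0.96),
    "lapatinib": math.log2(0.83),
    "combination": math.log2(0.67),
}

#: Protein markers measured on the lysate microarrays.
LMA_MARKERS = (
    "AKT",
    "pAKT",
    "ERK",
    "pERK",
    "cPARP",
    "KI67",
    "HER2",
    "pHER2-Y1222",
    "pHER2-Y877",
)

_PLATE_GEOMETRY = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SpikeSpec:
    """A causal sensitizer effect planted in the screen.

    Parameters
    ----------
    reagent_id:
        Library reagent carrying the effect; must exist in the generated
        library.
    reagent_class:
        ``"mimic"`` or ``"inhibitor"``.
    cell_lines:
        Cell lines in which the effect applies; ``None`` means all.
    arms:
        Treatment arms in which the effect applies; ``None`` means all
        drug-containing arms.
    effect_log2:
        Additive log2 viability shift; negative for sensitizers.
    also_toxic_without_drug:
        If true, the same effect is applied in the no-drug arm as well, which
        should disqualify the reagent under the no-drug exclusion criterion.
    targets_expressed_mirna:
        Inhibitors only: whether the inhibited miRNA is endogenously expressed
        in the untreated cells. Inhibitors of unexpressed miRNAs are excluded
        downstream.
    """

    reagent_id: str
    reagent_class: str = "mimic"
    cell_lines: tuple[str, ...] | None = None
    arms: tuple[str, ...] | None = None
    effect_log2: float = -1.0
    also_toxic_without_drug: bool = False
    targets_expressed_mirna: bool = True


@dataclass
class ScreenSimConfig:
    """Configuration of the simulated arrayed viability screen."""

    n_mimics: int = 810
    n_inhibitors: int = 816
    cell_lines: tuple[str, ...] = ("KPL4", "SUM190PT")
    arms: tuple[str, ...] = DEFAULT_ARMS
    no_drug_arm: str = "vehicle"
    plate_size: int = 384
    n_neg_controls: int = 8
    n_pos_controls: int = 8
    baseline_log2: float = 20.0
    drug_effect_log2: Mapping[str, float] | None = None
    spatial_gradient_log2: float = 0.3
    bowl_log2: float = 0.0
    noise_sd_log2: float = 0.15
    n_replicates: int = 1
    spikes: tuple[SpikeSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drug_effect_log2 is None:
            self.drug_effect_log2 = {
                arm: DEFAULT_DRUG_EFFECTS.get(arm, 0.0) for arm in self.arms
            }
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.noise_sd_log2 <= 0:
            raise ConfigError("noise_sd_log2 must be > 0")
        if self.no_drug_arm not in self.arms:
            raise ConfigError(
                f"no-drug arm {self.no_drug_arm!r} missing from arms {self.arms}"
            )
        if self.plate_capacity <= 0:
            raise ConfigError(
                "plate capacity exceeded: "
                f"{self.n_neg_controls + self.n_pos_controls} control wells "
                f"do not fit a {self.plate_size}-well plate"
            )
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    @property
    def drug_arms(self) -> tuple[str, ...]:
        return tuple(a for a in self.arms if a != self.no_drug_arm)

    @property
    def plate_capacity(self) -> int:
        """Library wells available per plate after control wells."""
        return self.plate_size - self.n_neg_controls - self.n_pos_controls

    @property
    def n_library(self) -> int:
        return self.n_mimics + self.n_inhibitors

    def library_ids(self) -> tuple[list[str], list[str]]:
        mimics = [f"mimic-{i + 1:04d}" for i in range(self.n_mimics)]
        inhibitors = [f"inhib-{i + 1:04d}" for i in range(self.n_inhibitors)]
        return mimics, inhibitors


@dataclass
class CohortSimConfig:
    """Configuration of a simulated clinical cohort.

    miRNA and mRNA expression are drawn from a one-factor Gaussian copula so
    that requested Spearman correlations are achieved exactly in expectation
    (Pearson latent r = 2*sin(pi*rho/6)); survival is exponential with
    proportional hazards on miRNA expression, with optional competing
    other-cause death and independent exponential censoring.
    """

    n_patients: int = 377
    n_mirnas: int = 6
    n_mrnas: int = 500
    stage_probs: tuple[float, ...] = (0.025, 0.35, 0.40, 0.20, 0.025)
    corr_structure: tuple[tuple[str, str, float], ...] = ()
    stage_effects: Mapping[str, float] = field(default_factory=dict)
    hazard_log_hr: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01
    other_death_hazard: float = 0.002
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not math.isclose(sum(self.stage_probs), 1.0, abs_tol=1e-9):
            raise ConfigError("stage_probs must sum to 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        seen: set[str] = set()
        for mirna, mrna, rho in self.corr_structure:
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"Spearman rho {rho} outside [-1, 1]")
            r = 2.0 * math.sin(math.pi * rho / 6.0)
            if abs(r) >= 1.0 - 1e-9:
                raise ConfigError(
                    f"correlation structure not positive semidefinite for rho={rho}"
                )
            if mrna in seen:
                raise ConfigError(f"mRNA {mrna} appears twice in corr_structure")
            seen.add(mrna)

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirnas)]

    def mrna_ids(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_mrnas)]


@dataclass
class GroundTruth:
    """Record of the effects a generator planted, for recovery testing.

    ``spiked_sensitizers`` holds one dict per spike (reagent, class, cell
    lines, arms, effect, toxicity and expression flags); ``differential_probes``
    the probes given a treatment shift; ``correlated_pairs`` the
    (miRNA, mRNA, rho) triples; ``prognostic_mirnas`` the miRNAs with a nonzero
    log hazard ratio; ``lma_effects`` the (condition, marker, shift) triples.
    """

    spiked_sensitizers: list[dict] = field(default_factory=list)
    differential_probes: list[dict] = field(default_factory=list)
    correlated_pairs: list[dict] = field(default_factory=list)
    prognostic_mirnas: list[dict] = field(default_factory=list)
    lma_effects: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class ExpressionPanel:
    """A probe x sample log2 expression matrix with detection calls.

    ``values`` and ``detected`` share index (probes) and columns (samples);
    ``samples`` is indexed by sample id with columns ``cell_line``, ``arm``
    and ``responder_class``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not (
            self.values.columns.equals(self.detected.columns)
        ):
            raise ValueError("values and detected must share probes and samples")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples table missing metadata for {list(missing)}")


@dataclass
class Cohort:
    """Patient-level clinical table plus expression matrices.

    ``patients`` is indexed by patient id with columns ``stage``,
    ``time_months``, ``event`` (1 = death) and ``cause`` ("disease", "other"
    or "" for censored); ``mirna`` and ``mrna`` are patients x features.
    """

    patients: pd.DataFrame
    mirna: pd.DataFrame
    mrna: pd.DataFrame


# ---------------------------------------------------------------------------
# screen generator
# ---------------------------------------------------------------------------


def _plate_geometry(plate_size: int) -> tuple[int, int]:
    if plate_size in _PLATE_GEOMETRY:
        return _PLATE_GEOMETRY[plate_size]
    rows = max(1, int(math.sqrt(plate_size / 1.5)))
    cols = math.ceil(plate_size / rows)
    return rows, cols


def _spatial_surface(rows: np.ndarray, cols: np.ndarray, n_rows: int, n_cols: int,
                     gradient: float, bowl: float) -> np.ndarray:
    """Linear row + column gradients plus an optional radial bowl, all in log2."""
    r = rows / max(n_rows - 1, 1) - 0.5
    c = cols / max(n_cols - 1, 1) - 0.5
    surface = gradient * (r + c)
    if bowl:
        surface = surface + bowl * (r**2 + c**2) / 0.5
    return surface


def _plate_layout(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Static well layout shared by every (cell line, arm, replicate) plate set.

    Library reagents are placed in a seed-determined shuffled order (printed
    library position is unrelated to reagent identity, so reagents with
    related ids must not cluster spatially); control wells are clustered at
    the end of each plate (as in printed library plates), which is why the
    loess surface is fitted on library wells only downstream.
    """
    mimics, inhibitors = cfg.library_ids()
    library = [(rid, "mimic") for rid in mimics] + [
        (rid, "inhibitor") for rid in inhibitors
    ]
    layout_rng = np.random.default_rng((cfg.seed, 0x1A))
    layout_rng.shuffle(library)
    n_rows, n_cols = _plate_geometry(cfg.plate_size)
    n_plates = math.ceil(len(library) / cfg.plate_capacity)
    records = []
    for p in range(n_plates):
        chunk = library[p * cfg.plate_capacity : (p + 1) * cfg.plate_capacity]
        wells: list[tuple[str, str]] = list(chunk)
        wells += [(f"neg-{i + 1:02d}", "neg_control") for i in range(cfg.n_neg_controls)]
        wells += [(f"pos-{i + 1:02d}", "pos_control") for i in range(cfg.n_pos_controls)]
        wells += [("", "empty")] * (cfg.plate_size - len(wells))
        for idx, (rid, rclass) in enumerate(wells):
            records.append(
                (p + 1, idx // n_cols, idx % n_cols, rid, rclass)
            )
    return pd.DataFrame(
        records, columns=["plate_num", "row", "col", "reagent_id", "reagent_class"]
    )


def _spike_lookup(cfg: ScreenSimConfig) -> dict[tuple[str, str, str], float]:
    mimics, inhibitors = cfg.library_ids()
    known = set(mimics) | set(inhibitors)
    table: dict[tuple[str, str, str], float] = {}
    for spike in cfg.spikes:
        if spike.reagent_id not in known:
            raise ConfigError(f"spiked reagent {spike.reagent_id!r} not in library")
        lines = spike.cell_lines if spike.cell_lines is not None else cfg.cell_lines
        arms = spike.arms if spike.arms is not None else cfg.drug_arms
        if spike.also_toxic_without_drug:
            arms = tuple(arms) + (cfg.no_drug_arm,)
        for line in lines:
            for arm in arms:
                key = (spike.reagent_id, line, arm)
                table[key] = table.get(key, 0.0) + spike.effect_log2
    return table


def generate_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the arrayed viability screen.

    Returns a well-level table (one row per well of every plate of every
    (cell line, arm, replicate) combination) and the ground truth of spiked
    sensitizer effects. Raw luminescence is
    ``2 ** (baseline + drug effect + spatial surface + spike effect + noise)``;
    negative-control and empty wells carry no reagent effect and positive
    (cell-death) controls are forced near background.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _plate_layout(cfg)
    spikes = _spike_lookup(cfg)
    n_rows, n_cols = _plate_geometry(cfg.plate_size)
    surface = _spatial_surface(
        layout["row"].to_numpy(),
        layout["col"].to_numpy(),
        n_rows,
        n_cols,
        cfg.spatial_gradient_log2,
        cfg.bowl_log2,
    )
    pos_level = cfg.baseline_log2 - 7.0  # death control: ~1% of baseline signal

    frames = []
    for line in cfg.cell_lines:
        for arm in cfg.arms:
            for rep in range(1, cfg.n_replicates + 1):
                block = layout.copy()
                log2sig = np.full(len(block), cfg.baseline_log2)
                log2sig += float(cfg.drug_effect_log2.get(arm, 0.0))
                log2sig += surface
                is_pos = (block["reagent_class"] == "pos_control").to_numpy()
                log2sig[is_pos] = pos_level + surface[is_pos]
                if spikes:
                    eff = np.array(
                        [
                            spikes.get((rid, line, arm), 0.0)
                            for rid in block["reagent_id"]
                        ]
                    )
                    log2sig += eff
                log2sig += rng.normal(0.0, cfg.noise_sd_log2, size=len(block))
                block["plate_id"] = [
                    f"{line}|{arm}|rep{rep}|p{p}" for p in block["plate_num"]
                ]
                block["cell_line"] = line
                block["arm"] = arm
                block["replicate"] = rep
                block["raw_signal"] = np.exp2(log2sig)
                frames.append(block)
    table = pd.concat(frames, ignore_index=True)[
        [
            "plate_id",
            "row",
            "col",
            "reagent_id",
            "reagent_class",
            "cell_line",
            "arm",
            "replicate",
            "raw_signal",
        ]
    ]
    truth = GroundTruth(
        spiked_sensitizers=[dataclasses.asdict(s) for s in cfg.spikes]
    )
    return table, truth


# ---------------------------------------------------------------------------
# lysate microarray generator
# ---------------------------------------------------------------------------


def generate_lma(
    cfg: ScreenSimConfig,
    markers: Sequence[str] = LMA_MARKERS,
    n_conditions: int | None = None,
    effects: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate lysate-microarray spots for reagent x arm x cell-line conditions.

    Each spot has an antibody ``raw`` intensity and a total-protein ``sypro``
    reference intensity; the reference enters multiplicatively, so
    ``log2(raw/sypro)`` is Gaussian per marker under the null. ``effects``
    maps ``(condition_id, marker)`` to an additive log2 shift and is recorded
    in the returned ground truth.
    """
    if not markers:
        raise ValueError("markers must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    mimics, inhibitors = cfg.library_ids()
    base_conditions = [
        f"{rid}|{arm}|{line}"
        for line in cfg.cell_lines
        for arm in cfg.arms
        for rid in (mimics + inhibitors)
    ]
    if n_conditions is None:
        conditions = base_conditions
    elif n_conditions <= len(base_conditions):
        conditions = base_conditions[:n_conditions]
    else:
        reps = math.ceil(n_conditions / len(base_conditions))
        conditions = (base_conditions * reps)[:n_conditions]
        conditions = [f"{c}|{i}" for i, c in enumerate(conditions)]
    effects = dict(effects or {})

    marker_mu = {m: rng.normal(2.0, 0.5) for m in markers}
    records = []
    for cond in conditions:
        parts = cond.split("|")
        line = parts[2] if len(parts) > 2 else ""
        arm = parts[1] if len(parts) > 1 else ""
        sypro_log2 = rng.normal(14.0, 0.3)
        for marker in markers:
            shift = effects.get((cond, marker), 0.0)
            ratio_log2 = marker_mu[marker] + shift + rng.normal(0.0, 0.5)
            records.append(
                (cond, line, arm, marker, np.exp2(sypro_log2 + ratio_log2),
                 np.exp2(sypro_log2))
            )
    table = pd.DataFrame(
        records,
        columns=["condition", "cell_line", "arm", "protein", "raw", "sypro"],
    )
    truth = GroundTruth(
        lma_effects=[
            {"condition": c, "marker": m, "shift_log2": v}
            for (c, m), v in effects.items()
        ]
    )
    return table, truth


# ---------------------------------------------------------------------------
# expression panel generator
# ---------------------------------------------------------------------------

_DEFAULT_RESPONDER_CLASS = {
    "SKBR3": "responsive",
    "BT-474": "responsive",
    "KPL4": "poor",
    "SUM190PT": "poor",
}


def generate_expression_panel(
    cell_lines: Sequence[str] = ("SKBR3", "BT-474", "KPL4", "SUM190PT"),
    arms: Sequence[str] = DEFAULT_ARMS,
    n_probes: int = 200,
    effects: Iterable[tuple[str, str, str, float]] = (),
    seed: int = 0,
    n_replicates: int = 1,
    responder_classes: Mapping[str, str] | None = None,
    frac_unexpressed: float = 0.15,
    detect_prob: float = 0.97,
    noise_sd: float = 0.5,
) -> tuple[ExpressionPanel, GroundTruth]:
    """Simulate a one-color miRNA microarray panel across treatment arms.

    ``effects`` is an iterable of ``(probe_id, responder_class, arm, shift)``:
    the probe is shifted by ``shift`` log2 units in samples of the given arm
    within cell lines of the given responder class (``"all"`` matches every
    class). A ``frac_unexpressed`` fraction of probes is flagged undetected in
    every sample, emulating features below the array's detection call.
    """
    rng = np.random.default_rng(seed)
    responder_classes = dict(responder_classes or _DEFAULT_RESPONDER_CLASS)
    probes = [f"probe-{i + 1:04d}" for i in range(n_probes)]
    sample_meta = []
    for line in cell_lines:
        for arm in arms:
            for rep in range(1, n_replicates + 1):
                sid = f"{line}|{arm}|r{rep}"
                sample_meta.append(
                    (sid, line, arm, responder_classes.get(line, "responsive"))
                )
    samples = pd.DataFrame(
        sample_meta, columns=["sample_id", "cell_line", "arm", "responder_class"]
    ).set_index("sample_id")

    n_unexpressed = int(round(frac_unexpressed * n_probes))
    unexpressed = set(probes[:n_unexpressed])
    probe_mu = rng.uniform(6.0, 12.0, size=n_probes)

    effect_map: dict[tuple[str, str, str], float] = {}
    truth_entries = []
    for probe, rclass, arm, shift in effects:
        effect_map[(probe, rclass, arm)] = effect_map.get((probe, rclass, arm), 0.0) + shift
        truth_entries.append(
            {"probe": probe, "responder_class": rclass, "arm": arm, "shift": shift}
        )

    values = np.empty((n_probes, len(samples)))
    detected = np.empty((n_probes, len(samples)), dtype=bool)
    for j, (sid, meta) in enumerate(samples.iterrows()):
        shifts = np.zeros(n_probes)
        for i, probe in enumerate(probes):
            for rclass in (meta["responder_class"], "all"):
                shifts[i] += effect_map.get((probe, rclass, meta["arm"]), 0.0)
        col = probe_mu + shifts + rng.normal(0.0, noise_sd, size=n_probes)
        det = rng.random(n_probes) < detect_prob
        for i, probe in enumerate(probes):
            if probe in unexpressed:
                det[i] = False
                col[i] = rng.normal(2.0, 0.3)  # background-level feature
        values[:, j] = col
        detected[:, j] = det

    panel = ExpressionPanel(
        values=pd.DataFrame(values, index=probes, columns=samples.index),
        detected=pd.DataFrame(detected, index=probes, columns=samples.index),
        samples=samples,
    )
    return panel, GroundTruth(differential_probes=truth_entries)


# ---------------------------------------------------------------------------
# clinical cohort generator
# ---------------------------------------------------------------------------


def generate_cohort(cfg: CohortSimConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a clinical cohort with stage, expression, and survival.

    Expression follows a one-factor Gaussian copula: each mRNA listed in
    ``corr_structure`` is tied to its miRNA at latent Pearson
    ``r = 2*sin(pi*rho/6)`` so the marginal Spearman correlation equals the
    requested ``rho``. Stage effects shift miRNA expression monotonically with
    stage; disease-death hazard is ``baseline * exp(sum log_hr * expr)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    mirna_ids = cfg.mirna_ids()
    mrna_ids = cfg.mrna_ids()
    patients = [f"pt-{i + 1:04d}" for i in range(n)]

    mirna = pd.DataFrame(
        rng.standard_normal((n, len(mirna_ids))), index=patients, columns=mirna_ids
    )
    mrna = pd.DataFrame(
        rng.standard_normal((n, len(mrna_ids))), index=patients, columns=mrna_ids
    )
    corr_truth = []
    for mir, gene, rho in cfg.corr_structure:
        if mir not in mirna.columns:
            raise ConfigError(f"unknown miRNA {mir!r} in corr_structure")
        if gene not in mrna.columns:
            raise ConfigError(f"unknown mRNA {gene!r} in corr_structure")
        r = 2.0 * math.sin(math.pi * rho / 6.0)
        z = mirna[mir].to_numpy()
        mrna[gene] = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
        corr_truth.append({"mirna": mir, "mrna": gene, "rho": rho})

    stage = rng.choice(len(cfg.stage_probs), size=n, p=np.asarray(cfg.stage_probs))
    for mir, coef in cfg.stage_effects.items():
        mirna[mir] = mirna[mir] + coef * stage

    log_hr = np.zeros(len(mirna_ids))
    prog_truth = []
    for k, mir in enumerate(mirna_ids):
        if mir in cfg.hazard_log_hr and cfg.hazard_log_hr[mir] != 0.0:
            log_hr[k] = cfg.hazard_log_hr[mir]
            prog_truth.append({"mirna": mir, "log_hr": float(log_hr[k])})

    lin = mirna.to_numpy() @ log_hr
    disease_rate = cfg.baseline_hazard * np.exp(lin)
    t_disease = rng.exponential(1.0 / disease_rate)
    if cfg.other_death_hazard > 0:
        t_other = rng.exponential(1.0 / cfg.other_death_hazard, size=n)
    else:
        t_other = np.full(n, np.inf)
    if cfg.censor_rate > 0:
        # exponential censoring with rate matched to the target censored
        # fraction under the average event hazard (approximate for nonzero
        # covariate effects)
        event_rate = float(np.mean(disease_rate)) + cfg.other_death_hazard
        c_rate = cfg.censor_rate / (1.0 - cfg.censor_rate) * event_rate
        t_censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)

    time = np.minimum.reduce([t_disease, t_other, t_censor])
    event = (time < t_censor).astype(int)
    cause = np.where(event == 0, "", np.where(t_disease <= t_other, "disease", "other"))

    patients_df = pd.DataFrame(
        {
            "stage": stage,
            "time_months": np.maximum(time, 1e-6),
            "event": event,
            "cause": cause,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    cohort = Cohort(patients=patients_df, mirna=mirna, mrna=mrna)
    truth = GroundTruth(correlated_pairs=corr_truth, prognostic_mirnas=prog_truth)
    return cohort, truth
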