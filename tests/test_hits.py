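"""Sensitizer calling, exclusion criteria, candidates, validation t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirsens import (
    apply_exclusions,
    call_sensitizers,
    expressed_mirnas,
    generate_expression_panel,
    group_stats,
    select_candidates,
    validation_ttest,
)
from mirsens.hits import significance_stars
from ._oracles import brute_force_hits
from .conftest import random_well_table


def table_from_values(values, cell_line="KPL4", arm="lapatinib",
                      reagent_class="mimic", prefix="r"):
    n = len(values)
    return pd.DataFrame(
        {
            "plate_id": f"{cell_line}|{arm}",
            "row": np.arange(n) // 24,
            "col": np.arange(n) % 24,
            "reagent_id": [f"{prefix}{i:04d}" for i in range(n)],
            "reagent_class": reagent_class,
            "cell_line": cell_line,
            "arm": arm,
            "raw_signal": 1.0,
            "normalized_viability": np.asarray(values, dtype=float),
        }
    )


class TestGroupStats:
    def test_hand_computed_median_and_sd(self):
        stats = group_stats(table_from_values([1, 2, 3, 4, 5]))
        assert stats.loc[0, "median"] == 3
        assert np.isclose(stats.loc[0, "sd"], 1.5811, atol=1e-4)

    def test_constant_group_degenerate(self):
        stats = group_stats(table_from_values([2.0] * 20))
        assert stats.loc[0, "sd"] == 0
        assert bool(stats.loc[0, "degenerate"])

    def test_controls_excluded_from_reagent_count(self):
        lib = table_from_values(np.arange(20))
        controls = table_from_values([5.0] * 4, prefix="neg")
        controls["reagent_class"] = "neg_control"
        controls["row"] = 10
        stats = group_stats(pd.concat([lib, controls], ignore_index=True))
        assert stats.loc[0, "n_reagents"] == 20

    def test_low_n_flagged(self):
        stats = group_stats(table_from_values([1, 2, 3]))
        assert bool(stats.loc[0, "low_n"])

    def test_mad_option_robust_to_outlier(self):
        values = list(np.zeros(99)) + [-50.0]
        sd_classic = group_stats(table_from_values(values)).loc[0, "sd"]
        sd_robust = group_stats(table_from_values(values), robust=True).loc[0, "sd"]
        assert sd_robust < sd_classic / 10


class TestCallSensitizers:
    def test_value_exactly_at_threshold_not_flagged(self):
        table = table_from_values([0.0, -3.0, -2.999, -3.001])
        stats = pd.DataFrame(
            [{"cell_line": "KPL4", "arm": "lapatinib", "n_reagents": 4,
              "median": 0.0, "sd": 1.0, "low_n": False, "degenerate": False}]
        )
        hits = call_sensitizers(table, stats, k=3.0).set_index("reagent_id")
        assert not hits.loc["r0001", "sensitizer"]  # exactly -3 SD
        assert not hits.loc["r0002", "sensitizer"]
        assert hits.loc["r0003", "sensitizer"]

    def test_constructed_outlier_recovered_with_stats_including_it(self):
        """One well placed exactly 4 SD below the median, where median and SD
        are recomputed including the outlier itself (fixed-point search)."""
        rng = np.random.default_rng(42)
        base = rng.normal(0, 1, 199)
        x = -4.0
        for _ in range(200):
            values = np.append(base, x)
            x_new = np.median(values) - 4.0 * np.std(values, ddof=1)
            if abs(x_new - x) < 1e-12:
                break
            x = x_new
        values = np.append(base, x)
        dev = (x - np.median(values)) / np.std(values, ddof=1)
        assert np.isclose(dev, -4.0, atol=1e-9)
        table = table_from_values(values)
        hits = call_sensitizers(table, group_stats(table), k=3.0)
        flagged = hits[hits.sensitizer].reagent_id.tolist()
        assert flagged == [f"r{199:04d}"]

    def test_no_flags_in_no_drug_arm(self):
        table = table_from_values([0.0] * 50 + [-10.0], arm="vehicle")
        hits = call_sensitizers(table, group_stats(table))
        assert not hits.sensitizer.any()

    def test_degenerate_group_yields_no_flags(self):
        table = table_from_values([1.0] * 30)
        hits = call_sensitizers(table, group_stats(table))
        assert not hits.sensitizer.any()

    def test_missing_group_stats_error_names_group(self):
        table = table_from_values([1, 2, 3])
        stats = group_stats(table_from_values([1, 2, 3], arm="combination"))
        with pytest.raises(KeyError, match="lapatinib"):
            call_sensitizers(table, stats)

    def test_null_gaussian_tail_rate(self):
        rng = np.random.default_rng(0)
        table = table_from_values(rng.normal(0, 1, 10_000))
        hits = call_sensitizers(table, group_stats(table))
        frac = hits.sensitizer.mean()
        assert 0.0005 <= frac <= 0.0035

    def test_replicates_averaged_before_call(self):
        single = table_from_values(np.linspace(-4, 4, 100))
        shifted = single.assign(
            row=99, normalized_viability=single.normalized_viability + 0.2
        )
        dup = pd.concat([single, shifted], ignore_index=True)
        hits = call_sensitizers(dup, group_stats(dup))
        assert len(hits) == 100  # one row per (reagent, cell line, arm)
        assert np.allclose(
            hits.sort_values("reagent_id").normalized_viability,
            single.normalized_viability + 0.1,
        )


class TestExclusions:
    def make_hits(self):
        drug = table_from_values([0.0] * 50 + [-5.0, -4.0], arm="lapatinib")
        drug.iloc[-1, drug.columns.get_loc("reagent_class")] = "inhibitor"
        nodrug = table_from_values([0.0] * 50 + [-5.0, 0.0], arm="vehicle")
        nodrug.iloc[-1, nodrug.columns.get_loc("reagent_class")] = "inhibitor"
        table = pd.concat([drug, nodrug], ignore_index=True)
        return call_sensitizers(table, group_stats(table))

    def test_no_drug_toxicity_excluded_with_reason(self):
        hits = self.make_hits()
        assert hits.set_index(["reagent_id", "arm"]).loc[("r0050", "lapatinib"), "sensitizer"]
        out = apply_exclusions(hits)
        row = out.set_index(["reagent_id", "arm"]).loc[("r0050", "lapatinib")]
        assert not row.sensitizer
        assert row.excluded_no_drug_effect
        assert row.exclusion_reason == "no_drug_effect"

    def test_inhibitor_of_unexpressed_target_excluded(self):
        hits = self.make_hits()
        out = apply_exclusions(hits, expressed={"KPL4": set()})
        row = out.set_index(["reagent_id", "arm"]).loc[("r0051", "lapatinib")]
        assert not row.sensitizer
        assert row.exclusion_reason == "target_not_expressed"

    def test_mimic_never_excluded_for_expression(self):
        drug = table_from_values([0.0] * 50 + [-5.0], arm="lapatinib")
        table = pd.concat(
            [drug, table_from_values([0.0] * 51, arm="vehicle")], ignore_index=True
        )
        hits = call_sensitizers(table, group_stats(table))
        out = apply_exclusions(hits, expressed={"KPL4": set()})
        assert out.set_index(["reagent_id", "arm"]).loc[("r0050", "lapatinib"), "sensitizer"]

    def test_unmapped_inhibitor_retained_with_warning(self, caplog):
        hits = self.make_hits()
        with caplog.at_level("WARNING", logger="mirsens"):
            out = apply_exclusions(
                hits, expressed={"KPL4": set()}, inhibitor_targets={}
            )
        assert out.set_index(["reagent_id", "arm"]).loc[("r0051", "lapatinib"), "sensitizer"]
        assert "no mappable target" in caplog.text

    def test_exclusion_is_per_cell_line(self):
        """Toxicity without drug in one cell line leaves the other intact."""
        parts = []
        for line in ("KPL4", "SUM190PT"):
            parts.append(table_from_values([0.0] * 50 + [-5.0], cell_line=line,
                                           arm="lapatinib"))
            veh = [0.0] * 50 + ([-5.0] if line == "KPL4" else [0.0])
            parts.append(table_from_values(veh, cell_line=line, arm="vehicle"))
        table = pd.concat(parts, ignore_index=True)
        out = apply_exclusions(call_sensitizers(table, group_stats(table)))
        keyed = out.set_index(["reagent_id", "cell_line", "arm"])
        assert not keyed.loc[("r0050", "KPL4", "lapatinib"), "sensitizer"]
        assert keyed.loc[("r0050", "SUM190PT", "lapatinib"), "sensitizer"]

    def test_expressed_mirnas_uses_flags_and_floor(self):
        panel, _ = generate_expression_panel(
            cell_lines=("KPL4",), n_probes=20, seed=8, frac_unexpressed=0.5
        )
        by_flag = expressed_mirnas(panel)
        everything = expressed_mirnas(panel, floor=-np.inf)
        assert by_flag["KPL4"] < everything["KPL4"]
        assert everything["KPL4"] == set(panel.values.index)


class TestSelectCandidates:
    @pytest.mark.parametrize(
        "contexts, expected",
        [
            ([("KPL4", "lapatinib"), ("KPL4", "combination")], True),
            ([("KPL4", "lapatinib"), ("SUM190PT", "lapatinib")], True),
            ([("KPL4", "lapatinib")], False),
        ],
    )
    def test_multi_context_rule(self, contexts, expected):
        parts = []
        for line in ("KPL4", "SUM190PT"):
            for arm in ("vehicle", "lapatinib", "combination"):
                values = [0.0] * 50 + [-5.0 if (line, arm) in contexts else 0.0]
                parts.append(table_from_values(values, cell_line=line, arm=arm))
        table = pd.concat(parts, ignore_index=True)
        out = select_candidates(call_sensitizers(table, group_stats(table)))
        assert out[out.reagent_id == "r0050"].candidate.all() == expected


class TestValidationTtest:
    def make_validation_table(self, candidate, control):
        rows = []
        for i, v in enumerate(candidate):
            rows.append(dict(reagent_id="cand", arm="lapatinib", replicate=i,
                             normalized_viability=v))
        for i, v in enumerate(control):
            rows.append(dict(reagent_id="neg", arm="lapatinib", replicate=i,
                             normalized_viability=v))
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one(self):
        table = self.make_validation_table([0.9, 0.95, 1.0], [0.9, 0.95, 1.0])
        report = validation_ttest(table, ["cand"], "neg")
        assert np.isclose(report.loc[0, "p"], 1.0, atol=1e-9)

    def test_strong_separation_below_point_001(self):
        table = self.make_validation_table([0.2, 0.25, 0.3], [0.9, 0.95, 1.0])
        report = validation_ttest(table, ["cand"], "neg")
        # closed form: pooled SD 0.05, t = -0.7 / (0.05*sqrt(2/3)), df = 4
        t = -0.7 / (0.05 * np.sqrt(2 / 3))
        expected = 2 * sps.t.sf(abs(t), df=4)
        assert np.isclose(report.loc[0, "p"], expected, rtol=1e-9)
        assert report.loc[0, "p"] < 0.001
        assert report.loc[0, "stars"] == "***"

    def test_single_replicate_gives_missing_p(self):
        table = self.make_validation_table([0.5], [0.9, 1.0])
        report = validation_ttest(table, ["cand"], "neg")
        assert np.isnan(report.loc[0, "p"])

    @pytest.mark.parametrize(
        "p, stars",
        [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.2, ""), (np.nan, "")],
    )
    def test_star_tiers(self, p, stars):
        assert significance_stars(p) == stars


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_tables(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = random_well_table(rng)
            expressed = None
            targets = None
            if rng.random() < 0.5:
                probes = [f"r{i:03d}" for i in range(0, 200, 2)]
                expressed = {line: set(probes) for line in table.cell_line.unique()}
                targets = {rid: rid for rid in
                           table[table.reagent_class == "inhibitor"].reagent_id.unique()
                           if rng.random() < 0.9}
            hits = call_sensitizers(table, group_stats(table, min_reagents=2))
            hits = apply_exclusions(hits, expressed=expressed, inhibitor_targets=targets)
            expected = brute_force_hits(
                table.to_dict("records"), expressed=expressed,
                inhibitor_targets=targets,
            )
            actual = {
                (r.reagent_id, r.cell_line, r.arm): bool(r.sensitizer)
                for r in hits.itertuples()
            }
            assert actual == expected
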