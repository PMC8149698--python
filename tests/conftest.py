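import numpy as np
import pandas as pd
import pytest

from mirsens import ScreenSimConfig


@pytest.fixture
def small_screen_config():
    """A one-plate screen small enough for fast unit tests."""
    return ScreenSimConfig(
        n_mimics=60,
        n_inhibitors=60,
        n_neg_controls=4,
        n_pos_controls=4,
        plate_size=96,
        cell_lines=("KPL4",),
        seed=11,
    )


def random_well_table(rng: np.random.Generator, max_wells: int = 1000) -> pd.DataFrame:
    """A random normalized screen table exercising edge cases of hit calling.

    Random group sizes (sometimes tiny, sometimes constant-valued), mimics,
    inhibitors and control wells, occasional replicate wells.
    """
    cell_lines = ["KPL4", "SUM190PT"][: rng.integers(1, 3)]
    arms = ["vehicle"] + list(
        rng.choice(["trastuzumab", "lapatinib", "combination"],
                   size=rng.integers(1, 4), replace=False)
    )
    # cap so replicate wells (~10%) and controls still fit under max_wells
    per_group = max_wells // (len(cell_lines) * len(arms))
    n_reagents = int(rng.integers(5, max(6, int(per_group / 1.15) - 4)))
    n_reagents = min(n_reagents, 180)
    reagents = [
        (f"r{i:03d}", "mimic" if rng.random() < 0.5 else "inhibitor")
        for i in range(n_reagents)
    ]
    rows = []
    well = 0
    for line in cell_lines:
        for arm in arms:
            constant_group = rng.random() < 0.05
            for rid, rclass in reagents:
                for _ in range(1 + (rng.random() < 0.1)):
                    value = 0.0 if constant_group else float(rng.normal(0, 1))
                    if rng.random() < 0.02:
                        value -= float(rng.uniform(3, 8))
                    rows.append(
                        dict(plate_id=f"{line}|{arm}", row=well // 24, col=well % 24,
                             reagent_id=rid, reagent_class=rclass, cell_line=line,
                             arm=arm, raw_signal=1.0, normalized_viability=value)
                    )
                    well += 1
            for i in range(rng.integers(0, 4)):
                rows.append(
                    dict(plate_id=f"{line}|{arm}", row=well // 24, col=well % 24,
                         reagent_id=f"neg-{i}", reagent_class="neg_control",
                         cell_line=line, arm=arm, raw_signal=1.0,
                         normalized_viability=float(rng.normal(0, 1)))
                )
                well += 1
    return pd.DataFrame(rows)
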