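import numpy as np
import pandas as pd
import pytest

from cnvaccord.types import SNPMap, StateMatrix


def build_map(chrom_pos):
    """SNPMap from a list of (chrom, pos) tuples."""
    df = pd.DataFrame(chrom_pos, columns=["chrom", "pos"])
    df.insert(0, "snp_id", [f"s{i}" for i in range(len(df))])
    return SNPMap(df)


def build_states(case_rows, control_rows, cohort_id="cohort"):
    """StateMatrix from explicit per-individual state lists."""
    states = np.array(list(case_rows) + list(control_rows), dtype=np.int8)
    labels = np.array(["case"] * len(case_rows) + ["control"] * len(control_rows), dtype=object)
    return StateMatrix(states=states, labels=labels, cohort_id=cohort_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    # two chromosomes, 10 kb spacing, one 50 kb gap on chrom 1 after s2
    return build_map(
        [(1, 1_000), (1, 11_000), (1, 21_000), (1, 71_000), (1, 81_000),
         (2, 5_000), (2, 15_000), (2, 25_000), (2, 35_000), (2, 45_000)]
    )
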