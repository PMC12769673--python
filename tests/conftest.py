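import numpy as np
import pandas as pd
import pytest

import sigmascreen as sg


@pytest.fixture(scope="session")
def small_library() -> sg.GuideLibrary:
    return sg.build_library(30, 4, 6, seed=11)


@pytest.fixture(scope="session")
def two_arm_design() -> sg.ScreenDesign:
    return sg.ScreenDesign(
        conditions=("ETOH", "ACT"),
        growth_inhibition={"ACT": 0.40},
        coverage=150.0,
    )


@pytest.fixture(scope="session")
def null_screen(small_library, two_arm_design):
    truth = sg.neutral_truth(small_library, two_arm_design)
    traj = sg.simulate_passaging(small_library, truth, two_arm_design, seed=5)
    table = sg.sample_counts(traj, two_arm_design, seed=7)
    return truth, traj, table


def make_sample_sheet(conditions, n_replicates, with_t0=True) -> pd.DataFrame:
    rows = []
    if with_t0:
        for r in range(1, n_replicates + 1):
            rows.append({"sample": f"T0_R{r}", "condition": "T0",
                         "replicate": r, "timepoint": "T0"})
    for cond in conditions:
        for r in range(1, n_replicates + 1):
            rows.append({"sample": f"{cond}_R{r}", "condition": cond,
                         "replicate": r, "timepoint": "D15"})
    return pd.DataFrame(rows).set_index("sample")
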