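import numpy as np
import pandas as pd
import pytest

from tknet import AnalysisConfig, CountTable, HostTable, SampleMetadata, SimulationConfig, generate_study
from tknet.pipeline import run_pipeline


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[2.0, 4.0], [3.0, 1.0], [5.0, 5.0]],
            index=["ASV1", "ASV2", "ASV3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    rows = []
    for exp in (1, 2):
        for grp in ("ND", "WD", "WD_Ch"):
            for m in (1, 2):
                rows.append((f"E{exp}.{grp}.m{m}", exp, grp))
    return SampleMetadata(
        pd.DataFrame(
            {"experiment": [r[1] for r in rows], "group": [r[2] for r in rows]},
            index=pd.Index([r[0] for r in rows], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def default_study():
    return generate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_result(default_study):
    return run_pipeline(
        default_study, AnalysisConfig(rng_seed=0), run_diversity=True, run_null=True, null_count=200
    )
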