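import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirpipe import simulate
from mirpipe.microarray import NormalizedMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_samples(cell_lines=("A", "B"), reps=2) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{cl}_{cond}_{r}",
            "cell_line": cl,
            "condition": cond,
            "replicate": str(r),
        }
        for cl in cell_lines
        for cond in ("CON", "IK1")
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows)


def make_normalized(values: dict[str, list[float]], cell_lines=("A", "B"), reps=2):
    """Build a NormalizedMatrix from per-miRNA value lists ordered like the
    sample sheet (cell_line-major, CON before IK1)."""
    samples = make_samples(cell_lines, reps)
    df = pd.DataFrame(values, index=samples["sample_id"]).T
    return NormalizedMatrix(
        values=df, expressed=pd.Series(True, index=df.index), samples=samples
    )


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """One full synthetic scenario at default study conditions, written to
    disk once per session (seed 42)."""
    outdir = tmp_path_factory.mktemp("scenario")
    manifest = simulate.simulate_scenario(outdir, simulate.SimConfig(seed=42))
    return manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
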