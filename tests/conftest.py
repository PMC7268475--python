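import numpy as np
import pytest

from uasyield import pipeline, synthdata
from uasyield.plotgrid import FieldSpec


@pytest.fixture(scope="session")
def small_spec() -> FieldSpec:
    return FieldSpec(n_cols=4, n_rows=3, seed=7)


@pytest.fixture(scope="session")
def small_field(small_spec) -> synthdata.SyntheticField:
    return synthdata.generate_field(small_spec)


@pytest.fixture(scope="session")
def noiseless_trial() -> pipeline.PipelineResult:
    """Full-scale 840-plot study with deterministic (noise-free) yields.

    Session-scoped: the heavy end-to-end run happens once and feeds the
    parameter-recovery, ablation and sample-size tests.
    """
    spec = FieldSpec(n_cols=42, n_rows=20, seed=1)
    return pipeline.run_pipeline(spec, yield_sigma=0.0)
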