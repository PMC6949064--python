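import numpy as np
import pandas as pd
import pytest

import mrnet


@pytest.fixture(scope="session")
def default_cohort():
    """The default desk-scale study cohort: 20 TFs (10 active, delta=2),
    2000 genes, 50 targets/TF, 150 PT + 100 NT, 3 batches, noise_sd=0.7."""
    truth = mrnet.generate_ground_truth(seed=11)
    return mrnet.simulate_cohort(truth, seed=11)


@pytest.fixture(scope="session")
def default_discovery(default_cohort):
    """Full discovery run (preprocess -> signature -> network -> MRA) on the
    default cohort. Session-scoped: the planted-recovery checks share it."""
    cfg = mrnet.RunConfig(rng_seed=11)
    return mrnet.run_discovery(
        default_cohort.expression,
        default_cohort.annotation,
        default_cohort.truth.tfs,
        cfg,
    )


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(0)
    genes = [f"g{i:02d}" for i in range(30)]
    samples = [f"s{j:02d}" for j in range(20)]
    return pd.DataFrame(
        rng.normal(7, 1, (30, 20)), index=genes, columns=samples
    )
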