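import numpy as np
import pandas as pd
import pytest

import methsets as m

REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "ExonBnd")


@pytest.fixture(scope="session")
def annotation():
    return m.generate_annotation(40, probes_per_gene=8, seed=101)


@pytest.fixture(scope="session")
def small_cohort(annotation):
    cells = {("Body", "hypo"): 5, ("TSS200", "hyper"): 3}
    cfg = m.SimConfig(
        n_samples=80,
        exposure_fraction=0.3,
        n_genes=40,
        n_affected_per_region=cells,
        seed=202,
    )
    return m.generate_cohort(cfg, annotation)


@pytest.fixture()
def null_matrix():
    """Expression-like null matrix with a balanced two-group design."""
    rng = np.random.default_rng(77)
    E = pd.DataFrame(
        rng.standard_normal((60, 24)),
        index=[f"g{j}" for j in range(60)],
        columns=[f"s{j}" for j in range(24)],
    )
    grp = np.zeros(24)
    grp[:12] = 1
    X = pd.DataFrame({"Intercept": 1.0, "exposure": grp}, index=E.columns)
    return E, X
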