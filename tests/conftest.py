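import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lmsubtypes as L

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 5-subtype cohort shared by fast tests: 60 patients, 600 genes."""
    cfg = L.SimulationConfig(
        n_patients=60,
        n_genes=600,
        n_template_markers_per_subtype=30,
        mesenchymal_extra_genes=4,
        n_liver_genes=50,
        n_normal_liver=8,
        seed=42,
    )
    expr, annot, truth, sets = L.generate_cohort(cfg)
    return {"config": cfg, "expr": expr, "annot": annot, "truth": truth, "sets": sets}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return L.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
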