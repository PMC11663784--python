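import numpy as np
import pandas as pd
import pytest

from radsig.io import ExpressionMatrix, SampleTable
from radsig.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One shared synthetic study: two discovery cohorts + validation,
    strong planted signal, modest size so every stage runs in seconds."""
    cfg = SimulationConfig(
        n_genes=500,
        cohort_sizes={"discovery_a": 80, "discovery_b": 80, "validation": 70},
        n_signal_up=25,
        n_signal_down=25,
        effect_size_sd_units=1.5,
        seed=7,
    )
    return cfg, simulate_study(cfg)


@pytest.fixture()
def toy_expr():
    """3 genes x 4 samples with hand-enterable values."""
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 7.0, 7.0], [2.0, 4.0, 6.0, 8.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame)


def make_samples(sample_ids, pcr, cohort="c1", batch=None, t_stage=3, n_stage=1):
    n = len(sample_ids)
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "cohort": [cohort] * n if np.isscalar(cohort) else list(cohort),
                "batch": ([cohort] * n if np.isscalar(cohort) else list(cohort))
                if batch is None
                else (list(batch) if not np.isscalar(batch) else [batch] * n),
                "pcr": list(pcr),
                "t_stage": [t_stage] * n if np.isscalar(t_stage) else list(t_stage),
                "n_stage": [n_stage] * n if np.isscalar(n_stage) else list(n_stage),
            }
        )
    )
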