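import numpy as np
import pandas as pd
import pytest

from mb17q.cohort import ExpressionCohort
from mb17q.config import SimConfig
from mb17q.simulate import gen_expression_cohort, gen_variant_replicates


@pytest.fixture(scope="session")
def small_variant_sim():
    """A modest simulated variant cohort shared across filter tests."""
    cfg = SimConfig(
        seed=11, n_samples=40, true_variant_rate=0.5, artifact_rate=4.0
    )
    reps, pooled, truth = gen_variant_replicates(cfg)
    return cfg, reps, pooled, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """60-sample expression cohort with zero noise: folds are exact."""
    cfg = SimConfig(
        seed=5, n_samples=60, i17q_fraction=0.5, noise_sd=0.0, n_features=300,
        n_chr17_features=120,
    )
    return cfg, gen_expression_cohort(cfg)


@pytest.fixture()
def random_cohort():
    """A fully random 20x10 cohort with hand-set metadata for oracle checks."""
    rng = np.random.default_rng(42)
    features = [f"f{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(10)]
    matrix = pd.DataFrame(
        rng.normal(7, 2, (20, 10)), index=features, columns=samples
    )
    feature_meta = pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(20)],
            "chrom": ["chr17"] * 8 + ["chr7"] * 12,
            "pos": list(rng.integers(1, 80_000_000, 8)) + list(
                rng.integers(1, 150_000_000, 12)
            ),
            "n_probes": rng.integers(1, 8, 20),
        },
        index=features,
    )
    sample_meta = pd.DataFrame(
        {
            "subgroup": ["WNT", "WNT", "SHH", "SHH", "SHH", "group3", "group3",
                         "group4", "group4", "group4"],
            "i17q_status": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1],
            "sex": ["M", "F"] * 5,
        },
        index=samples,
    )
    return ExpressionCohort(matrix, feature_meta, sample_meta)
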