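import numpy as np
import pandas as pd
import pytest

from tcdyn.matrix import TimeCourseMatrix

TIME_POINTS = (0.6, 1, 2.5, 4, 6, 12)


def matrix_from_log2_means(means_by_gene: dict, replicates: int = 3, noise_sd: float = 0.0,
                           seed: int = 0) -> TimeCourseMatrix:
    """Build a TimeCourseMatrix whose per-time-point log2 means are given
    exactly (optionally jittered), for constructed oracle cases."""
    n_t = len(next(iter(means_by_gene.values())))
    cols = [f"T{t + 1}_R{r + 1}" for t in range(n_t) for r in range(replicates)]
    design = pd.DataFrame(
        {
            "time_point": np.repeat(list(TIME_POINTS[:n_t]), replicates),
            "replicate": list(np.tile(np.arange(1, replicates + 1), n_t)),
        },
        index=cols,
    )
    rng = np.random.default_rng(seed)
    rows = {}
    for g, means in means_by_gene.items():
        vals = np.repeat(np.asarray(means, dtype=float), replicates)
        if noise_sd:
            vals = vals + rng.normal(0, noise_sd, size=vals.size)
        rows[g] = vals
    values = pd.DataFrame(rows, index=cols).T
    return TimeCourseMatrix(values=values, design=design)


@pytest.fixture
def make_matrix():
    return matrix_from_log2_means
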