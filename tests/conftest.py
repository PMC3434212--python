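import numpy as np
import pytest

from beadpipe import (SimConfig, build_expression_matrix, generate_cohort,
                      log2_quantile_normalize)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale cohort: full study layout, few probes, fast to process."""
    return SimConfig(n_probes=300, n_neg_controls=40, beads_per_probe=10,
                     rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    arrays, meta, _ = small_cohort
    return build_expression_matrix(arrays, meta)


@pytest.fixture(scope="session")
def small_norm(small_matrix):
    return log2_quantile_normalize(small_matrix)


@pytest.fixture(scope="session")
def baseline_groups(small_matrix):
    m = small_matrix
    return {
        "control": m.samples_where(group="control", timepoint="baseline"),
        "patient": m.samples_where(group="patient", timepoint="baseline"),
    }


def mad_oracle(values, multiplier=2.0):
    """Definitional bead-outlier filter: literal median/MAD bounds check."""
    import statistics

    med = statistics.median(values)
    mad = statistics.median([abs(v - med) for v in values])
    lo, hi = med - multiplier * mad, med + multiplier * mad
    retained = [v for v in values if lo <= v <= hi]
    removed = [v for v in values if not (lo <= v <= hi)]
    return retained, removed
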