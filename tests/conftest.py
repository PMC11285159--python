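import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240729)


@pytest.fixture
def small_counts_table():
    """Six hand-constructed sites covering the classification cases."""
    rows = [
        # chrom pos ref A_m C_m G_m T_m A_f C_f G_f T_f
        ("chr1", 100, "A", 10, 0, 10, 0, 20, 0, 0, 0),   # G: XY pattern
        ("chr1", 200, "T", 0, 0, 0, 30, 0, 0, 0, 30),    # monomorphic
        ("chr1", 300, "A", 6, 2, 2, 0, 5, 5, 0, 0),      # multi-allelic
        ("chr2", 100, "C", 0, 25, 0, 0, 0, 12, 0, 13),   # T: ZW pattern
        ("chr2", 200, "A", 2, 1, 0, 0, 9, 9, 0, 0),      # male pool shallow
        ("chr2", 300, "G", 12, 0, 12, 0, 11, 0, 13, 0),  # balanced SNP
    ]
    cols = ["chrom", "pos", "ref", "A_m", "C_m", "G_m", "T_m",
            "A_f", "C_f", "G_f", "T_f"]
    return pd.DataFrame(rows, columns=cols)
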