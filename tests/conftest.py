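import numpy as np
import pandas as pd
import pytest

from cohortcna.datatypes import SnpManifest
from cohortcna.simulate import SimConfig, simulate_cohort

MB = 1_000_000


@pytest.fixture(scope="session")
def toy_manifest():
    """Three small chromosomes, 200 evenly spaced probes each."""
    rows = []
    for c, n in (("chr1", 200), ("chr2", 200), ("chrX", 200)):
        for i in range(n):
            rows.append((f"{c}_p{i:03d}", c, (i + 1) * 50_000,
                         0.40 + 0.1 * np.sin(i / 20)))
    return SnpManifest(pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gc_fraction"]))


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 10-sample cohort on a reduced probe grid (shared, read-only)."""
    cfg = SimConfig(
        n_per_group={"hyperplasia": 2, "benign": 4, "malignant": 4},
        probes_per_chrom={"chr1": 1500, "chr2": 1500, "chr3": 1500,
                          "chr4": 1500},
        seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free 6-sample cohort for exactness oracles."""
    cfg = SimConfig.zero_noise(
        n_per_group={"hyperplasia": 1, "benign": 2, "malignant": 3},
        probes_per_chrom={"chr1": 800, "chr2": 800, "chr3": 800, "chr4": 800},
        seed=5)
    return simulate_cohort(cfg)
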