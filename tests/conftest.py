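import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tepav import SimConfig, simulate_features, simulate_truth_panel

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_panel():
    """A modest truth panel shared by read-only module tests."""
    return simulate_truth_panel(SimConfig(seed=11, n_samples=60, n_tes=300))


@pytest.fixture(scope="session")
def small_features(small_panel):
    features, coverages = simulate_features(small_panel, seed=12)
    return features, coverages


@pytest.fixture
def write_sam(tmp_path):
    """Write a minimal coordinate-sorted SAM file.

    Reads are (chrom, start, length, mq) tuples, 1-based start.
    """

    def _write(reads, chroms=None, name="reads.sam"):
        chroms = chroms or {"chr1": 1_000_000}
        lines = ["@HD\tVN:1.6\tSO:coordinate"]
        for chrom, length in chroms.items():
            lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
        for i, (chrom, start, length, mq) in enumerate(
            sorted(reads, key=lambda r: (r[0], r[1]))
        ):
            seq = "A" * length
            qual = "I" * length
            lines.append(
                f"r{i}\t0\t{chrom}\t{start}\t{mq}\t{length}M\t*\t0\t0\t{seq}\t{qual}"
            )
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
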