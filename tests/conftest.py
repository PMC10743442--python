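from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def cterm_ig_alignment():
    """Synthetic 29-sequence Cterm-Ig alignment with 7 invariant columns."""
    from dgrscan.motif import read_aligned_fasta

    ids, seqs = read_aligned_fasta(DATA_DIR / "cterm_ig_synthetic_29.afa")
    return ids, seqs


@pytest.fixture(scope="session")
def sim7():
    """A simulated dual-target genome (seed 7) with its annotation and truth."""
    from dgrscan.simulate import SimulationParams, simulate_genome

    return simulate_genome(SimulationParams(seed=7, p_sub=0.5, q_background=0.0))
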