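import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def simulated(tmp_path):
    """Factory: build (fasta, bam, truth_logs, contig_seq) from a SimulationSpec."""
    from cisindel.simulate import make_reference, simulate_reads

    def build(spec, name="ds"):
        fasta = tmp_path / f"{name}.fa"
        bam = tmp_path / f"{name}.bam"
        seq = make_reference(spec, fasta)
        logs = simulate_reads(spec, fasta, bam, truth_tsv=tmp_path / f"{name}.truth.tsv")
        return fasta, bam, logs, seq

    return build


def find_motif(seq: str, motif: str, start: int) -> int:
    """1-based position of *motif* in *seq* at or after 0-based *start*."""
    i = seq.find(motif, start)
    assert i >= 0, f"motif {motif} not found"
    return i + 1
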