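import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="reads.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_fastq(tmp_path):
    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq, qual in records:
                fh.write(f"@{rec_id}\n{seq}\n+\n{qual}\n")
        return path

    return _write
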