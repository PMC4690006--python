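import random

import pytest

from cpkfamily.seqio import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def random_records():
    """Factory for reproducible random protein record collections."""

    def make(n, min_len=5, max_len=120, seed=0):
        rng = random.Random(seed)
        return [
            ProteinRecord(
                f"rec{i:03d}",
                "".join(rng.choice(AA) for _ in range(rng.randint(min_len, max_len))),
                f"random record {i}",
            )
            for i in range(n)
        ]

    return make


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing raw FASTA text to a temp file and returning its path."""

    def write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
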