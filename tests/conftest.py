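from __future__ import annotations

import numpy as np
import pytest

from promarch import PromoterRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_record(rng):
    """A 500 nt i.i.d. uniform promoter record."""
    seq = "".join(rng.choice(list("ACGT"), size=500))
    return PromoterRecord(id="rand500", sequence=seq)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA text to a temp file and returning its path."""

    def write(text: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
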