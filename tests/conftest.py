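import numpy as np
import pytest

from utreg.io import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20170309)


def random_record(rng, length, gid="g", region="utr5", gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return SequenceRecord(gid, seq, region)


@pytest.fixture
def make_fasta(tmp_path):
    def _write(text, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
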