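import numpy as np
import pytest

from polymorphome import synth
from polymorphome.core_io import TranscriptRecord
from polymorphome.taxflow import Taxonomy


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    """Small Metazoa/bacteria/fungi taxonomy shared across LCA tests."""
    return Taxonomy(synth.toy_taxonomy())


@pytest.fixture()
def fasta_file(tmp_path):
    """Write a FASTA from (id, seq) pairs and return its path."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def make_record(rid: str, seq: str, component: str | None = None) -> TranscriptRecord:
    return TranscriptRecord(id=rid, sequence=seq, component_id=component or rid)


@pytest.fixture(scope="session")
def random_records():
    """Random ACGT records (some with N) for oracle comparisons."""
    rng = np.random.default_rng(12345)
    records = []
    for i in range(500):
        n = int(rng.integers(30, 301))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if i % 7 == 0:  # sprinkle ambiguity codes
            pos = int(rng.integers(0, n))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        records.append(make_record(f"r{i}", seq))
    return records
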