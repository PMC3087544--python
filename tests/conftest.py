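import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodekit.taxa import BarcodeRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(record_id, species, sequence, marker="M"):
    return BarcodeRecord(
        record_id=record_id,
        marker=marker,
        genus=species.split()[0],
        species=species,
        sequence=sequence,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def sample_fasta(tmp_path):
    text = (
        ">AB1|Aster tataricus\nACGTACGTACGT\n"
        ">AB2|Aster tataricus\nACGTACGAACGT\n"
        ">AB3|Aster alpinus\nACCTACGTACGA\n"
        ">CD1|Carduus nutans\nTTGTACGTACGA\n"
    )
    path = tmp_path / "sample.fasta"
    path.write_text(text)
    return path
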