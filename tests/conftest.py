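import numpy as np
import pytest

from iuorfkit.io import SequenceRecord, TISCall
from iuorfkit.orfs import CanonicalOrf

RNA = "ACGU"


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(RNA), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_sorf_transcript():
    """Hand-built transcript with two qualifying upstream sORFs.

    cTIS=1; sORF1 5..13 (spacer 15), sORF2 18..26 (spacer 2),
    ntTIS=28, canonical stop 40..42.
    """
    seq = (
        "AUG" + "C" + "AUG" + "CCC" + "UAA" + "CCCC"
        + "AUG" + "CCC" + "UGA" + "C" + "AUG"
        + "CCCCCCCCC" + "UAA" + "CCC"
    )
    record = SequenceRecord(id="twosorf", seq=seq)
    canonical = CanonicalOrf(transcript_id="twosorf", cTIS=1, cSTOP_end=42)
    calls = [
        TISCall("twosorf", 1, "AUG", 9.0, is_canonical=True),
        TISCall("twosorf", 5, "AUG", 5.0),
        TISCall("twosorf", 18, "AUG", 2.0),
        TISCall("twosorf", 28, "AUG", 1.0),
    ]
    return record, canonical, calls
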