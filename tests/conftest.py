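import numpy as np
import pytest

# The published stem-loop context of the rolling-circle origin used as the
# worked exemplar throughout: an 11-bp perfect stem around an 11-nt loop
# containing the TAGTATTAA nonamer (one mismatch to canonical TAGTATTAC).
EXEMPLAR_33MER = "CGAGATTCGTCCTTAGTATTAAGACGAATCTCG"

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
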