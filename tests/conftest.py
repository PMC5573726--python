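"""Shared fixtures: toy references and the miR-34 family fixture set."""

import pytest

from isomirkit import build_reference_set
from isomirkit.mir34 import build_mir34_reference

# Toy hairpin: 5p mature in the first half, 3p mature in the second half.
# The base after each mature differs from U/A so that +U/+A NTA calls are
# never confusable with templated extension.
TOY_5P = "UGAGGUAGUAGGUUGUAUAGCA"          # 22 nt
TOY_3P = "CUAUGCAAUUUUCUACCAGACC"          # 22 nt
TOY_HAIRPIN = (
    "GGGAAACUAU" + TOY_5P + "CC" + "GAUCGAUC" + TOY_3P + "GGAAACCCAA"
)


@pytest.fixture
def toy_refset():
    return build_reference_set(
        [("toy-mir-1", TOY_HAIRPIN)],
        [("toy-miR-1-5p", TOY_5P), ("toy-miR-1-3p", TOY_3P)],
    )


@pytest.fixture
def mir34_refset():
    return build_mir34_reference()
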