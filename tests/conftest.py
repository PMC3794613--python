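from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from dicomps import (
    Isoacceptor,
    IsoacceptorSet,
    build_codon_assignment,
    enumerate_pairs,
    packaged_isoacceptor_set,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iso48():
    """The packaged 48-member synthetic mammalian-like isoacceptor set."""
    return packaged_isoacceptor_set()


@pytest.fixture(scope="session")
def assignment(iso48):
    return build_codon_assignment(iso48)


@pytest.fixture(scope="session")
def universe(iso48):
    return enumerate_pairs(iso48)


#: a compact decoding set: inosine-34 readers cover most codons, so almost
#: every pair is common in any background and only a deliberately planted
#: rare dicodon can produce a rare pair
TOY_TABLE = """amino_acid\tanticodon\tgene_count
Ile\tAAU\t10
Ile\tUAU\t2
Gly\tGCC\t8
Gly\tCCC\t4
Pro\tAGG\t6
Lys\tUUU\t7
Glu\tUUC\t6
Ala\tAGC\t9
Val\tAAC\t8
Leu\tAAG\t7
Ser\tAGA\t6
Thr\tAGU\t5
Arg\tACG\t5
"""


@pytest.fixture(scope="session")
def toy_table_text():
    return TOY_TABLE


@pytest.fixture()
def toy_iso():
    """A 3-member set: two Ile isoacceptors plus Gly-CCC."""
    return IsoacceptorSet(
        members=(
            Isoacceptor("Ile", "AAU", 10),
            Isoacceptor("Ile", "UAU", 2),
            Isoacceptor("Gly", "CCC", 5),
        ),
        species_label="toy",
    )
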