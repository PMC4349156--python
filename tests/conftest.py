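"""Shared fixtures: hand-checkable toy alignments and one preset dataset."""

import numpy as np
import pytest

from mmcoal import (
    LabeledAlignment,
    SampleRecord,
    preset_ckma,
    simulate_balanced_locus,
)


def make_alignment(seqs, roles=None, localities=None, regions=None, ids=None):
    """Build a LabeledAlignment from a list of sequence strings."""
    n = len(seqs)
    ids = ids or [f"s{i+1}" for i in range(n)]
    roles = roles or ["ingroup"] * n
    localities = localities or ["Syn"] * n
    regions = regions or ["none"] * n
    samples = [
        SampleRecord(id=i, locality=l, region=r, role=ro, taxon="test")
        for i, l, r, ro in zip(ids, localities, regions, roles)
    ]
    matrix = np.array([list(s) for s in seqs], dtype="U1")
    return LabeledAlignment(samples, matrix)


@pytest.fixture
def toy4():
    """4 x 10 alignment with S=3, H=4, h=1, K=10/6, Tajima's D ~ 0.168."""
    return make_alignment([
        "AAAAAAAAAA",
        "AAAAAAAAAT",
        "AAAAAAAATT",
        "AAAAAAATTT",
    ])


@pytest.fixture
def toy_fst():
    """2+2 samples: within-group diffs 1 and 1, between-group diffs all 3."""
    return make_alignment(
        ["AAAAG", "AAAAT", "CCAAC", "CCAAA"],
        localities=["L1", "L1", "L2", "L2"],
    )


@pytest.fixture
def toy_polarized():
    """4 ingroup + outgroup; derived allele counts 1, 2, 3 at columns 1-3."""
    return make_alignment(
        [
            "TCGAA",  # derived at columns 1, 2, 3
            "ACGAA",  # derived at columns 2, 3
            "AAGAA",  # derived at column 3
            "AAAAA",  # all ancestral
            "AAAAA",  # outgroup
        ],
        roles=["ingroup"] * 4 + ["outgroup"],
        ids=["s1", "s2", "s3", "s4", "og"],
    )


@pytest.fixture(scope="session")
def ckma_like():
    """One balanced-locus dataset from the documented preset."""
    return simulate_balanced_locus(preset_ckma())
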