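"""Shared fixtures: the published annotation and seeded synthetic genomes."""

from __future__ import annotations

import pytest

from mitocomp.refdata import dstuposa_annotation
from mitocomp.synthetic import GenomeSpec, generate


@pytest.fixture(scope="session")
def table4():
    """The published 38-feature *D. stuposa* annotation (no sequence)."""
    return dstuposa_annotation()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One synthetic mitogenome under the default study conditions."""
    ann, ledger = generate(GenomeSpec(seed=20))
    return ann, ledger


@pytest.fixture()
def synthetic_ann(synthetic_genome):
    ann, _ = synthetic_genome
    return ann
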