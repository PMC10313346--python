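import io
import os

import pytest

from pairlift import ChromOrder, build_index, parse_chain, write_pairs
from pairlift.fixtures import (
    Deletion,
    Insertion,
    Inversion,
    RearrangementPlan,
    Translocation,
    make_chain,
)

IDENTITY_CHAIN = "chain 100 chrA 1000 + 0 1000 chrA 1000 + 0 1000 1\n1000\n\n"
TWO_BLOCK_CHAIN = "chain 90 chrA 1000 + 0 1000 chrB 900 + 0 900 2\n500 100 0\n400\n\n"
MINUS_CHAIN = "chain 100 chrA 1000 + 100 200 chrB 1000 - 300 400 3\n100\n\n"


@pytest.fixture
def identity_chains():
    return parse_chain(io.StringIO(IDENTITY_CHAIN))


@pytest.fixture
def two_block_chains():
    return parse_chain(io.StringIO(TWO_BLOCK_CHAIN))


@pytest.fixture
def minus_chains():
    return parse_chain(io.StringIO(MINUS_CHAIN))


@pytest.fixture
def identity_index(identity_chains):
    return build_index(identity_chains)


@pytest.fixture
def mixed_plan():
    """One edit of every kind across two small chromosomes."""
    return RearrangementPlan(
        chrom_sizes={"chrA": 20_000, "chrB": 15_000},
        edits=[
            Deletion("chrA", 1_000, 2_000),
            Inversion("chrA", 5_000, 7_000),
            Insertion("chrB", 9_000, 500),
            Translocation("chrB", 2_000, 4_000, "chrA", 10_000),
        ],
    )


@pytest.fixture
def mixed_fixture(mixed_plan):
    return make_chain(mixed_plan)


def write_fixture_files(fixture, directory):
    """Write chain + target-sizes files for a FixtureChain; returns paths."""
    chain_path = os.path.join(directory, "fixture.chain")
    sizes_path = os.path.join(directory, "target.sizes")
    with open(chain_path, "w") as fh:
        fh.write(fixture.chain_text)
    with open(sizes_path, "w") as fh:
        for name, size in fixture.target_sizes.items():
            fh.write(f"{name}\t{size}\n")
    return chain_path, sizes_path


def write_pairs_file(records, chrom_sizes, path):
    order = ChromOrder(chrom_sizes.items())
    write_pairs(records, order, path, check_sorted=False)
    return order
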