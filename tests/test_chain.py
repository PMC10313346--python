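"""Chain parsing and single-base liftover arithmetic."""

import gzip
import io

import numpy as np
import pytest

from pairlift import (
    AMBIGUOUS,
    ChainConsistencyError,
    ChainFormatError,
    LiftedPoint,
    UNMAPPED,
    build_index,
    chains_to_text,
    invert_chains,
    lift_point,
    parse_chain,
)
from pairlift.fixtures import BaseMapOracle, random_plan, make_chain, oracle_lift

from conftest import IDENTITY_CHAIN, MINUS_CHAIN, TWO_BLOCK_CHAIN


class TestParse:
    def test_identity_chain_single_block(self, identity_chains):
        header, blocks = identity_chains[0]
        assert header.chain_id == 1 and header.q_strand == "+"
        assert len(blocks) == 1
        assert (blocks[0].t_lo, blocks[0].t_hi, blocks[0].q_lo) == (0, 1000, 0)

    def test_gap_line_advances_both_cursors(self, two_block_chains):
        _, blocks = two_block_chains[0]
        assert [(b.t_lo, b.t_hi, b.q_lo) for b in blocks] == [(0, 500, 0), (600, 1000, 500)]

    @pytest.mark.parametrize(
        "text",
        [
            # sums do not reconcile with t_end
            "chain 90 chrA 1000 + 0 1000 chrB 900 + 0 900 2\n500 100 0\n300\n",
            # cursor overruns q_end
            "chain 90 chrA 1000 + 0 1000 chrB 900 + 0 800 2\n500 100 0\n400\n",
        ],
    )
    def test_irreconcilable_cursor_walk_is_an_error(self, text):
        with pytest.raises(ChainConsistencyError):
            parse_chain(io.StringIO(text))

    @pytest.mark.parametrize(
        "text",
        [
            "chain 90 chrA 1000 + 0 1000 chrB 900 + 0 900\n400\n",  # 12 fields
            "chain x chrA 1000 + 0 1000 chrB 900 + 0 900 2\n400\n",  # non-numeric
            "chain 90 chrA 1000 - 0 1000 chrB 900 + 0 900 2\n400\n",  # t_strand '-'
            "400\n",  # data line outside a chain
        ],
    )
    def test_malformed_input_raises_format_error(self, text):
        with pytest.raises(ChainFormatError):
            parse_chain(io.StringIO(text))

    def test_error_message_carries_line_number(self):
        bad = "# comment\nchain 90 chrA 1000 + 0 1000 chrB 900 + 0 900\n"
        with pytest.raises(ChainFormatError, match="line 2"):
            parse_chain(io.StringIO(bad))

    def test_comments_and_gzip_input(self, tmp_path):
        path = tmp_path / "c.chain.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("# a comment\n" + IDENTITY_CHAIN)
        chains = parse_chain(str(path))
        assert len(chains) == 1

    def test_serialization_round_trip(self, two_block_chains):
        text = chains_to_text(two_block_chains)
        assert parse_chain(io.StringIO(text)) == two_block_chains


class TestIndexAndLift:
    def test_identity_lifts_every_base_to_itself(self, identity_index):
        for pos in (0, 500, 999):
            assert lift_point(identity_index, "chrA", pos) == LiftedPoint(
                "chrA", pos, inverted=False, score=100
            )

    def test_gap_bases_are_unmapped(self, two_block_chains):
        index = build_index(two_block_chains)
        assert lift_point(index, "chrA", 700) == LiftedPoint("chrB", 600, False, 90)
        assert lift_point(index, "chrA", 550) is UNMAPPED

    def test_minus_strand_block_reverses_coordinates(self, minus_chains):
        index = build_index(minus_chains)
        assert lift_point(index, "chrA", 100) == LiftedPoint("chrB", 699, True, 100)
        assert lift_point(index, "chrA", 150) == LiftedPoint("chrB", 649, True, 100)

    def test_unknown_chromosome_is_unmapped_not_an_error(self, identity_index):
        assert lift_point(identity_index, "chrZ", 5) is UNMAPPED

    def test_min_score_excludes_low_scoring_chains(self):
        both = parse_chain(io.StringIO(IDENTITY_CHAIN + MINUS_CHAIN.replace("chain 100", "chain 10")))
        index = build_index(both, min_score=50)
        assert lift_point(index, "chrA", 150) == LiftedPoint("chrA", 150, False, 100)
        # and the low-score chain's exclusive bases become unmapped
        index_lo = build_index(both, min_score=0)
        assert isinstance(lift_point(index_lo, "chrA", 150), LiftedPoint)

    def test_raising_min_score_never_adds_mappable_bases(self, two_block_chains):
        lo = build_index(two_block_chains, min_score=0)
        hi = build_index(two_block_chains, min_score=95)
        for pos in range(0, 1000, 7):
            if isinstance(lift_point(hi, "chrA", pos), LiftedPoint):
                assert isinstance(lift_point(lo, "chrA", pos), LiftedPoint)

    def test_overlap_resolved_by_score_and_exact_tie_is_ambiguous(self):
        overlap_hi = (
            "chain 200 chrA 1000 + 0 500 chrB 900 + 0 500 10\n500\n\n"
            "chain 100 chrA 1000 + 0 500 chrB 900 + 100 600 11\n500\n\n"
        )
        index = build_index(parse_chain(io.StringIO(overlap_hi)))
        assert lift_point(index, "chrA", 250) == LiftedPoint("chrB", 250, False, 200)
        tie = overlap_hi.replace("chain 200", "chain 100")
        index_tie = build_index(parse_chain(io.StringIO(tie)))
        assert lift_point(index_tie, "chrA", 250) is AMBIGUOUS

    def test_chain_to_missing_target_chrom_is_skipped_with_count(self, two_block_chains):
        index = build_index(two_block_chains, target_sizes={"chrC": 100})
        assert index.skipped_chains == 1
        assert lift_point(index, "chrA", 100) is UNMAPPED

    def test_empty_chain_set_gives_empty_index(self):
        index = build_index([])
        assert lift_point(index, "chrA", 0) is UNMAPPED

    def test_negative_position_rejected(self, identity_index):
        with pytest.raises(ValueError):
            lift_point(identity_index, "chrA", -1)


class TestInvert:
    def test_identity_chain_inverts_to_itself(self, identity_chains):
        assert invert_chains(identity_chains) == identity_chains

    def test_two_block_chain_inverse_maps_back(self, two_block_chains):
        inverted = build_index(invert_chains(two_block_chains))
        assert lift_point(inverted, "chrB", 500) == LiftedPoint("chrA", 600, False, 90)
        assert lift_point(inverted, "chrB", 899) == LiftedPoint("chrA", 999, False, 90)

    def test_double_inversion_is_identity(self, two_block_chains, minus_chains):
        for chains in (two_block_chains, minus_chains):
            assert invert_chains(invert_chains(chains)) == chains

    def test_round_trip_on_every_uniquely_mapped_base(self, minus_chains, two_block_chains):
        for chains in (minus_chains, two_block_chains):
            fwd = build_index(chains)
            rev = build_index(invert_chains(chains))
            for pos in range(1000):
                hit = lift_point(fwd, "chrA", pos)
                if isinstance(hit, LiftedPoint):
                    back = lift_point(rev, hit.chrom, hit.pos)
                    assert back == LiftedPoint("chrA", pos, hit.inverted, hit.score)


class TestOracleEquivalence:
    def test_offset_preserved_within_blocks(self, minus_chains):
        index = build_index(minus_chains)
        a = lift_point(index, "chrA", 110)
        b = lift_point(index, "chrA", 120)
        assert a.pos - b.pos == 10  # '-' block: negated offset

    def test_lift_point_matches_exhaustive_oracle_on_small_plans(self):
        """Spot oracle check (five plans); the full sweep lives in acceptance."""
        rng = np.random.default_rng(20240915)
        for _ in range(5):
            plan = random_plan(rng, max_chrom=20_000)
            fixture = make_chain(plan)
            index = build_index(fixture.chains)
            for chrom, size in plan.chrom_sizes.items():
                for pos in range(0, size, 3):
                    assert lift_point(index, chrom, pos) == oracle_lift(
                        fixture.oracle, chrom, pos
                    )
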