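"""The synthetic-rearrangement generator and its exhaustive oracle."""

import numpy as np
import pytest

from pairlift import LiftedPoint, ParameterError, PlanError, UNMAPPED
from pairlift.fixtures import (
    Deletion,
    Insertion,
    Inversion,
    RearrangementPlan,
    Translocation,
    make_chain,
    oracle_lift,
    random_plan,
    simulate_contacts,
)


class TestMakeChain:
    def test_empty_plan_yields_identity_mapping(self):
        fixture = make_chain(RearrangementPlan({"chrA": 500}))
        assert fixture.target_sizes == {"chrA": 500}
        for pos in range(500):
            assert oracle_lift(fixture.oracle, "chrA", pos) == LiftedPoint(
                "chrA", pos, False, 500
            )

    def test_deletion_unmaps_exactly_its_bases(self):
        fixture = make_chain(
            RearrangementPlan({"chrA": 1_000}, [Deletion("chrA", 300, 400)])
        )
        unmapped = [
            pos for pos in range(1_000)
            if oracle_lift(fixture.oracle, "chrA", pos) is UNMAPPED
        ]
        assert unmapped == list(range(300, 400))
        assert fixture.target_sizes == {"chrA": 900}

    def test_insertion_creates_no_unmapped_source_bases(self):
        fixture = make_chain(
            RearrangementPlan({"chrA": 1_000}, [Insertion("chrA", 500, 200)])
        )
        assert fixture.oracle.n_mapped() == 1_000
        assert fixture.target_sizes == {"chrA": 1_200}
        # bases after the breakpoint shift right by the inserted length
        assert oracle_lift(fixture.oracle, "chrA", 600).pos == 800

    def test_inversion_strand_is_minus_exactly_on_the_interval(self):
        fixture = make_chain(
            RearrangementPlan({"chrA": 1_000}, [Inversion("chrA", 200, 300)])
        )
        for pos in range(1_000):
            hit = oracle_lift(fixture.oracle, "chrA", pos)
            assert hit.inverted == (200 <= pos < 300)
        # interval reversed in place
        assert oracle_lift(fixture.oracle, "chrA", 200).pos == 299
        assert oracle_lift(fixture.oracle, "chrA", 299).pos == 200

    def test_translocation_moves_segment_to_dest_chromosome(self):
        fixture = make_chain(
            RearrangementPlan(
                {"chrA": 1_000, "chrB": 500},
                [Translocation("chrA", 100, 200, "chrB", 250)],
            )
        )
        assert fixture.target_sizes == {"chrA": 900, "chrB": 600}
        hit = oracle_lift(fixture.oracle, "chrA", 150)
        assert hit.chrom == "chrB" and hit.pos == 300
        # dest bases after the breakpoint shift by the inserted segment
        assert oracle_lift(fixture.oracle, "chrB", 250).pos == 350

    def test_chain_text_is_format_valid(self, mixed_fixture):
        # parsed without error at construction; every chain reconciled
        assert len(mixed_fixture.chains) >= 4
        for header, blocks in mixed_fixture.chains:
            assert sum(b.t_hi - b.t_lo for b in blocks) == header.t_end - header.t_start

    @pytest.mark.parametrize(
        "edits",
        [
            [Deletion("chrA", 100, 300), Inversion("chrA", 200, 400)],  # overlap
            [Deletion("chrA", 100, 100)],  # zero length
            [Deletion("chrZ", 0, 10)],  # unknown chromosome
            [Translocation("chrA", 10, 20, "chrA", 15)],  # breakpoint inside itself
        ],
    )
    def test_invalid_plans_rejected(self, edits):
        with pytest.raises(PlanError):
            make_chain(RearrangementPlan({"chrA": 1_000}, edits))


class TestRandomPlans:
    def test_oracle_covers_every_base_decision(self):
        """Each base is mapped, unmapped or ambiguous — never undefined."""
        rng = np.random.default_rng(77)
        plan = random_plan(rng, max_chrom=15_000)
        fixture = make_chain(plan)
        n_decisions = sum(
            1
            for chrom, size in plan.chrom_sizes.items()
            for pos in range(0, size, 11)
            if oracle_lift(fixture.oracle, chrom, pos) is not None
        )
        assert n_decisions == sum(
            len(range(0, size, 11)) for size in plan.chrom_sizes.values()
        )

    def test_plans_are_reproducible_under_a_seeded_generator(self):
        p1 = random_plan(np.random.default_rng(123))
        p2 = random_plan(np.random.default_rng(123))
        assert p1 == p2


class TestSimulateContacts:
    SIZES = {"chr1": 60_000, "chr2": 40_000, "chr3": 30_000}

    def test_zero_n_yields_nothing(self):
        assert list(simulate_contacts(self.SIZES, 0)) == []

    def test_zero_trans_fraction_means_all_cis(self):
        records = list(simulate_contacts(self.SIZES, 2_000, trans_fraction=0.0, seed=1))
        assert all(r.chrom1 == r.chrom2 for r in records)

    def test_trans_fraction_within_3_sigma_binomial(self):
        n, p = 20_000, 0.1
        records = list(simulate_contacts(self.SIZES, n, trans_fraction=p, seed=42))
        observed = sum(r.chrom1 != r.chrom2 for r in records)
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(observed - n * p) <= 3 * sigma

    def test_cis_positions_respect_chromosome_bounds(self):
        for rec in simulate_contacts(self.SIZES, 3_000, seed=5):
            assert 0 <= rec.pos1 < self.SIZES[rec.chrom1]
            assert 0 <= rec.pos2 < self.SIZES[rec.chrom2]
            if rec.chrom1 == rec.chrom2:
                assert rec.pos2 > rec.pos1  # cis distance >= 1

    def test_bit_for_bit_reproducible_under_fixed_seed(self):
        a = list(simulate_contacts(self.SIZES, 500, seed=9))
        b = list(simulate_contacts(self.SIZES, 500, seed=9))
        assert a == b
        c = list(simulate_contacts(self.SIZES, 500, seed=10))
        assert a != c

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": -1},
            {"n": 1, "decay_exponent": 0.0},
            {"n": 1, "trans_fraction": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            list(simulate_contacts(self.SIZES, **kwargs))

    def test_steeper_decay_shortens_distances(self):
        shallow = list(simulate_contacts(self.SIZES, 3_000, decay_exponent=0.5,
                                         trans_fraction=0.0, seed=4))
        steep = list(simulate_contacts(self.SIZES, 3_000, decay_exponent=2.0,
                                       trans_fraction=0.0, seed=4))
        med = lambda rs: float(np.median([r.pos2 - r.pos1 for r in rs]))
        assert med(steep) < med(shallow)
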