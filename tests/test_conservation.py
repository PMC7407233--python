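"""Chain parsing, BSJ liftover, cross-verification and set partitions."""

import numpy as np
import pytest

from circkit.bsj import BsjCandidate
from circkit.conservation import (
    ChainParseError, cross_verify, lift_bsj,
    multi_species_partition, parse_chain, shared_fraction, write_chain,
    MAPPED, SPLIT, STRAND_INCONSISTENT, UNMAPPED,
)


def cand(start, end, strand="+", chrom="chrA"):
    return BsjCandidate(chrom, start, end, strand)


def write_lines(tmp_path, text, name="c.chain"):
    p = tmp_path / name
    p.write_text(text)
    return p


IDENTITY = "chain 100 chrA 10000 + 0 1000 chrA 10000 + 0 1000 1\n1000\n\n"


class TestParseChain:
    def test_identity_chain(self, tmp_path):
        cm = parse_chain(write_lines(tmp_path, IDENTITY))
        assert len(cm.chains) == 1
        ch = cm.chains[0]
        assert ch.blocks == [(0, 1000, 0)]
        assert ch.map_base(500) == ("chrA", 500, "+")

    def test_gap_recorded_as_two_blocks(self, tmp_path):
        text = ("chain 100 chrA 10000 + 0 1050 chrB 10000 + 0 1000 7\n"
                "500\t50\t0\n500\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        assert cm.chains[0].blocks == [(0, 500, 0), (550, 500, 500)]
        assert cm.chains[0].map_base(520) is None

    def test_block_length_mismatch_names_chain(self, tmp_path):
        text = "chain 100 chrA 10000 + 0 1000 chrB 10000 + 0 1000 9\n900\n\n"
        with pytest.raises(ChainParseError, match="9"):
            parse_chain(write_lines(tmp_path, text))

    def test_roundtrip_on_generator_chains(self, sim_dir, tmp_path):
        out, _ = sim_dir
        cm = parse_chain(out / "pig.chain")
        assert cm.chains
        back = tmp_path / "back.chain"
        write_chain(cm, back)
        cm2 = parse_chain(back)
        assert [(c.chain_id, c.score, c.blocks, c.t_strand, c.t_chrom)
                for c in cm.chains] \
            == [(c.chain_id, c.score, c.blocks, c.t_strand, c.t_chrom)
                for c in cm2.chains]


class TestLiftBsj:
    def test_offset_chain(self, tmp_path):
        text = ("chain 100 chrA 10000 + 0 1000 chrB 20000 + 1000 2000 1\n"
                "1000\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        lr = lift_bsj(cand(100, 600), cm)
        assert (lr.status, lr.chrom, lr.start, lr.end, lr.strand) \
            == (MAPPED, "chrB", 1100, 1600, "+")

    def test_endpoint_in_gap_is_unmapped(self, tmp_path):
        text = ("chain 100 chrA 10000 + 0 1050 chrB 10000 + 0 1000 1\n"
                "500\t50\t0\n500\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        assert lift_bsj(cand(100, 530), cm).status == UNMAPPED

    def test_endpoints_on_two_chains_is_split(self, tmp_path):
        text = ("chain 100 chrA 10000 + 0 500 chrB 10000 + 0 500 1\n500\n\n"
                "chain 100 chrA 10000 + 500 1000 chrB 10000 + 5000 5500 2\n"
                "500\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        assert lift_bsj(cand(100, 900), cm).status == SPLIT

    def test_chains_with_opposite_target_strands_are_inconsistent(
            self, tmp_path):
        text = ("chain 100 chrA 10000 + 0 500 chrB 10000 + 0 500 1\n500\n\n"
                "chain 100 chrA 10000 + 500 1000 chrB 10000 - 5000 5500 2\n"
                "500\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        assert lift_bsj(cand(100, 900), cm).status == STRAND_INCONSISTENT

    def test_inverted_chain_reverses_and_flips_verified_per_base(
            self, tmp_path):
        text = ("chain 100 chrA 10000 + 100 1100 chrB 20000 - 3000 4000 1\n"
                "1000\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        ch = cm.chains[0]
        # per-base check of the reversed-strand arithmetic
        for p in (100, 500, 1099):
            chrom, t, strand = ch.map_base(p)
            assert t == 20000 - 1 - (3000 + (p - 100))
        lr = lift_bsj(cand(200, 700), cm)
        assert lr.status == MAPPED and lr.strand == "-"
        # interval flips: source start maps to target high end
        assert lr.end - lr.start == 500
        assert lr.start == 20000 - 1 - (3000 + (699 - 100))

    def test_highest_score_wins_then_lowest_id(self, tmp_path):
        text = ("chain 50 chrA 10000 + 0 1000 chrB 20000 + 0 1000 1\n1000\n\n"
                "chain 99 chrA 10000 + 0 1000 chrB 20000 + 5000 6000 2\n"
                "1000\n\n")
        cm = parse_chain(write_lines(tmp_path, text))
        lr = lift_bsj(cand(10, 20), cm)
        assert lr.chain_id == 2 and lr.start == 5010

    def test_round_trip_through_inverse_chain(self, tmp_path):
        fwd = ("chain 100 chrA 10000 + 0 1000 chrB 20000 + 4000 5000 1\n"
               "1000\n\n")
        inv = ("chain 100 chrB 20000 + 4000 5000 chrA 10000 + 0 1000 1\n"
               "1000\n\n")
        cm_f = parse_chain(write_lines(tmp_path, fwd, "f.chain"))
        cm_i = parse_chain(write_lines(tmp_path, inv, "i.chain"))
        c0 = cand(123, 777)
        lr = lift_bsj(c0, cm_f)
        back = lift_bsj(cand(lr.start, lr.end, lr.strand, lr.chrom), cm_i)
        assert (back.start, back.end, back.strand) == (123, 777, "+")

    def test_agreement_with_generator_expected_statuses(self, sim_dir):
        """Planted liftover outcomes are recovered exactly for every
        circRNA and species."""
        out, truth = sim_dir
        for species in ("pig", "mouse"):
            cm = parse_chain(out / f"{species}.chain")
            for t in truth.circs:
                if species not in t.lift:
                    continue
                lr = lift_bsj(cand(t.start, t.end, t.strand, t.chrom), cm)
                exp = t.lift[species]
                assert lr.status == exp["status"], (t.circ_id, species)
                if exp["status"] == "mapped":
                    assert (lr.chrom, lr.start, lr.end, lr.strand) == \
                        (exp["chrom"], exp["start"], exp["end"],
                         exp["strand"]), (t.circ_id, species)

    def test_agreement_with_per_base_oracle_small(self):
        from circkit.scenarios import liftover_oracle_agreement

        out = liftover_oracle_agreement(99, n_maps=20, intervals_per_map=10)
        assert out["agreement"] == 1.0


class TestCrossVerify:
    def lifted(self, status=MAPPED, chrom="chrB", start=100, end=600,
               strand="+"):
        from circkit.conservation import LiftResult

        return LiftResult("c1", status, chrom, start, end, strand, 1)

    def test_exact_match_with_enriched_target(self):
        target = cand(100, 600, "+", "chrB")
        recs = cross_verify([self.lifted()], [target],
                            {target.circ_id: True}, strict=True)
        assert recs[0].conserved and recs[0].target_enriched

    def test_non_enriched_target_fails_strict_mode(self):
        target = cand(100, 600, "+", "chrB")
        recs = cross_verify([self.lifted()], [target],
                            {target.circ_id: False}, strict=True)
        assert not recs[0].conserved and recs[0].target_expressed
        lenient = cross_verify([self.lifted()], [target],
                               {target.circ_id: False}, strict=False)
        assert lenient[0].conserved

    def test_slack_matching(self):
        target = cand(103, 597, "+", "chrB")
        assert not cross_verify([self.lifted()], [target],
                                {target.circ_id: True}, slack=0)[0].conserved
        assert cross_verify([self.lifted()], [target],
                            {target.circ_id: True}, slack=3)[0].conserved

    def test_planted_conservation_recovered_exactly(self, sim_dir):
        """The synthetic multi-species truth is recovered exactly at
        slack 0 in strict mode."""
        from circkit.pipeline import load_target_circs

        out, truth = sim_dir
        for species in ("pig", "mouse"):
            cm = parse_chain(out / f"{species}.chain")
            lifted, expected = [], {}
            for t in truth.circs:
                if species not in t.lift:
                    continue
                lifted.append(lift_bsj(cand(t.start, t.end, t.strand,
                                            t.chrom), cm))
                exp = t.lift[species]
                expected[t.circ_id] = bool(exp.get("target_enriched"))
            targets, flags = load_target_circs(out / f"{species}_circs.tsv")
            recs = cross_verify(lifted, targets, flags, slack=0, strict=True)
            got = {r.circ_id: r.conserved for r in recs}
            assert got == expected


class TestPartition:
    def test_disjoint_sets(self):
        out = multi_species_partition({"a": {1, 2}, "b": {3}, "c": {4}})
        assert out["a"] == 2 and out["b"] == 1 and out["c"] == 1
        assert out["a+b+c"] == 0

    def test_identical_sets_all_in_triple_intersection(self):
        out = multi_species_partition({"a": {1, 2}, "b": {1, 2},
                                       "c": {1, 2}})
        assert out["a+b+c"] == 2
        assert sum(v for k, v in out.items() if k != "a+b+c") == 0

    def test_regions_sum_to_union_and_order_invariant(self):
        rng = np.random.default_rng(21)
        sets = {n: set(rng.integers(0, 50, size=20).tolist())
                for n in "xyz"}
        out = multi_species_partition(sets)
        assert sum(out.values()) == len(set().union(*sets.values()))
        reordered = multi_species_partition(dict(reversed(list(sets.items()))))
        assert out == reordered

    def test_shared_fraction_arithmetic(self):
        """A 2073-member set with 252 exclusive members is 87.8% shared."""
        assert shared_fraction(2073, 252) == pytest.approx(1821 / 2073)
        assert shared_fraction(2073, 252) >= 0.80
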