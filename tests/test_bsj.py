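"""BSJ calling, candidate filtering and host-gene summaries."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from circkit.bsj import (
    BsjCandidate, ChimericJunctionRecord, FilterParams,
    alternative_splicing_rate, call_bsjs, circ_per_host_gene,
    filter_candidates, junction_proportion,
)


def rec(pos_a, pos_b, strand="+", chrom="chr1", sample="s1", rid="r"):
    return ChimericJunctionRecord(chrom, pos_a, strand, chrom, pos_b, strand,
                                  rid, sample)


def cand(start=100, end=600, strand="+", counts=None, linear=None, host=None):
    c = BsjCandidate("chr1", start, end, strand,
                     counts=dict(counts or {}),
                     linear_counts=dict(linear or {}))
    c.host_gene = host
    return c


class TestCallBsjs:
    def test_backsplice_orientation_yields_one_candidate(self):
        out = call_bsjs([rec(599, 100)])  # donor downstream, acceptor upstream
        assert len(out) == 1
        c = out[0]
        assert (c.chrom, c.start, c.end, c.strand) == ("chr1", 100, 600, "+")
        assert c.counts == {"s1": 1}

    def test_linear_orientation_is_ignored(self):
        assert call_bsjs([rec(100, 599)]) == []

    def test_trans_chimera_ignored(self):
        r = ChimericJunctionRecord("chr1", 599, "+", "chr2", 100, "+", "r", "s1")
        assert call_bsjs([r]) == []

    def test_unknown_strand_rejected(self):
        assert call_bsjs([rec(599, 100, strand="?")]) == []

    def test_minus_strand_orientation(self):
        # on the minus strand the donor sits at the low coordinate
        out = call_bsjs([rec(100, 599, strand="-")])
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].strand) == (100, 600, "-")

    def test_order_invariance(self, truth, sim_dir):
        from circkit.bsj import read_junction_tsv

        out, _ = sim_dir
        records = list(read_junction_tsv(out / "junctions.tsv"))
        a = call_bsjs(records)
        rng = np.random.default_rng(1)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        b = call_bsjs(shuffled)
        assert [(c.key, sorted(c.counts.items())) for c in a] \
            == [(c.key, sorted(c.counts.items())) for c in b]

    def test_counts_match_generator_truth(self, truth, sim_dir):
        from circkit.bsj import read_junction_tsv

        out, _ = sim_dir
        called = {c.key: c.counts
                  for c in call_bsjs(read_junction_tsv(out / "junctions.tsv"))}
        for t in truth.circs:
            expected = {s: n for s, n in t.counts.items() if n > 0}
            if not expected:
                assert (t.chrom, t.start, t.end, t.strand) not in called
            else:
                assert called[(t.chrom, t.start, t.end, t.strand)] == expected


class TestFilterCandidates:
    @pytest.mark.parametrize("counts, kept", [
        ({"a": 3, "b": 2}, True),
        ({"a": 1, "b": 1}, False),
        ({"a": 2, "b": 0}, False),
        ({"a": 5, "b": 5}, True),
        ({"a": 0, "b": 2}, False),
    ])
    def test_read_support_defaults(self, counts, kept):
        out = filter_candidates([cand(counts=counts)], FilterParams())
        assert bool(out) is kept

    def test_junction_proportion_filter(self):
        c = cand(counts={"a": 1, "b": 2}, linear={"a": 250, "b": 250})
        assert filter_candidates([c], FilterParams(min_reads=1)) == []
        assert junction_proportion(c) == pytest.approx(3 / 503)

    def test_proportion_uses_untreated_samples_only(self):
        c = cand(counts={"u": 2, "t": 50}, linear={"u": 500, "t": 0})
        p = FilterParams(min_reads=2, min_samples=2,
                         untreated_samples={"u"})
        # pooled untreated proportion 2/502 < 1% -> removed
        assert filter_candidates([c], p) == []

    def test_mask_overlap_by_one_base_removes(self):
        tree = IntervalTree()
        tree.addi(599, 700)
        c = cand(counts={"a": 3, "b": 3}, linear={"a": 3, "b": 3})
        out = filter_candidates([c], FilterParams(
            mask_intervals={"chr1": tree}))
        assert out == []
        # half-open: mask ending exactly at the start does not overlap
        tree2 = IntervalTree()
        tree2.addi(50, 100)
        out2 = filter_candidates([c], FilterParams(
            mask_intervals={"chr1": tree2}))
        assert len(out2) == 1

    def test_subset_and_idempotent(self, sim_dir):
        from circkit.bsj import call_bsjs, load_mask_bed, read_junction_tsv
        from circkit.pipeline import attach_linear_counts

        out, _ = sim_dir
        cands = call_bsjs(read_junction_tsv(out / "junctions.tsv"))
        attach_linear_counts(cands, pd.read_csv(
            out / "circ_linear_counts.tsv", sep="\t"))
        p = FilterParams(mask_intervals=load_mask_bed(out / "mask.bed"))
        once = filter_candidates(cands, p)
        assert {c.key for c in once} <= {c.key for c in cands}
        twice = filter_candidates(once, p)
        assert [c.key for c in twice] == [c.key for c in once]

    def test_survivors_satisfy_all_criteria_brute_force(self, sim_dir):
        from circkit.bsj import call_bsjs, load_mask_bed, read_junction_tsv
        from circkit.pipeline import attach_linear_counts

        out, _ = sim_dir
        counts_df = pd.read_csv(out / "circ_linear_counts.tsv", sep="\t")
        untreated = set(counts_df.loc[counts_df["group"] == "untreated",
                                      "sample_id"])
        cands = call_bsjs(read_junction_tsv(out / "junctions.tsv"))
        attach_linear_counts(cands, counts_df)
        mask = load_mask_bed(out / "mask.bed")
        p = FilterParams(mask_intervals=mask, untreated_samples=untreated)
        for c in filter_candidates(cands, p):
            assert sum(1 for v in c.counts.values() if v >= 2) >= 2
            cc = sum(c.counts.get(s, 0) for s in untreated)
            ll = sum(c.linear_counts.get(s, 0) for s in untreated)
            assert cc / (cc + ll) >= 0.01
            for iv in mask.get(c.chrom, IntervalTree()):
                assert not (iv.begin < c.end and iv.end > c.start)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(min_reads=0)
        with pytest.raises(ValueError):
            FilterParams(min_junction_proportion=1.5)


class TestAlternativeSplicing:
    def test_shared_start_pair_both_flagged(self):
        a = cand(100, 600, counts={"s": 10}, host="G")
        b = cand(100, 800, counts={"s": 5}, host="G")
        rate, table = alternative_splicing_rate([a, b])
        assert rate == 1.0
        assert len(table) == 1

    def test_minor_variant_with_three_reads_not_counted(self):
        a = cand(100, 600, counts={"s": 10}, host="G")
        b = cand(100, 800, counts={"s": 3}, host="G")
        rate, table = alternative_splicing_rate([a, b])
        assert rate == 0.0 and table == []

    def test_sharing_both_coordinates_is_not_a_variant(self):
        a = cand(100, 600, counts={"s": 10}, host="G")
        b = cand(100, 600, counts={"s": 10}, host="G")
        rate, _ = alternative_splicing_rate([a, b])
        assert rate == 0.0

    def test_planted_rate_recovered(self):
        """A 500-candidate set with ~3.4% planted variant pairs at deep
        support recovers the rate within one percentage point."""
        from circkit.simulate import SimulationConfig, simulate_annotation

        cfg = SimulationConfig(seed=5, n_genes=520, n_circ=500,
                               exons_per_gene=(8, 12), n_antisense=0,
                               n_intergenic=0, alt_splicing_rate=0.034)
        truth = simulate_annotation(cfg)
        cands = []
        for t in truth.circs:
            c = cand(t.start, t.end, t.strand, counts={"s": 20},
                     host=t.host_gene)
            c.chrom = t.chrom
            cands.append(c)
        rate, _ = alternative_splicing_rate(cands)
        planted = sum(t.alt_variant for t in truth.circs) / len(truth.circs)
        assert abs(rate - planted) <= 0.01
        assert abs(rate - 0.034) <= 0.02


class TestCircPerHostGene:
    def test_per_million_normalization(self):
        cands = [cand(100, 600, host="G"), cand(100, 800, host="G"),
                 cand(200, 900, host="G")]
        df = circ_per_host_gene(cands, {"s1": 1_000_000})
        assert df.loc[0, "circ_per_million"] == pytest.approx(3.0)

    def test_empty_input(self):
        assert circ_per_host_gene([], {"s1": 10}).empty

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            circ_per_host_gene([cand(host="G")], {"s1": 0})

    def test_two_systems_with_2x_rates_separate(self):
        """Planted 2x difference in circs-per-gene is detected by a
        rank-sum comparison at n=200 genes."""
        from scipy import stats

        rng = np.random.default_rng(3)
        sys_a, sys_b = [], []
        for g in range(200):
            for k in range(rng.poisson(2.0)):
                sys_a.append(cand(100 + k, 600 + k, host=f"g{g}"))
            for k in range(rng.poisson(4.0)):
                sys_b.append(cand(100 + k, 600 + k, host=f"g{g}"))
        ta = circ_per_host_gene(sys_a, {"s": 1_000_000})
        tb = circ_per_host_gene(sys_b, {"s": 1_000_000})
        a = ta.set_index("gene_id")["circ_per_million"]
        b = tb.set_index("gene_id")["circ_per_million"]
        genes = [f"g{g}" for g in range(200)]
        stat, p = stats.ranksums(a.reindex(genes).fillna(0),
                                 b.reindex(genes).fillna(0))
        assert p < 1e-6
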