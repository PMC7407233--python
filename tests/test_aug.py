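"""AUG classification, flank features and distribution comparisons."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from circkit.aug import (
    alu_pair_distance, classify_aug, compare_distributions,
    compare_host_translation, ecdf, flanking_intron_lengths,
)
from circkit.bsj import BsjCandidate


def cand(start, end, strand="+", chrom="chr1", host=None):
    c = BsjCandidate(chrom, start, end, strand)
    c.host_gene = host
    return c


def alu_trees(intervals):
    trees = {}
    for chrom, s, e, strand in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(s, e, strand)
    return trees


class TestClassifyAug:
    def test_start_codon_inside_interval(self, annotation, truth):
        g = next(g for g in truth.genes if g.coding and g.strand == "+")
        c = cand(g.cds_start - 100, g.cds_start + 400, "+", g.chrom,
                 g.gene_id)
        assert classify_aug(c, annotation).is_aug

    def test_start_codon_upstream_of_interval(self, annotation, truth):
        g = next(g for g in truth.genes if g.coding and g.strand == "+")
        c = cand(g.cds_start + 100, g.cds_start + 400, "+", g.chrom,
                 g.gene_id)
        assert not classify_aug(c, annotation).is_aug

    def test_hostless_candidate_is_never_aug(self, annotation):
        assert not classify_aug(cand(10, 20), annotation).is_aug

    def test_matches_generator_truth_everywhere(self, annotation, truth):
        """100% agreement with the planted AUG status on the default
        annotation."""
        for t in truth.circs:
            if t.fail_mode:
                continue
            c = cand(t.start, t.end, t.strand, t.chrom, t.host_gene)
            assert classify_aug(c, annotation).is_aug == t.is_aug, t.circ_id


class TestFlankingIntrons:
    def test_matches_generator_truth(self, annotation, truth):
        for t in truth.circs:
            if not t.host_gene or t.fail_mode:
                continue
            c = cand(t.start, t.end, t.strand, t.chrom, t.host_gene)
            up, down, approx = flanking_intron_lengths(c, annotation)
            assert not approx, t.circ_id
            assert up == t.upstream_intron, t.circ_id
            assert down == t.downstream_intron, t.circ_id

    def test_terminal_exon_has_no_upstream_intron(self, annotation, truth):
        g = next(g for g in truth.genes if g.coding)
        first = g.exons[0]
        second = g.exons[1]
        lo = min(first[0], second[0])
        hi = max(first[1], second[1])
        c = cand(lo, hi, g.strand, g.chrom, g.gene_id)
        up, down, approx = flanking_intron_lengths(c, annotation)
        assert up is None and down is not None

    def test_non_boundary_interval_flagged_approximate(self, annotation,
                                                       truth):
        g = next(g for g in truth.genes if g.coding)
        exons = sorted(g.exons)
        c = cand(exons[1][0] + 7, exons[-2][1], g.strand, g.chrom, g.gene_id)
        _, _, approx = flanking_intron_lengths(c, annotation)
        assert approx


class TestAluPairDistance:
    def test_nearest_opposite_pair(self):
        trees = alu_trees([("chr1", 700, 900, "+"), ("chr1", 2150, 2400, "-")])
        # upstream gap 100 (900..1000), downstream gap 150 (2000..2150)
        assert alu_pair_distance(cand(1000, 2000), trees) == 250

    def test_same_orientation_only_is_missing(self):
        trees = alu_trees([("chr1", 700, 900, "+"), ("chr1", 2150, 2400, "+")])
        assert alu_pair_distance(cand(1000, 2000), trees) is None

    def test_outside_window_is_missing(self):
        trees = alu_trees([("chr1", 700, 900, "+"),
                           ("chr1", 500_000, 500_300, "-")])
        assert alu_pair_distance(cand(1000, 2000), trees) is None

    def test_equals_exhaustive_search_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            alus = []
            for k in range(rng.integers(5, 40)):
                s = int(rng.integers(0, 60_000))
                alus.append(("chr1", s, s + int(rng.integers(100, 400)),
                             "+" if rng.random() < 0.5 else "-"))
            c = cand(25_000, 30_000)
            got = alu_pair_distance(c, alu_trees(alus), window=10_000)
            # brute force over all pairs
            ups = [(e, st) for _, s, e, st in alus
                   if e <= c.start and e > c.start - 10_000]
            downs = [(s, st) for _, s, e, st in alus
                     if s >= c.end and s < c.end + 10_000]
            dists = [(c.start - ue) + (ds - c.end)
                     for ue, ust in ups for ds, dst in downs if ust != dst]
            assert got == (min(dists) if dists else None)

    def test_symmetric_under_coordinate_mirroring(self):
        alus = [("chr1", 700, 900, "+"), ("chr1", 2150, 2400, "-"),
                ("chr1", 300, 450, "-")]
        c = cand(1000, 2000)
        d = alu_pair_distance(c, alu_trees(alus))
        M = 10_000
        mirrored = [("chr1", M - e, M - s, "-" if st == "+" else "+")
                    for _, s, e, st in alus]
        cm = cand(M - 2000, M - 1000)
        assert alu_pair_distance(cm, alu_trees(mirrored)) == d

    def test_matches_generator_truth(self, truth):
        trees = alu_trees(truth.alus)
        for t in truth.circs:
            if not t.host_gene or t.fail_mode:
                continue
            c = cand(t.start, t.end, t.strand, t.chrom)
            assert alu_pair_distance(c, trees) == t.alu_distance, t.circ_id


class TestCompareDistributions:
    def test_identical_samples_give_p_one(self):
        stat, p = compare_distributions([1, 1, 1], [1, 1, 1], test="ks")
        assert stat == 0.0 and p == 1.0

    def test_exact_ranksum_on_toy_sets(self):
        """{1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 labelings,
        exact two-sided p = 2/20 = 0.1."""
        _, p = compare_distributions([1, 2, 3], [4, 5, 6], test="ranksum")
        assert p == pytest.approx(0.1)

    def test_ks_statistic_equals_ecdf_sup_difference(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            stat, _ = compare_distributions(x, y, test="ks")
            grid = np.concatenate([x, y])
            fx = np.array([(x <= v).mean() for v in grid])
            fy = np.array([(y <= v).mean() for v in grid])
            assert stat == pytest.approx(np.abs(fx - fy).max())

    def test_missing_values_removed_and_empty_rejected(self):
        stat, p = compare_distributions([1.0, None, 2.0], [1.5, np.nan, 2.5])
        assert 0 <= p <= 1
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])

    def test_ecdf_steps(self):
        x, f = ecdf([3.0, 1.0, 2.0])
        assert list(x) == [1.0, 2.0, 3.0]
        assert list(f) == pytest.approx([1 / 3, 2 / 3, 1.0])


class TestHostTranslation:
    def make_table(self, rng, n_aug, n_nonaug, ratio):
        rows = []
        for k in range(n_aug + n_nonaug):
            mean = 100.0 * (ratio if k < n_aug else 1.0)
            for s in range(4):
                rows.append((f"g{k}", f"s{s}", int(rng.poisson(mean))))
        df = pd.DataFrame(rows, columns=["gene_id", "sample_id",
                                         "psite_count"])
        aug = {f"g{k}" for k in range(n_aug)}
        non = {f"g{k}" for k in range(n_aug, n_aug + n_nonaug)}
        return df, aug, non

    def test_shared_gene_rejected(self):
        rng = np.random.default_rng(0)
        df, aug, non = self.make_table(rng, 5, 5, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            compare_host_translation(df, aug, aug)

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(0)
        df, aug, non = self.make_table(rng, 5, 5, 1.0)
        with pytest.raises(ValueError):
            compare_host_translation(df, set(), non)

    def test_null_calibration(self):
        """With both groups from the same distribution the p-value is
        roughly uniform (coarse check: rarely tiny)."""
        rng = np.random.default_rng(13)
        small = 0
        for rep in range(40):
            df, aug, non = self.make_table(rng, 30, 30, 1.0)
            out = compare_host_translation(df, aug, non)
            small += out.p_value < 0.05
        assert small <= 8

    def test_planted_reduction_detected_with_direction(self):
        """2x lower P-site counts in AUG hosts at n=150 per group is
        significant with direction AUG < non-AUG in nearly all runs."""
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(20):
            df, aug, non = self.make_table(rng, 150, 150, 0.5)
            out = compare_host_translation(df, aug, non)
            hits += (out.p_value < 0.05
                     and out.direction == "AUG < non-AUG")
        assert hits >= 19

    def test_direction_on_default_study(self, pipeline_run):
        _, report = pipeline_run
        tc = report["stages"]["aug"]["translation"]
        assert tc["direction"] == "AUG < non-AUG"
        assert tc["p_value"] < 0.05
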