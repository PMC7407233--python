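"""Exon-level differential usage and circRNA composition reconstruction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from circkit.annotation import load_annotation
from circkit.bsj import BsjCandidate
from circkit.exon_usage import (
    CircExonComposition, DEPLETED, INCONCLUSIVE, RESISTANT,
    annotation_vs_resistant_summary, compare_compositions,
    compose_circular_exons,
)
from circkit.exon_usage import test_exon_usage as run_exon_test


def exon_table(counts: dict[str, list[int]], gene="g1") -> pd.DataFrame:
    """counts: exon_id -> per-sample counts over u1,u2,u3,t1,t2,t3."""
    samples = [("u1", "untreated"), ("u2", "untreated"), ("u3", "untreated"),
               ("t1", "treated"), ("t2", "treated"), ("t3", "treated")]
    rows = []
    for e, (eid, ys) in enumerate(counts.items()):
        for (sid, grp), y in zip(samples, ys):
            rows.append((gene, eid, "chr1", 1000 * e, 1000 * e + 100,
                         sid, grp, y))
    return pd.DataFrame(rows, columns=["gene_id", "exon_id", "chrom", "start",
                                       "end", "sample_id", "group", "count"])


class TestExonUsageTest:
    def test_counts_proportional_to_totals_are_null(self):
        # exon is exactly 20% of the gene total in every sample
        tab = exon_table({
            "e1": [20, 40, 30, 10, 16, 12],
            "e2": [80, 160, 120, 40, 64, 48],
        })
        out = run_exon_test(tab)
        for r in out:
            assert abs(r.rel_logFC) < 1e-6
            assert r.status == INCONCLUSIVE

    def test_needs_two_samples_per_group(self):
        tab = exon_table({"e1": [5, 5, 5, 5, 5, 5]})
        tab = tab[tab["sample_id"] != "t2"]
        tab = tab[tab["sample_id"] != "t3"]
        with pytest.raises(ValueError, match="2 samples per group"):
            run_exon_test(tab)

    def test_all_zero_exons_skipped(self):
        tab = exon_table({"e1": [0, 0, 0, 0, 0, 0],
                          "e2": [10, 12, 9, 11, 10, 12]})
        out = run_exon_test(tab)
        assert {r.exon_id for r in out} == {"e2"}

    def test_poisson_limit_agrees_with_poisson_glm(self):
        """In the dispersion->0 limit the NB LRT matches a Poisson-GLM
        LRT within 1e-3 in p on 50 random exons."""
        from circkit.exon_usage import _nb_lrt

        rng = np.random.default_rng(1)
        checked = 0
        for k in range(50):
            totals = rng.poisson(2000, size=6).astype(float)
            w = rng.uniform(0.1, 0.3)
            y = rng.poisson(w * totals).astype(float)
            off = np.log(totals)
            g = np.array([False, False, False, True, True, True])
            _, _, p_nb = _nb_lrt(y, off, g, alpha=1e-8)
            X = np.column_stack([np.ones(6), g.astype(float)])
            fa = sm.GLM(y, X, family=sm.families.Poisson(),
                        offset=off).fit()
            f0 = sm.GLM(y, X[:, :1], family=sm.families.Poisson(),
                        offset=off).fit()
            p_pois = stats.chi2.sf(max(0, 2 * (fa.llf - f0.llf)), 1)
            assert p_nb == pytest.approx(p_pois, abs=1e-3)
            checked += 1
        assert checked == 50

    def test_sample_order_permutation_never_changes_status(self):
        rng = np.random.default_rng(2)
        tab = exon_table({
            "e1": list(rng.poisson(100, 6)),
            "e2": list(rng.poisson([300, 300, 300, 900, 900, 900])),
            "e3": list(rng.poisson(500, 6)),
        })
        base = {r.exon_id: r.status for r in run_exon_test(tab)}
        shuffled = tab.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert {r.exon_id: r.status
                for r in run_exon_test(shuffled)} == base

    def test_direction_of_status_calls(self):
        """A strong relative increase under treatment is resistant, the
        compensating exon is depleted."""
        tab = exon_table({
            "e1": [100, 110, 95, 400, 380, 420],
            "e2": [900, 890, 905, 600, 620, 580],
        })
        out = {r.exon_id: r for r in run_exon_test(tab)}
        assert out["e1"].status == RESISTANT and out["e1"].rel_logFC > 0
        assert out["e2"].status == DEPLETED and out["e2"].rel_logFC < 0


def make_composition(circ_id, annotated, resistant):
    return CircExonComposition(circ_id, annotated, resistant)


@pytest.fixture(scope="module")
def four_exon_gene(tmp_path_factory):
    # 4-exon plus-strand gene; circRNA spans all four exons
    gtf = tmp_path_factory.mktemp("comp") / "g.gtf"
    lines = ['chr1\tx\tgene\t101\t2000\t.\t+\t.\tgene_id "G";',
             'chr1\tx\ttranscript\t101\t2000\t.\t+\t.\t'
             'gene_id "G"; transcript_id "T";']
    exons = [(100, 200), (400, 500), (800, 900), (1500, 1600)]
    for s, e in exons:
        lines.append(f'chr1\tx\texon\t{s + 1}\t{e}\t.\t+\t.\t'
                     f'gene_id "G"; transcript_id "T";')
    gtf.write_text("\n".join(lines) + "\n")
    ann = load_annotation(gtf)
    cand = BsjCandidate("chr1", 100, 1600, "+", counts={"s": 5})
    cand.host_gene = "G"
    return ann, cand, exons


class TestComposition:

    def _results(self, exons, statuses):
        from circkit.exon_usage import ExonUsageResult

        return [ExonUsageResult("G", f"e{i}", "chr1", s, e,
                                1.0 if st == RESISTANT else -1.0, 0.01,
                                0.001, 0.01, st)
                for i, ((s, e), st) in enumerate(zip(exons, statuses))]

    def test_internal_exon_depleted_gives_skipped_composition(self, four_exon_gene):
        """Four annotated exons with exon 2 depleted reconstruct the
        {1,3,4} composition (internal alternative splicing)."""
        ann, cand, exons = four_exon_gene
        res = self._results(exons, [RESISTANT, DEPLETED, RESISTANT,
                                    RESISTANT])
        comp = compose_circular_exons(cand, res, ann)
        assert comp.annotated_exon_count == 4
        assert comp.resistant_indices == {1, 3, 4}

    def test_all_resistant(self, four_exon_gene):
        ann, cand, exons = four_exon_gene
        res = self._results(exons, [RESISTANT] * 4)
        comp = compose_circular_exons(cand, res, ann)
        assert comp.resistant_exon_count == comp.annotated_exon_count == 4

    def test_all_depleted_is_the_not_expressed_pattern(self, four_exon_gene):
        ann, cand, exons = four_exon_gene
        res = self._results(exons, [DEPLETED] * 4)
        comp = compose_circular_exons(cand, res, ann)
        assert comp.resistant_exon_count == 0
        assert comp.annotated_exon_count == 4

    def test_no_annotated_exon_inside_interval_is_flagged(self, four_exon_gene):
        ann, _, _ = four_exon_gene
        c = BsjCandidate("chr1", 210, 390, "+")
        c.host_gene = "G"
        comp = compose_circular_exons(c, [], ann)
        assert comp.annotated_exon_count == 0 and comp.approximate

    def test_resistant_never_exceeds_annotated(self, pipeline_run, sim_dir):
        """Structural invariant re-checked on the full synthetic study."""
        out, truth = sim_dir
        import pandas as pd

        ann = load_annotation(out / "annotation.gtf")
        results = run_exon_test(pd.read_csv(out / "exon_counts.tsv",
                                              sep="\t"))
        for t in truth.circs:
            if not t.host_gene or t.fail_mode:
                continue
            c = BsjCandidate(t.chrom, t.start, t.end, t.strand)
            c.host_gene = t.host_gene
            comp = compose_circular_exons(c, results, ann)
            assert comp.resistant_exon_count <= comp.annotated_exon_count


class TestCompareCompositions:
    def test_differential(self):
        a = make_composition("c", [(1, 2), (3, 4), (5, 6), (7, 8)],
                             [(1, 2), (5, 6), (7, 8)])
        b = make_composition("c", [(1, 2), (3, 4), (5, 6), (7, 8)],
                             [(1, 2), (3, 4), (5, 6), (7, 8)])
        assert compare_compositions(a, b) == "differential"

    def test_identical(self):
        a = make_composition("c", [(1, 2)], [(1, 2)])
        b = make_composition("c", [(1, 2)], [(1, 2)])
        assert compare_compositions(a, b) == "identical"

    def test_different_bsjs_not_comparable(self):
        a = make_composition("c1", [(1, 2)], [(1, 2)])
        b = make_composition("c2", [(1, 2)], [(1, 2)])
        assert compare_compositions(a, b) == "not_comparable"


class TestAnnotationVsResistant:
    def test_fully_resistant_gives_p_one(self):
        comps = [make_composition(f"c{i}", [(0, 1), (2, 3)], [(0, 1), (2, 3)])
                 for i in range(5)]
        out = annotation_vs_resistant_summary(comps)
        assert out["p_value"] == pytest.approx(1.0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="nothing to summarize"):
            annotation_vs_resistant_summary([])

    def test_planted_dropout_shifts_resistant_median_down(self):
        """30% exon dropout at n=300 gives a strongly significant
        annotated > resistant gap."""
        rng = np.random.default_rng(3)
        comps = []
        for i in range(300):
            n = int(rng.integers(3, 9))
            exons = [(100 * k, 100 * k + 50) for k in range(n)]
            kept = [ex for ex in exons if rng.random() > 0.3]
            comps.append(make_composition(f"c{i}", exons, kept))
        out = annotation_vs_resistant_summary(comps)
        assert out["median_resistant"] < out["median_annotated"]
        assert out["p_value"] < 0.001
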