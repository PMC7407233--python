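"""Benchmark scenarios: calibration, recovery and oracle-agreement studies.

Each function builds a synthetic study at the stated conditions, runs
the corresponding pipeline stage, and scores it — against planted truth
(calibration/recovery) or against a naive brute-force reference
implementation (oracle agreement). The brute-force references here are
deliberately simple re-statements of the definitions (per-base liftover
maps, all-pairs overlap) kept independent of the optimized code paths
they validate.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
import numpy as np
import pandas as pd

from .bsj import BsjCandidate
from .conservation import (Chain, ChainMap, LiftResult, lift_bsj, MAPPED,
                           UNMAPPED, SPLIT, STRAND_INCONSISTENT,
                           shared_fraction)
from .enrichment import CircLinearCounts, run_enrichment
from .exon_usage import RESISTANT, test_exon_usage
from .simulate import SimulationConfig, simulate_all, simulate_circ_counts
from .tracks import Peak, overlap_peaks


def huvec_shared_fraction(total: int = 2073, exclusive: int = 252) -> dict:
    """Shared fraction of an enriched circRNA set from its printed total
    and exclusive counts, computed through the set-overlap machinery:
    a set of `total` members of which `total - exclusive` also occur in
    the union of the other systems."""
    from .tracks import set_overlap_report

    a = {f"c{i}" for i in range(total)}
    others = {f"c{i}" for i in range(total - exclusive)} | {"other_only"}
    rep = set_overlap_report(a, others)
    frac = rep["fraction_a"]
    assert abs(frac - shared_fraction(total, exclusive)) < 1e-12
    return {"total": total, "exclusive": exclusive,
            "shared_fraction_pct": 100.0 * frac}


# ------------------------------------------------ default-study fixtures

def _default_study(seed: int, **overrides):
    """Simulate the default synthetic study into a temp dir."""
    cfg = SimulationConfig(seed=seed, **overrides)
    out = Path(tempfile.mkdtemp(prefix="circkit_scenario_"))
    truth = simulate_all(cfg, out)
    return out, truth


def filter_fixture_agreement(seed: int) -> dict:
    """Survivors of the default candidate filter vs generator truth
    (exact set equality)."""
    from .bsj import (FilterParams, call_bsjs, filter_candidates,
                      load_mask_bed, read_junction_tsv)
    from .pipeline import attach_linear_counts

    out, truth = _default_study(seed)
    counts_df = pd.read_csv(out / "circ_linear_counts.tsv", sep="\t")
    cands = call_bsjs(read_junction_tsv(out / "junctions.tsv"))
    attach_linear_counts(cands, counts_df)
    untreated = set(counts_df.loc[counts_df["group"] == "untreated",
                                  "sample_id"])
    survivors = filter_candidates(cands, FilterParams(
        mask_intervals=load_mask_bed(out / "mask.bed"),
        untreated_samples=untreated))
    got = {c.key for c in survivors}
    expected = {(c.chrom, c.start, c.end, c.strand)
                for c in truth.circs if c.expected_pass_filter}
    return {"n_expected": len(expected), "n_got": len(got),
            "exact_match": got == expected,
            "agreement": 1.0 if got == expected else 0.0}


def aug_truth_agreement(seed: int) -> dict:
    """AUG classification vs planted truth on the default annotation."""
    from .annotation import load_annotation
    from .aug import classify_aug

    out, truth = _default_study(seed)
    ann = load_annotation(out / "annotation.gtf")
    n = agree = 0
    for t in truth.circs:
        if t.fail_mode:
            continue
        c = BsjCandidate(t.chrom, t.start, t.end, t.strand)
        c.host_gene = t.host_gene
        n += 1
        agree += classify_aug(c, ann).is_aug == t.is_aug
    return {"n": n, "agreement": agree / n}


def _aug_feature_pvalues(out, truth) -> dict:
    from .annotation import load_annotation
    from .aug import (alu_pair_distance, compare_distributions,
                      flanking_intron_lengths, load_alu_bed)

    ann = load_annotation(out / "annotation.gtf")
    alu = load_alu_bed(out / "alu.bed")
    feats = {"aug": {"alu": [], "intron": []},
             "nonaug": {"alu": [], "intron": []}}
    for t in truth.circs:
        if not t.host_gene or t.fail_mode:
            continue
        c = BsjCandidate(t.chrom, t.start, t.end, t.strand)
        c.host_gene = t.host_gene
        key = "aug" if t.is_aug else "nonaug"
        d = alu_pair_distance(c, alu)
        if d is not None:
            feats[key]["alu"].append(d)
        up, down, _ = flanking_intron_lengths(c, ann)
        for v in (up, down):
            if v is not None:
                feats[key]["intron"].append(v)
    result = {}
    for feature in ("alu", "intron"):
        a, b = feats["aug"][feature], feats["nonaug"][feature]
        stat, p = compare_distributions(a, b, test="ks")
        result[feature] = {
            "p_value": p,
            "aug_larger": float(np.median(a)) > float(np.median(b)),
        }
    return result


def aug_feature_direction(seed: int) -> dict:
    """KS comparison of Alu-pair distances and flanking intron lengths,
    AUG vs non-AUG, on the default planted geometry."""
    out, truth = _default_study(seed)
    return _aug_feature_pvalues(out, truth)


def aug_feature_null_rate(seed: int, n_seeds: int = 20,
                          threshold: float = 0.01) -> dict:
    """Fraction of flat-geometry (null) replicates on which both feature
    KS tests stay non-significant."""
    ok = 0
    for k in range(n_seeds):
        out, truth = _default_study(seed + 1000 + k, alu_flat_geometry=True)
        res = _aug_feature_pvalues(out, truth)
        ok += (res["alu"]["p_value"] >= threshold
               and res["intron"]["p_value"] >= threshold)
    return {"n_seeds": n_seeds, "nonssignificant_fraction": ok / n_seeds}


def composition_accuracy(seed: int) -> dict:
    """Fraction of hosted circRNAs whose reconstructed resistant-exon
    composition equals the planted one on the default study."""
    from .annotation import load_annotation
    from .exon_usage import compose_circular_exons

    out, truth = _default_study(seed)
    ann = load_annotation(out / "annotation.gtf")
    results = test_exon_usage(pd.read_csv(out / "exon_counts.tsv", sep="\t"))
    n = hit = 0
    for t in truth.circs:
        if not t.host_gene or t.fail_mode:
            continue
        c = BsjCandidate(t.chrom, t.start, t.end, t.strand)
        c.host_gene = t.host_gene
        comp = compose_circular_exons(c, results, ann)
        n += 1
        hit += sorted(comp.resistant_exons) == sorted(t.included_exons)
    return {"n": n, "accuracy": hit / n}


def ranksum_exact_check() -> dict:
    """Exact two-sided rank-sum p for {1,2,3} vs {4,5,6} (enumeration
    over the 20 labelings gives 0.1)."""
    from .aug import compare_distributions

    _, p = compare_distributions([1, 2, 3], [4, 5, 6], test="ranksum")
    return {"p_value": p}


# ------------------------------------------------- beta-binomial studies

def betabinomial_null_calibration(seed: int, n_circ: int = 1000,
                                  depth: float = 100.0, fraction: float = 0.1,
                                  rho: float = 0.01,
                                  n_samples_per_group: int = 3) -> dict:
    """Type-I error of the enrichment test on null circRNAs (no group
    difference). Returns the empirical P(p < 0.05)."""
    rng = np.random.default_rng([seed, 11])
    tables = []
    for k in range(n_circ):
        c, l, g = simulate_circ_counts(rng, n_samples_per_group, depth,
                                       fraction, fraction, rho)
        tables.append(CircLinearCounts(f"null{k}", c, l, g))
    results = run_enrichment(tables)
    ps = np.array([r.p_value for r in results if r.p_value is not None])
    return {
        "n_tested": int(len(ps)),
        "type1_rate": float(np.mean(ps < 0.05)),
    }


def enrichment_recovery(seed: int, n_null: int = 800, n_planted: int = 200,
                        depth: float = 200.0, mu0: float = 0.1,
                        mu1: float = 0.6, rho: float = 0.01,
                        alpha: float = 0.05,
                        n_samples_per_group: int = 3) -> dict:
    """Sensitivity and empirical FDR for planted fraction shifts
    (mu0 -> mu1 under treatment) among null circRNAs at q < alpha."""
    rng = np.random.default_rng([seed, 12])
    tables, truth = [], {}
    for k in range(n_planted + n_null):
        planted = k < n_planted
        c, l, g = simulate_circ_counts(rng, n_samples_per_group, depth,
                                       mu0, mu1 if planted else mu0, rho)
        cid = f"c{k}"
        tables.append(CircLinearCounts(cid, c, l, g))
        truth[cid] = planted
    results = run_enrichment(tables, alpha=alpha)
    called = {r.circ_id for r in results if r.enriched}
    tp = sum(1 for c in called if truth[c])
    fp = len(called) - tp
    return {
        "sensitivity": tp / n_planted,
        "fdr": fp / max(len(called), 1),
        "n_called": len(called),
    }


# --------------------------------------------------- exon usage recovery

def simulate_exon_recovery_table(seed: int, n_genes: int = 50,
                                 exons_per_gene: int = 10,
                                 planted_per_gene: int = 2,
                                 depth_gene: float = 1000.0,
                                 uplift: float = 4.0,
                                 gene_depletion: float = 0.3,
                                 dispersion: float = 0.02,
                                 n_samples_per_group: int = 3
                                 ) -> tuple[pd.DataFrame, set[str]]:
    """NB exon count table with `planted_per_gene` exons per gene whose
    relative usage rises `uplift`-fold under treatment; the remaining
    exons follow the global linear depletion only. Returns (table,
    planted exon ids)."""
    rng = np.random.default_rng([seed, 13])
    rows, planted = [], set()
    samples = ([(f"u{j}", "untreated") for j in range(n_samples_per_group)]
               + [(f"t{j}", "treated") for j in range(n_samples_per_group)])
    for gi in range(n_genes):
        gid = f"g{gi:03d}"
        w = rng.uniform(0.7, 1.3, size=exons_per_gene)
        w = w / w.sum()
        for e in range(exons_per_gene):
            eid = f"{gid}_e{e}"
            is_planted = e < planted_per_gene
            if is_planted:
                planted.add(eid)
            for sample_id, group in samples:
                mean = depth_gene * w[e]
                if group == "treated":
                    mean *= gene_depletion * (uplift if is_planted else 1.0)
                lam = rng.gamma(1.0 / dispersion, dispersion * mean)
                rows.append((gid, eid, "chr1", 1000 * e, 1000 * e + 200,
                             sample_id, group, int(rng.poisson(lam))))
    table = pd.DataFrame(rows, columns=["gene_id", "exon_id", "chrom",
                                        "start", "end", "sample_id", "group",
                                        "count"])
    return table, planted


def exon_usage_recovery(seed: int, alpha: float = 0.05, **kwargs) -> dict:
    """Recovery of planted relative-usage shifts: fraction of planted
    exons called resistant (correct direction) and the empirical FDR of
    the resistant calls."""
    table, planted = simulate_exon_recovery_table(seed, **kwargs)
    results = test_exon_usage(table, alpha=alpha)
    called = {r.exon_id for r in results if r.status == RESISTANT}
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted),
        "fdr": (len(called) - tp) / max(len(called), 1),
        "n_called": len(called),
        "n_planted": len(planted),
    }


# --------------------------------------------------- liftover oracle

def random_chain_map(rng: np.random.Generator, chrom_len: int = 10_000,
                     t_size: int = 50_000) -> ChainMap:
    """Random chain map over one source chromosome: 1-4 chains with an
    offset/gap/inversion mix, random scores, possibly overlapping."""
    chains = []
    n_chains = int(rng.integers(1, 5))
    for cid in range(1, n_chains + 1):
        s = int(rng.integers(0, chrom_len - 2000))
        t_strand = "-" if rng.random() < 0.3 else "+"
        n_blocks = int(rng.integers(1, 5))
        blocks = []
        t = int(rng.integers(0, t_size - chrom_len - 1000))
        s_pos, t_pos = s, t
        for b in range(n_blocks):
            size = int(rng.integers(50, 600))
            if s_pos + size > chrom_len:
                break
            blocks.append((s_pos, size, t_pos))
            dt = int(rng.integers(0, 300))
            dq = int(rng.integers(0, 300))
            s_pos += size + dt
            t_pos += size + dq
        if not blocks:
            continue
        s_end = blocks[-1][0] + blocks[-1][1]
        t_end = blocks[-1][2] + blocks[-1][1]
        chains.append(Chain(
            chain_id=cid, score=float(rng.integers(1, 1000)),
            s_chrom="chrS", s_size=chrom_len, s_start=blocks[0][0],
            s_end=s_end, t_chrom="chrT", t_size=t_size, t_strand=t_strand,
            t_start=blocks[0][2], t_end=t_end))
        chains[-1].blocks = blocks
        chains[-1].__post_init__()
    return ChainMap(chains)


def _per_base_map(cm: ChainMap, chrom_len: int):
    """Brute-force per-base source->target map: for every base the
    best covering chain (max score, then lowest id) and its target
    coordinate, built by filling arrays block by block."""
    score = np.full(chrom_len, -np.inf)
    cid = np.full(chrom_len, -1, dtype=int)
    tpos = np.full(chrom_len, -1, dtype=int)
    tstrand = np.zeros(chrom_len, dtype=int)  # 0 '+', 1 '-'
    for c in sorted(cm.chains, key=lambda c: (c.score, -c.chain_id)):
        for s0, size, t0 in c.blocks:
            span = slice(s0, s0 + size)
            better = np.full(size, True)
            prev = score[span]
            better = (c.score > prev) | ((c.score == prev)
                                         & (c.chain_id < cid[span]))
            t = t0 + np.arange(size)
            if c.t_strand == "-":
                t = c.t_size - 1 - t
            score[span] = np.where(better, c.score, prev)
            cid[span] = np.where(better, c.chain_id, cid[span])
            tpos[span] = np.where(better, t, tpos[span])
            tstrand[span] = np.where(better, c.t_strand == "-",
                                     tstrand[span])
    return cid, tpos, tstrand


def brute_force_lift(cand: BsjCandidate, cm: ChainMap,
                     per_base=None) -> LiftResult:
    """Independent per-base re-statement of the endpoint-lift rule."""
    chrom_len = max((c.s_end for c in cm.chains), default=0) + 1
    if per_base is None:
        per_base = _per_base_map(cm, chrom_len)
    cid, tpos, tstrand = per_base
    p1, p2 = cand.start, cand.end - 1
    if p1 >= len(cid) or p2 >= len(cid) or cid[p1] < 0 or cid[p2] < 0:
        return LiftResult(cand.circ_id, UNMAPPED)
    if cid[p1] != cid[p2]:
        ch1 = next(c for c in cm.chains if c.chain_id == cid[p1])
        ch2 = next(c for c in cm.chains if c.chain_id == cid[p2])
        if ch1.t_chrom != ch2.t_chrom or ch1.t_strand != ch2.t_strand:
            return LiftResult(cand.circ_id, STRAND_INCONSISTENT)
        return LiftResult(cand.circ_id, SPLIT)
    ch = next(c for c in cm.chains if c.chain_id == cid[p1])
    lo, hi = sorted((int(tpos[p1]), int(tpos[p2])))
    strand = cand.strand
    if tstrand[p1]:
        strand = "-" if strand == "+" else "+"
    return LiftResult(cand.circ_id, MAPPED, ch.t_chrom, lo, hi + 1, strand,
                      ch.chain_id)


def liftover_oracle_agreement(seed: int, n_maps: int = 100,
                              intervals_per_map: int = 10,
                              chrom_len: int = 10_000) -> dict:
    """Fraction of random (interval, chain-map) lifts on which the block
    arithmetic agrees with the per-base brute force, statuses included."""
    rng = np.random.default_rng([seed, 14])
    n_total = n_agree = 0
    for m in range(n_maps):
        cm = random_chain_map(rng, chrom_len=chrom_len)
        per_base = _per_base_map(cm, chrom_len + 1)
        for k in range(intervals_per_map):
            s = int(rng.integers(0, chrom_len - 10))
            e = s + int(rng.integers(2, min(3000, chrom_len - s)))
            cand = BsjCandidate("chrS", s, e, "+" if rng.random() < 0.5
                                else "-")
            a = lift_bsj(cand, cm)
            b = brute_force_lift(cand, cm, per_base)
            n_total += 1
            n_agree += (a.status, a.chrom, a.start, a.end, a.strand) == \
                       (b.status, b.chrom, b.start, b.end, b.strand)
    return {"n": n_total, "agreement": n_agree / n_total}


# --------------------------------------------------- overlap oracle

def brute_force_overlap(cands, peaks) -> tuple[dict[str, int], dict[int, int]]:
    """O(n*m) all-pairs restatement of half-open interval overlap."""
    per_circ = {c.circ_id: 0 for c in cands}
    per_peak = {i: 0 for i in range(len(peaks))}
    for c in cands:
        for i, p in enumerate(peaks):
            if p.chrom == c.chrom and p.start < c.end and p.end > c.start:
                per_circ[c.circ_id] += 1
                per_peak[i] += 1
    return per_circ, per_peak


def overlap_oracle_agreement(seed: int, n_circ: int = 300,
                             n_peaks: int = 500) -> dict:
    """Exact equality of the indexed overlap engine with brute force on
    random circ/peak fixtures."""
    rng = np.random.default_rng([seed, 15])
    cands = []
    for k in range(n_circ):
        chrom = f"chr{int(rng.integers(1, 4))}"
        s = int(rng.integers(0, 100_000))
        cands.append(BsjCandidate(chrom, s, s + int(rng.integers(100, 5000)),
                                  "+"))
    peaks = []
    for k in range(n_peaks):
        chrom = f"chr{int(rng.integers(1, 4))}"
        s = int(rng.integers(0, 100_000))
        peaks.append(Peak(chrom, s, s + int(rng.integers(20, 400))))
    fast = overlap_peaks(cands, peaks)
    slow = brute_force_overlap(cands, peaks)
    return {"n_pairs": n_circ * n_peaks, "agree": fast == slow,
            "agreement": 1.0 if fast == slow else 0.0}
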