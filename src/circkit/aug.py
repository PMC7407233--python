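"""AUG circRNA classification and genomic flank features.

An AUG circRNA contains the start codon of its host gene's canonical
coding sequence within the BSJ interval, so the circle carries a
potential translation start. This module classifies candidates, measures
the genomic features that distinguish the class — flanking intron
lengths and the distance to the nearest pair of reverse-complementary
Alu repeats (inverted Alu pairs promote back-splicing by bringing the
splice sites together) — and compares feature and expression
distributions between classes with KS and Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GenomeAnnotation, canonical_cds_start
from .bsj import BsjCandidate


@dataclass
class AugCall:
    circ_id: str
    is_aug: bool
    cds_start: Optional[int] = None


@dataclass
class FlankFeatures:
    circ_id: str
    upstream_intron_len: Optional[int] = None
    downstream_intron_len: Optional[int] = None
    alu_pair_distance: Optional[int] = None
    approximate: bool = False


def classify_aug(cand: BsjCandidate, ann: GenomeAnnotation) -> AugCall:
    """is_aug iff the host gene is coding and its canonical CDS start
    codon (first base) lies inside [start, end). Depends only on the BSJ
    interval and the annotation, never on exon composition."""
    if cand.host_gene is None:
        return AugCall(cand.circ_id, False)
    gene = ann.genes[cand.host_gene]
    pos = canonical_cds_start(gene)
    if pos is None:
        return AugCall(cand.circ_id, False)
    return AugCall(cand.circ_id, cand.start <= pos < cand.end, pos)


def flanking_intron_lengths(cand: BsjCandidate, ann: GenomeAnnotation
                            ) -> tuple[Optional[int], Optional[int], bool]:
    """Lengths of the introns flanking the circRNA in transcription order.

    Upstream = the intron immediately 5' of the circ's first exon,
    downstream = immediately 3' of its last exon; missing (None) at
    terminal exons. When a BSJ boundary does not coincide with an
    annotated exon boundary, the nearest enclosing exon boundaries are
    used and the result is flagged approximate (third return value).
    """
    if cand.host_gene is None:
        raise ValueError(f"{cand.circ_id}: host gene not assigned")
    gene = ann.genes[cand.host_gene]
    exons = sorted(gene.canonical_transcript.exons)  # genomic order
    starts = {s for s, _ in exons}
    ends = {e for _, e in exons}
    approximate = cand.start not in starts or cand.end not in ends
    # exon index containing (or nearest to) each genomic boundary
    left_i = max((i for i, (s, e) in enumerate(exons) if s <= cand.start),
                 default=0)
    right_i = min((i for i, (s, e) in enumerate(exons) if e >= cand.end),
                  default=len(exons) - 1)

    def intron_before(i: int) -> Optional[int]:
        if i == 0:
            return None
        return exons[i][0] - exons[i - 1][1]

    def intron_after(i: int) -> Optional[int]:
        if i == len(exons) - 1:
            return None
        return exons[i + 1][0] - exons[i][1]

    left_len = intron_before(left_i)
    right_len = intron_after(right_i)
    if gene.strand == "+":
        up, down = left_len, right_len
    else:
        up, down = right_len, left_len
    return up, down, approximate


def load_alu_bed(path) -> dict[str, IntervalTree]:
    """Strand-annotated Alu BED6 into per-chrom interval trees; the
    payload is the strand."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            trees.setdefault(f[0], IntervalTree()).addi(
                int(f[1]), int(f[2]), f[5] if len(f) > 5 else ".")
    return trees


def alu_pair_distance(cand: BsjCandidate,
                      alu: dict[str, IntervalTree],
                      window: int = 100_000) -> Optional[int]:
    """Distance to the nearest reverse-complementary Alu pair.

    Candidate pairs are (upstream Alu ending at or before the circ start
    within `window`, downstream Alu starting at or after the circ end
    within `window`) with opposite strands — the inverted-repeat geometry
    that loops the locus for back-splicing. The distance of a pair is
    (start - upstream_end) + (downstream_start - end); the minimum over
    all opposite-strand pairs is returned, None when no such pair exists.
    """
    tree = alu.get(cand.chrom)
    if tree is None:
        return None
    ups = [(iv.end, iv.data) for iv in tree.overlap(cand.start - window, cand.start)
           if iv.end <= cand.start and iv.data in "+-"]
    downs = [(iv.begin, iv.data) for iv in tree.overlap(cand.end, cand.end + window)
             if iv.begin >= cand.end and iv.data in "+-"]
    best: Optional[int] = None
    for u_end, u_strand in ups:
        for d_start, d_strand in downs:
            if u_strand == d_strand:
                continue
            d = (cand.start - u_end) + (d_start - cand.end)
            if best is None or d < best:
                best = d
    return best


def noncirc_gene_anchor(gene) -> tuple[int, int]:
    """Flank anchor for mRNAs hosting no detected circRNA.

    The comparison of Alu distances and intron lengths needs an interval
    to anchor on for genes without circRNAs; we use the genomic span of
    the gene's longest internal consecutive exon pair (terminal exons
    excluded), a placeholder choice reported as such."""
    exons = sorted(gene.canonical_transcript.exons)
    if len(exons) < 4:
        return (exons[0][0], exons[-1][1])
    internal = exons[1:-1]
    best = max(range(len(internal) - 1),
               key=lambda i: internal[i + 1][1] - internal[i][0])
    return (internal[best][0], internal[best + 1][1])


def compare_distributions(x: Sequence[float], y: Sequence[float],
                          test: str = "ks") -> tuple[float, float]:
    """Two-sided comparison of two samples, KS or Wilcoxon rank-sum.

    Missing values (None/NaN) are removed; identical constant samples
    give p = 1. Rank-sum uses the exact null when both samples are small
    so toy inputs match hand enumeration."""
    x = np.asarray([v for v in x if v is not None], dtype=float)
    y = np.asarray([v for v in y if v is not None], dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each group must be nonempty")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 0.0, 1.0
    if test == "ks":
        res = stats.ks_2samp(x, y, method="asymp")
    elif test == "ranksum":
        method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Step ECDF (x sorted, F(x)) for expression-distribution plots."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, len(v) + 1) / len(v)


@dataclass
class TranslationComparison:
    n_aug: int
    n_nonaug: int
    median_aug: float
    median_nonaug: float
    statistic: float
    p_value: float
    direction: str  # "AUG < non-AUG", "AUG > non-AUG" or "none"


def compare_host_translation(psite_table, aug_hosts: set[str],
                             nonaug_hosts: set[str]) -> TranslationComparison:
    """Rank-sum comparison of per-gene ribosome P-site counts between
    AUG-circRNA host genes and non-AUG host genes.

    P-site counts quantify translation; the table is long format
    (gene_id, sample_id, psite_count) and is normalized to counts per
    million of each P-site library before per-gene averaging. The two
    host-gene groups must be disjoint and nonempty.
    """
    shared = aug_hosts & nonaug_hosts
    if shared:
        raise ValueError(f"host-gene groups overlap: {sorted(shared)[:5]}")
    if not aug_hosts or not nonaug_hosts:
        raise ValueError("both host-gene groups must be nonempty")
    df = psite_table.copy()
    lib = df.groupby("sample_id")["psite_count"].transform("sum")
    df["cpm"] = df["psite_count"] / lib * 1e6
    per_gene = df.groupby("gene_id")["cpm"].mean()
    a = per_gene.reindex(sorted(aug_hosts)).dropna().to_numpy()
    b = per_gene.reindex(sorted(nonaug_hosts)).dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a host-gene group has no P-site data")
    stat, p = stats.ranksums(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a < med_b:
        direction = "AUG < non-AUG"
    elif med_a > med_b:
        direction = "AUG > non-AUG"
    else:
        direction = "none"
    return TranslationComparison(len(a), len(b), med_a, med_b,
                                 float(stat), float(p), direction)
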