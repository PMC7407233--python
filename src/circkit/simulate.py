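"""Synthetic CircleSeq study generator with planted ground truth.

Emulates a paired RNase R-treated/untreated design over toy genomes:
an Ensembl-dialect GTF annotation, chimeric junction records, circular/
linear and exon-level count tables drawn from the same beta-binomial and
negative-binomial models the pipeline fits, Alu/Ago2 tracks, m6A IP
counts, ribosome-footprint junctions, P-site tables, and cross-species
chain files with planted liftover outcomes. Every emitted record traces
to a truth row, so each pipeline stage can be scored against a known
answer.

Randomness is organized as sub-streams keyed by (seed, domain, record
index), so adding records never reshuffles existing ones, and the same
config+seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

# domain codes for sub-stream derivation
_D_GENOME, _D_COUNTS, _D_EXONS, _D_TRACKS, _D_CHAINS, _D_PSITES = range(6)

SPECIES_TARGETS = ("pig", "mouse")


def _rng(seed: int, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, domain, index])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic CircleSeq experiment.

    Defaults follow the emulated design: 3 treated + 3 untreated
    libraries per cell model, circular fractions near 0.1 that rise to
    0.6 for truly RNase R-enriched circRNAs, mild replicate
    overdispersion (rho 0.01), 4x relative uplift of circRNA exons under
    treatment, and two extra species for liftover."""

    seed: int
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (10, 14)
    n_circ: int = 60
    max_circ_exons: int = 3          # span cap keeps relative uplift plantable
    fraction_enriched: float = 0.6
    fraction_aug: float = 0.3
    circ_fraction_untreated: float = 0.1
    circ_fraction_treated_enriched: float = 0.6
    rho: float = 0.01
    exon_dropout_rate: float = 0.2
    fraction_fully_depleted: float = 0.08
    depth_circ: int = 150            # mean circ+linear junction total per sample
    depth_gene: int = 1000           # mean exon-count total per gene per sample
    exon_uplift: float = 4.0         # relative usage fold for circ exons, treated
    gene_depletion: float = 0.3      # linear-RNA survival under RNase R
    n_samples_per_group: int = 3
    alt_splicing_rate: float = 0.034
    n_filter_fail: int = 8
    n_antisense: int = 2
    n_intergenic: int = 1
    n_species: int = 2
    fraction_conserved: float = 0.4
    fraction_target_enriched: float = 0.7
    alu_nonaug_mean: float = 2000.0
    alu_aug_mean: float = 6000.0
    alu_flat_geometry: bool = False  # equal Alu/intron geometry for both classes
    fraction_ago2: float = 0.3
    fraction_m6a: float = 0.25
    fraction_ribo: float = 0.2
    psite_base_mean: float = 200.0
    psite_aug_ratio: float = 0.5
    library_size: int = 20_000_000

    def __post_init__(self):
        for name in ("fraction_enriched", "fraction_aug", "exon_dropout_rate",
                     "fraction_fully_depleted", "fraction_conserved",
                     "fraction_target_enriched", "fraction_ago2",
                     "fraction_m6a", "fraction_ribo", "alt_splicing_rate",
                     "circ_fraction_untreated", "circ_fraction_treated_enriched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @property
    def samples(self) -> list[tuple[str, str]]:
        n = self.n_samples_per_group
        return ([(f"untreated_{i+1}", "untreated") for i in range(n)]
                + [(f"treated_{i+1}", "treated") for i in range(n)])


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]     # transcription order
    cds_start: Optional[int]         # genomic pos of start-codon base 1
    cds_span: Optional[tuple[int, int]]
    coding: bool
    aug_class: bool                  # long-intron AUG-host gene class
    alt_transcript: bool


@dataclass
class CircTruth:
    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene: Optional[str]
    localization: str
    member_exons: list[tuple[int, int]] = field(default_factory=list)
    included_exons: list[tuple[int, int]] = field(default_factory=list)
    enriched: bool = False
    is_aug: bool = False
    upstream_intron: Optional[int] = None
    downstream_intron: Optional[int] = None
    alu_distance: Optional[int] = None
    counts: dict = field(default_factory=dict)
    linear_counts: dict = field(default_factory=dict)
    expected_pass_filter: bool = True
    fail_mode: Optional[str] = None
    alt_variant: bool = False
    ago2_peaks: int = 0
    m6a_flag: bool = False
    ribo_flag: bool = False
    lift: dict = field(default_factory=dict)   # species -> expected LiftResult


@dataclass
class SimulationTruth:
    config: SimulationConfig
    genes: list[GeneTruth] = field(default_factory=list)
    circs: list[CircTruth] = field(default_factory=list)
    mask_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    library_sizes: dict = field(default_factory=dict)
    alus: list[tuple[str, int, int, str]] = field(default_factory=list)

    def circ(self, circ_id: str) -> CircTruth:
        return next(c for c in self.circs if c.circ_id == circ_id)


# ---------------------------------------------------------------- genome

_CHROM_SIZE = 10_000_000
_GENE_GAP = 40_000
_FIRST_GENE_POS = 200_000
_DECOY_ALU_REGION = (0, 20_000)


def simulate_annotation(cfg: SimulationConfig) -> SimulationTruth:
    """Lay out the toy genome: genes with exon/intron geometry, CDS and
    UTRs, a second (non-canonical) transcript on every fifth gene, and
    one noncoding gene per ten. AUG-class genes draw longer introns (the
    planted Fig-5-style geometry) unless alu_flat_geometry is set."""
    truth = SimulationTruth(config=cfg)
    rng = _rng(cfg.seed, _D_GENOME)
    cursor = {"chr1": _FIRST_GENE_POS, "chr2": _FIRST_GENE_POS}
    lo, hi = cfg.exons_per_gene
    if lo < 6:
        raise ValueError("exons_per_gene lower bound must be >= 6 "
                         "(need internal exons for circ placement)")
    if lo > hi:
        raise ValueError("exons_per_gene range is empty")
    n_aug_genes = int(round(cfg.fraction_aug * cfg.n_genes))
    for gi in range(cfg.n_genes):
        g_rng = _rng(cfg.seed, _D_GENOME, gi + 1)
        chrom = "chr1" if gi % 2 == 0 else "chr2"
        strand = "+" if g_rng.random() < 0.5 else "-"
        noncoding = (gi % 10 == 9)
        aug_class = (gi < n_aug_genes) and not noncoding
        n_ex = int(g_rng.integers(lo, hi + 1))
        ex_lens = g_rng.integers(120, 281, size=n_ex)
        if aug_class and not cfg.alu_flat_geometry:
            in_lens = g_rng.integers(3000, 8001, size=n_ex - 1)
        else:
            in_lens = g_rng.integers(300, 1501, size=n_ex - 1)
        pos = cursor[chrom]
        exons_genomic = []
        for k in range(n_ex):
            exons_genomic.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        g_start, g_end = exons_genomic[0][0], exons_genomic[-1][1]
        cursor[chrom] = g_end + _GENE_GAP
        # transcription order
        tx_exons = exons_genomic if strand == "+" else exons_genomic[::-1]
        cds_start = cds_span = None
        if not noncoding:
            # start codon 30 bp into the second exon (transcription order),
            # stop inside the second-to-last exon
            e2 = tx_exons[1]
            e_pen = tx_exons[-2]
            if strand == "+":
                cds_start = e2[0] + 30
                cds_span = (cds_start, e_pen[1] - 30)
            else:
                cds_start = e2[1] - 1 - 30
                cds_span = (e_pen[0] + 30, cds_start + 1)
        truth.genes.append(GeneTruth(
            gene_id=f"G{gi:03d}", chrom=chrom, strand=strand,
            start=g_start, end=g_end, exons=tx_exons,
            cds_start=cds_start, cds_span=cds_span, coding=not noncoding,
            aug_class=aug_class, alt_transcript=(gi % 5 == 4 and not noncoding),
        ))
    _plan_circs(cfg, truth, rng)
    return truth


def _circ_interval(exons_tx: list[tuple[int, int]], i: int, j: int
                   ) -> tuple[int, int]:
    """Genomic interval spanned by transcription-order exons i..j (0-based
    inclusive)."""
    chosen = exons_tx[i:j + 1]
    return min(s for s, _ in chosen), max(e for _, e in chosen)


def _plan_circs(cfg: SimulationConfig, truth: SimulationTruth,
                rng: np.random.Generator) -> None:
    if cfg.n_circ == 0:
        return
    coding = [g for g in truth.genes if g.coding]
    if not coding:
        raise ValueError("cannot place circRNAs: no coding genes configured")
    aug_genes = [g for g in coding if g.aug_class]
    non_genes = [g for g in coding if not g.aug_class]
    n_hosted = cfg.n_circ - cfg.n_antisense - cfg.n_intergenic
    n_aug = int(round(cfg.fraction_aug * n_hosted))
    if n_aug > 0 and not aug_genes:
        raise ValueError("fraction_aug > 0 but no AUG-class genes available")
    if n_hosted - n_aug > 0 and not non_genes:
        raise ValueError("no non-AUG genes available for non-AUG circRNAs")
    n_pairs = max(1, round(cfg.alt_splicing_rate * cfg.n_circ / 2)) \
        if cfg.alt_splicing_rate > 0 else 0

    plans: list[tuple[GeneTruth, bool]] = []   # (gene, is_aug)
    for k in range(n_aug):
        plans.append((aug_genes[k % len(aug_genes)], True))
    # reserve a few single-circ genes: the chain generator anchors its
    # exotic liftover geometries (gap/split/inversion) on them
    n_non = n_hosted - n_aug
    reserved = non_genes[-5:] if len(non_genes) >= 8 and n_non > 5 else []
    regular = non_genes[:-len(reserved)] if reserved else non_genes
    for k in range(n_non - len(reserved)):
        plans.append((regular[k % len(regular)], False))
    for g in reserved:
        plans.append((g, False))
    # alternative-splicing partners share the host gene of the preceding
    # circ (and its start coordinate)
    for ci in range(1, min(2 * n_pairs, len(plans)), 2):
        plans[ci] = plans[ci - 1]

    n_enriched = int(round(cfg.fraction_enriched * cfg.n_circ))
    used_spans: dict[str, set[tuple[int, int]]] = {}
    pair_anchor: dict[int, tuple[int, int]] = {}  # anchor ci -> (i, j)
    ci = 0
    for gene, is_aug in plans:
        c_rng = _rng(cfg.seed, _D_GENOME, 10_000 + ci)
        n_ex = len(gene.exons)
        make_pair_partner = (ci < 2 * n_pairs and ci % 2 == 1
                             and (ci - 1) in pair_anchor)
        for _attempt in range(50):
            if make_pair_partner:
                i0, j_prev = pair_anchor[ci - 1]
                j_hi = min(i0 + cfg.max_circ_exons - 1, n_ex - 2)
                i, j = i0, int(c_rng.integers(i0 + 1, j_hi + 1))
                if j == j_prev:
                    continue
            elif is_aug:
                # any short span covering the start-codon exon (tx index 1)
                i = int(c_rng.integers(0, 2))
                j_hi = min(i + cfg.max_circ_exons - 1, n_ex - 2)
                j = int(c_rng.integers(max(i, 1), j_hi + 1))
            else:
                i = int(c_rng.integers(2, n_ex - 2))
                j_hi = min(i + cfg.max_circ_exons - 1, n_ex - 2)
                j = int(c_rng.integers(i, j_hi + 1))  # j == i: single exon
            span = (i, j)
            used = used_spans.setdefault(gene.gene_id, set())
            # avoid *incidental* variant pairs: only planted partners may
            # share exactly one boundary with an existing span
            shares_one = any((i == i2) ^ (j == j2) for i2, j2 in used)
            if span not in used and (make_pair_partner or not shares_one):
                used.add(span)
                break
        else:
            # random placement exhausted: deterministic scan for a free span
            if make_pair_partner:
                i0 = pair_anchor[ci - 1][0]
                pool = [(i0, j) for j in
                        range(i0 + 1, min(i0 + cfg.max_circ_exons,
                                          n_ex - 1))]
            elif is_aug:
                pool = [(i, j) for i in (0, 1)
                        for j in range(max(i, 1),
                                       min(i + cfg.max_circ_exons,
                                           n_ex - 1))]
            else:
                pool = [(i, j) for i in range(2, n_ex - 2)
                        for j in range(i, min(i + cfg.max_circ_exons,
                                              n_ex - 1))]
            used = used_spans.setdefault(gene.gene_id, set())
            free = [s for s in pool if s not in used]
            if not free:
                raise ValueError(
                    f"gene {gene.gene_id} has no free circRNA span left; "
                    "increase n_genes or exons_per_gene")
            # prefer a span without incidental boundary sharing
            clean = [s for s in free
                     if not any((s[0] == i2) ^ (s[1] == j2)
                                for i2, j2 in used)]
            i, j = (clean or free)[0]
            used.add((i, j))
        if ci < 2 * n_pairs and ci % 2 == 0:
            pair_anchor[ci] = (i, j)
        start, end = _circ_interval(gene.exons, i, j)
        members = gene.exons[i:j + 1]
        # flanking introns in transcription order
        up = down = None
        if i > 0:
            prev = gene.exons[i - 1]
            up = (min(s for s, _ in [gene.exons[i]]) - prev[1]) \
                if gene.strand == "+" else (prev[0] - gene.exons[i][1])
            up = abs(up)
        if j < n_ex - 1:
            nxt = gene.exons[j + 1]
            down = (nxt[0] - gene.exons[j][1]) if gene.strand == "+" \
                else (gene.exons[j][0] - nxt[1])
            down = abs(down)
        cds_s, cds_e = gene.cds_span
        if start >= cds_s and end <= cds_e:
            loc = "CDS"
        else:
            into5 = (start < cds_s) if gene.strand == "+" else (end > cds_e)
            into3 = (end > cds_e) if gene.strand == "+" else (start < cds_s)
            loc = ("5UTR-3UTR" if into5 and into3
                   else "5UTR" if into5 else "3UTR")
        truth.circs.append(CircTruth(
            circ_id=f"{gene.chrom}:{start}-{end}:{gene.strand}",
            chrom=gene.chrom, start=start, end=end, strand=gene.strand,
            host_gene=gene.gene_id, localization=loc, member_exons=members,
            enriched=(ci < n_enriched),
            is_aug=bool(gene.cds_start is not None
                        and start <= gene.cds_start < end),
            upstream_intron=up, downstream_intron=down,
            alt_variant=(ci < 2 * n_pairs),
        ))
        ci += 1
    # antisense candidates: opposite strand of a gene body
    for k in range(cfg.n_antisense):
        g = coding[(3 * k + 1) % len(coding)]
        strand = "-" if g.strand == "+" else "+"
        s = g.start + 50
        e = min(g.end, s + 800)
        truth.circs.append(CircTruth(
            circ_id=f"{g.chrom}:{s}-{e}:{strand}", chrom=g.chrom,
            start=s, end=e, strand=strand, host_gene=None,
            localization="antisense", enriched=True))
        ci += 1
    # intergenic candidates: inside a gene gap
    for k in range(cfg.n_intergenic):
        g = truth.genes[2 * k]
        s = g.end + 5000
        e = s + 600
        truth.circs.append(CircTruth(
            circ_id=f"{g.chrom}:{s}-{e}:+", chrom=g.chrom, start=s, end=e,
            strand="+", host_gene=None, localization="intergenic",
            enriched=True))
        ci += 1
    # alternative-splicing truth from realized geometry: same-gene,
    # same-strand circs sharing exactly one BSJ coordinate (the planted
    # pairs plus any incidental boundary sharing)
    hosted_now = [c for c in truth.circs if c.host_gene]
    by_host: dict[str, list[CircTruth]] = {}
    for c in hosted_now:
        c.alt_variant = False
        by_host.setdefault(c.host_gene, []).append(c)
    for group in by_host.values():
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                a, b = group[x], group[y]
                if (a.start == b.start) + (a.end == b.end) == 1:
                    a.alt_variant = b.alt_variant = True
    # exon inclusion truth: gene-level union of member exons with dropout;
    # fully-depleted circs (single-circ genes only) lose all members
    drop_rng = _rng(cfg.seed, _D_GENOME, 99_999)
    per_gene_members: dict[str, set[tuple[int, int]]] = {}
    hosted = [c for c in truth.circs if c.host_gene]
    by_gene: dict[str, list[CircTruth]] = {}
    for c in hosted:
        by_gene.setdefault(c.host_gene, []).append(c)
    n_depleted = int(round(cfg.fraction_fully_depleted * len(hosted)))
    depleted_ids: set[str] = set()
    for gene_id, group in by_gene.items():
        if len(group) == 1 and len(depleted_ids) < n_depleted \
                and not group[0].alt_variant:
            depleted_ids.add(group[0].circ_id)
    for c in hosted:
        if c.circ_id in depleted_ids:
            continue
        keep = per_gene_members.setdefault(c.host_gene, set())
        for ex in c.member_exons:
            if ex in keep:
                continue
            if drop_rng.random() >= cfg.exon_dropout_rate:
                keep.add(ex)
    for c in hosted:
        gene = next(g for g in truth.genes if g.gene_id == c.host_gene)
        inside = [ex for ex in gene.exons
                  if ex[0] >= c.start and ex[1] <= c.end]
        included = per_gene_members.get(c.host_gene, set())
        c.included_exons = [ex for ex in inside if ex in included]


def write_gtf(truth: SimulationTruth, path) -> None:
    """Emit the annotation as Ensembl-dialect GTF (1-based inclusive)."""
    lines = []

    def feat(chrom, feature, s, e, strand, attrs):
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        lines.append(f"{chrom}\tsim\t{feature}\t{s + 1}\t{e}\t.\t{strand}\t.\t{a}")

    for g in truth.genes:
        biotype = "protein_coding" if g.coding else "lincRNA"
        feat(g.chrom, "gene", g.start, g.end, g.strand,
             [("gene_id", g.gene_id), ("gene_biotype", biotype)])
        exons_genomic = sorted(g.exons)
        tid = f"{g.gene_id}.t1"
        feat(g.chrom, "transcript", g.start, g.end, g.strand,
             [("gene_id", g.gene_id), ("transcript_id", tid)])
        for s, e in exons_genomic:
            feat(g.chrom, "exon", s, e, g.strand,
                 [("gene_id", g.gene_id), ("transcript_id", tid)])
        if g.coding:
            cs, ce = g.cds_span
            for s, e in exons_genomic:
                s2, e2 = max(s, cs), min(e, ce)
                if s2 < e2:
                    feat(g.chrom, "CDS", s2, e2, g.strand,
                         [("gene_id", g.gene_id), ("transcript_id", tid)])
                # UTR pieces: genomically before/after the CDS span
                if s < cs:
                    u = ("five_prime_utr" if g.strand == "+"
                         else "three_prime_utr")
                    feat(g.chrom, u, s, min(e, cs), g.strand,
                         [("gene_id", g.gene_id), ("transcript_id", tid)])
                if e > ce:
                    u = ("three_prime_utr" if g.strand == "+"
                         else "five_prime_utr")
                    feat(g.chrom, u, max(s, ce), e, g.strand,
                         [("gene_id", g.gene_id), ("transcript_id", tid)])
        if g.alt_transcript:
            # shorter second isoform: drops the last transcription exon
            tid2 = f"{g.gene_id}.t2"
            alt = sorted(g.exons[:-1])
            feat(g.chrom, "transcript", alt[0][0], alt[-1][1], g.strand,
                 [("gene_id", g.gene_id), ("transcript_id", tid2)])
            for s, e in alt:
                feat(g.chrom, "exon", s, e, g.strand,
                     [("gene_id", g.gene_id), ("transcript_id", tid2)])
            if g.coding:
                cs, ce = g.cds_span
                for s, e in alt:
                    s2, e2 = max(s, cs), min(e, ce)
                    if s2 < e2:
                        feat(g.chrom, "CDS", s2, e2, g.strand,
                             [("gene_id", g.gene_id), ("transcript_id", tid2)])
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ------------------------------------------------------------- experiment

def simulate_circ_counts(rng: np.random.Generator, n_samples_per_group: int,
                         depth: float, mu0: float, mu1: float, rho: float
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one circRNA's (circ, linear, group) per-sample counts:
    totals Poisson(depth), circ beta-binomial with group means mu0/mu1
    and intra-class correlation rho."""
    n = n_samples_per_group
    group = np.array([0] * n + [1] * n)
    totals = rng.poisson(depth, size=2 * n)
    circ = np.zeros(2 * n, dtype=int)
    s = (1 - rho) / rho
    for j, (t, g) in enumerate(zip(totals, group)):
        if t == 0:
            continue
        mu = mu1 if g else mu0
        p = rng.beta(mu * s, (1 - mu) * s)
        circ[j] = rng.binomial(t, p)
    return circ, totals - circ, group


def simulate_experiment(cfg: SimulationConfig, truth: SimulationTruth,
                        outdir) -> None:
    """Draw counts for every planted circRNA, append the filter-failure
    decoys, and write the junction file, the circular/linear count table
    and the exon count table. The junction file contains exactly the
    reads the count table books (internal consistency)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = cfg.samples
    untreated = [s for s, g in samples if g == "untreated"]
    _append_filter_fails(cfg, truth)
    jlines = []
    crows = []
    for idx, c in enumerate(truth.circs):
        rng = _rng(cfg.seed, _D_COUNTS, idx)
        mu1 = cfg.circ_fraction_treated_enriched if c.enriched \
            else cfg.circ_fraction_untreated
        if c.fail_mode == "low_support":
            circ, lin, grp = simulate_circ_counts(
                rng, cfg.n_samples_per_group, 8.0,
                0.05, 0.05, cfg.rho)
        elif c.fail_mode == "one_sample":
            circ, lin, grp = simulate_circ_counts(
                rng, cfg.n_samples_per_group, cfg.depth_circ,
                cfg.circ_fraction_untreated, mu1, cfg.rho)
            circ[1:] = 0  # support confined to the first sample
        elif c.fail_mode == "low_proportion":
            circ, lin, grp = simulate_circ_counts(
                rng, cfg.n_samples_per_group, 3000.0, 0.003, 0.003, cfg.rho)
        else:
            circ, lin, grp = simulate_circ_counts(
                rng, cfg.n_samples_per_group, cfg.depth_circ,
                cfg.circ_fraction_untreated, mu1, cfg.rho)
        for (sample_id, group), cc, ll in zip(samples, circ, lin):
            c.counts[sample_id] = int(cc)
            c.linear_counts[sample_id] = int(ll)
            crows.append((c.circ_id, sample_id, group, int(cc), int(ll)))
            for r in range(int(cc)):
                if c.strand == "+":
                    donor, acceptor = c.end - 1, c.start
                else:
                    donor, acceptor = c.start, c.end - 1
                jlines.append(f"{c.chrom}\t{donor}\t{c.strand}\t{c.chrom}\t"
                              f"{acceptor}\t{c.strand}\t"
                              f"r{idx}_{sample_id}_{r}\t{sample_id}")
        c.expected_pass_filter = _passes_filter(cfg, c, untreated, truth)
    (outdir / "junctions.tsv").write_text(
        "\n".join(jlines) + ("\n" if jlines else ""))
    pd.DataFrame(crows, columns=["circ_id", "sample_id", "group",
                                 "circ_count", "linear_count"]
                 ).to_csv(outdir / "circ_linear_counts.tsv", sep="\t",
                          index=False)
    _write_mask(truth, outdir / "mask.bed")
    _simulate_exon_counts(cfg, truth, outdir / "exon_counts.tsv")
    truth.library_sizes = {s: cfg.library_size for s, _ in samples}


def _append_filter_fails(cfg: SimulationConfig, truth: SimulationTruth) -> None:
    if any(c.fail_mode for c in truth.circs):
        return
    modes = ["low_support", "one_sample", "low_proportion", "masked"]
    pos = _CHROM_SIZE - 500_000
    for k in range(cfg.n_filter_fail):
        mode = modes[k % len(modes)]
        s = pos + k * 5000
        e = s + 700
        c = CircTruth(
            circ_id=f"chr2:{s}-{e}:+", chrom="chr2", start=s, end=e,
            strand="+", host_gene=None, localization="intergenic",
            enriched=False, fail_mode=mode, expected_pass_filter=False)
        truth.circs.append(c)
        if mode == "masked":
            truth.mask_intervals.append(("chr2", s + 100, s + 300))


def _passes_filter(cfg: SimulationConfig, c: CircTruth,
                   untreated: list[str], truth: SimulationTruth) -> bool:
    """Direct arithmetic re-statement of the candidate filter on the
    drawn counts (the truth side of the filter fixture)."""
    n_ok = sum(1 for v in c.counts.values() if v >= 2)
    if n_ok < 2:
        return False
    cc = sum(c.counts[s] for s in untreated)
    ll = sum(c.linear_counts[s] for s in untreated)
    if cc + ll > 0 and cc / (cc + ll) < 0.01:
        return False
    for chrom, ms, me in truth.mask_intervals:
        if chrom == c.chrom and ms < c.end and me > c.start:
            return False
    return True


def _simulate_exon_counts(cfg: SimulationConfig, truth: SimulationTruth,
                          path) -> None:
    """NB exon counts: untreated mean proportional to exon usage weight;
    treated mean globally depleted (linear decay) with the planted
    uplift on circRNA-included exons.

    Because the usage test normalizes by the realized gene total, an
    absolute uplift f on exons carrying weight share W only yields a
    relative shift f / (1 + (f-1) W).  The generator therefore solves f
    per gene so the *relative* shift of included exons equals
    cfg.exon_uplift wherever geometrically possible (W < 1/uplift), and
    saturates f otherwise."""
    rows = []
    samples = cfg.samples
    included_by_gene: dict[str, set[tuple[int, int]]] = {}
    for c in truth.circs:
        if c.host_gene:
            included_by_gene.setdefault(c.host_gene, set()).update(
                c.included_exons)
    R = cfg.exon_uplift
    for gi, g in enumerate(truth.genes):
        if not g.coding:
            continue
        rng = _rng(cfg.seed, _D_EXONS, gi)
        inc = included_by_gene.get(g.gene_id, set())
        exons_genomic = sorted(g.exons)
        w = rng.uniform(0.7, 1.3, size=len(exons_genomic))
        w = w / w.sum()
        W = sum(we for (s, e), we in zip(exons_genomic, w) if (s, e) in inc)
        if W < 1.0 / R * 0.95:
            f = R * (1 - W) / (1 - R * W)
        else:
            f = 40.0
        for (s, e), we in zip(exons_genomic, w):
            uplift = f if (s, e) in inc else 1.0
            for sample_id, group in samples:
                mean = cfg.depth_gene * we
                if group == "treated":
                    mean *= cfg.gene_depletion * uplift
                # NB via gamma-Poisson, dispersion 0.02
                disp = 0.02
                lam = rng.gamma(1.0 / disp, disp * mean)
                y = int(rng.poisson(lam))
                rows.append((g.gene_id, f"{g.gene_id}_ex{s}", g.chrom, s, e,
                             sample_id, group, y))
    pd.DataFrame(rows, columns=["gene_id", "exon_id", "chrom", "start", "end",
                                "sample_id", "group", "count"]
                 ).to_csv(path, sep="\t", index=False)


def _write_mask(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in truth.mask_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\trepeat\t0\t+\n")


# ----------------------------------------------------------------- tracks

def _brute_force_alu_distance(c: CircTruth,
                              alus: list[tuple[str, int, int, str]],
                              window: int = 100_000) -> Optional[int]:
    ups = [(e, st) for ch, s, e, st in alus
           if ch == c.chrom and e <= c.start and e > c.start - window]
    downs = [(s, st) for ch, s, e, st in alus
             if ch == c.chrom and s >= c.end and s < c.end + window]
    best = None
    for ue, ust in ups:
        for ds, dst in downs:
            if ust == dst:
                continue
            d = (c.start - ue) + (ds - c.end)
            if best is None or d < best:
                best = d
    return best


def simulate_tracks(cfg: SimulationConfig, truth: SimulationTruth,
                    outdir) -> None:
    """Alu BED, Ago2 peaks, m6A IP/control counts, P-site table and
    ribosome-footprint junctions, all tied to truth flags. AUG circRNAs
    receive a more distant inverted Alu pair (unless alu_flat_geometry);
    the recorded truth distance is an exhaustive all-pairs search over
    every placed Alu, so decoys can never silently invalidate it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alus: list[tuple[str, int, int, str]] = []
    # decoy Alus, same strand, confined to the reserved head of each chrom
    d_rng = _rng(cfg.seed, _D_TRACKS, 0)
    for chrom in ("chr1", "chr2"):
        p = _DECOY_ALU_REGION[0] + 100
        while p < _DECOY_ALU_REGION[1]:
            alus.append((chrom, p, p + 300, "+"))
            p += int(d_rng.integers(800, 2000))
    hosted = [c for c in truth.circs if c.host_gene and not c.fail_mode]
    peaks = []
    m6a_rows = []
    fp_lines = []
    n_ago2 = int(round(cfg.fraction_ago2 * len(hosted)))
    n_m6a = int(round(cfg.fraction_m6a * len(hosted)))
    n_ribo = int(round(cfg.fraction_ribo * len(hosted)))
    for idx, c in enumerate(hosted):
        rng = _rng(cfg.seed, _D_TRACKS, 1000 + idx)
        # planted inverted Alu pair
        mean = cfg.alu_aug_mean if (c.is_aug and not cfg.alu_flat_geometry) \
            else cfg.alu_nonaug_mean
        total = float(np.clip(rng.normal(mean, mean * 0.25), 200, 12_000))
        d_up = max(50, int(total * rng.uniform(0.3, 0.7)))
        d_down = max(50, int(total) - d_up)
        flip = bool(rng.random() < 0.5)
        up_strand, down_strand = ("+", "-") if not flip else ("-", "+")
        alus.append((c.chrom, c.start - d_up - 300, c.start - d_up, up_strand))
        alus.append((c.chrom, c.end + d_down, c.end + d_down + 300, down_strand))
        # Ago2 peaks inside the circ
        c.ago2_peaks = 0
        if idx < n_ago2:
            k = int(rng.integers(1, 4))
            width = 50
            for pk in range(k):
                off = int(rng.integers(0, max(1, c.end - c.start - width)))
                peaks.append((c.chrom, c.start + off, c.start + off + width))
            c.ago2_peaks = k
    # deterministic m6a/ribo assignment, decorrelated: m6A from the top
    # of the hosted list, ribosome association from the bottom
    for idx, c in enumerate(hosted):
        c.m6a_flag = idx < n_m6a
        c.ribo_flag = idx >= len(hosted) - n_ribo
    for idx, c in enumerate(hosted):
        rng = _rng(cfg.seed, _D_TRACKS, 50_000 + idx)
        mu_ip = 0.5 if c.m6a_flag else 0.1
        circ, lin, grp = simulate_circ_counts(
            rng, cfg.n_samples_per_group, 300.0, 0.1, mu_ip, cfg.rho)
        for j, g in enumerate(grp):
            sample = f"{'IP' if g else 'control'}_{j % cfg.n_samples_per_group + 1}"
            m6a_rows.append((c.circ_id, sample, "IP" if g else "control",
                             int(circ[j]), int(lin[j])))
        if c.ribo_flag:
            n_fp = int(rng.integers(2, 6))
            for r in range(n_fp):
                if c.strand == "+":
                    donor, acceptor = c.end - 1, c.start
                else:
                    donor, acceptor = c.start, c.end - 1
                fp_lines.append(f"{c.chrom}\t{donor}\t{c.strand}\t{c.chrom}\t"
                                f"{acceptor}\t{c.strand}\tfp{idx}_{r}\tribo1")
        else:
            # linear (forward) splice footprints elsewhere in the host gene
            gene = next(g for g in truth.genes if g.gene_id == c.host_gene)
            ex = sorted(gene.exons)
            if len(ex) >= 2:
                if gene.strand == "+":
                    donor, acceptor = ex[0][1] - 1, ex[1][0]
                else:
                    donor, acceptor = ex[1][0], ex[0][1] - 1
                fp_lines.append(f"{gene.chrom}\t{donor}\t{gene.strand}\t"
                                f"{gene.chrom}\t{acceptor}\t{gene.strand}\t"
                                f"fplin{idx}\tribo1")
    truth.alus = sorted(alus)
    for c in truth.circs:
        if c.host_gene and not c.fail_mode:
            c.alu_distance = _brute_force_alu_distance(c, alus)
    # truth peak counts by brute force: overlapping circRNAs of one gene
    # can share a peak, so the planted count alone is not the answer
    for c in hosted:
        c.ago2_peaks = sum(1 for chrom, s, e in peaks
                           if chrom == c.chrom and s < c.end and e > c.start)
    with open(outdir / "alu.bed", "w") as fh:
        for chrom, s, e, st in truth.alus:
            fh.write(f"{chrom}\t{s}\t{e}\tAlu\t0\t{st}\n")
    with open(outdir / "ago2_peaks.bed", "w") as fh:
        for i, (chrom, s, e) in enumerate(sorted(peaks)):
            fh.write(f"{chrom}\t{s}\t{e}\tpeak{i}\t100\t.\n")
    pd.DataFrame(m6a_rows, columns=["circ_id", "sample_id", "group",
                                    "circ_count", "linear_count"]
                 ).to_csv(outdir / "m6a_counts.tsv", sep="\t", index=False)
    (outdir / "ribo_junctions.tsv").write_text(
        "\n".join(fp_lines) + ("\n" if fp_lines else ""))
    _simulate_psites(cfg, truth, outdir / "psites.tsv")


def _simulate_psites(cfg: SimulationConfig, truth: SimulationTruth,
                     path) -> None:
    rows = []
    aug_hosts = {c.host_gene for c in truth.circs if c.is_aug and c.host_gene}
    for gi, g in enumerate(truth.genes):
        if not g.coding:
            continue
        rng = _rng(cfg.seed, _D_PSITES, gi)
        mean = cfg.psite_base_mean * (cfg.psite_aug_ratio
                                      if g.gene_id in aug_hosts else 1.0)
        for s in range(1, 5):
            disp = 0.05
            lam = rng.gamma(1.0 / disp, disp * mean)
            rows.append((g.gene_id, f"heart_{s}", int(rng.poisson(lam))))
    pd.DataFrame(rows, columns=["gene_id", "sample_id", "psite_count"]
                 ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- chains

_STATUS_PLANS = ("mapped", "inverted", "unmapped", "split",
                 "strand_inconsistent")


def simulate_chains(cfg: SimulationConfig, truth: SimulationTruth,
                    outdir) -> None:
    """Per extra species: a chain file built from offset, inverted,
    gapped and split neighborhoods around each host gene, an expected
    LiftResult per circ, and the target-species circRNA set (lifted
    coordinates of planted-conserved circs with enrichment flags)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hosted = [c for c in truth.circs if c.host_gene and not c.fail_mode]
    by_gene: dict[str, list[CircTruth]] = {}
    for c in hosted:
        by_gene.setdefault(c.host_gene, []).append(c)
    single_genes = sorted(g for g, cs in by_gene.items() if len(cs) == 1)
    multi_genes = sorted(g for g in by_gene if g not in single_genes)
    for sp in range(cfg.n_species):
        species = SPECIES_TARGETS[sp] if sp < len(SPECIES_TARGETS) \
            else f"species{sp}"
        # plan: multi-circ genes always plain-mapped; single-circ genes
        # rotate through the exotic statuses, shifted per species
        plan: dict[str, str] = {g: "mapped" for g in multi_genes}
        for k, g in enumerate(single_genes):
            plan[g] = _STATUS_PLANS[(k + sp) % len(_STATUS_PLANS)]
        chain_lines: list[str] = []
        cid = 1
        t_cursor = 500_000
        t_size = _CHROM_SIZE
        for gene_id in sorted(by_gene):
            gene = next(g for g in truth.genes if g.gene_id == gene_id)
            circs = by_gene[gene_id]
            a, b = gene.start - 200, gene.end + 200
            t_chrom = f"{species}_chr1"
            mode = plan[gene_id]
            if mode == "mapped":
                F = t_cursor
                chain_lines += _chain_text(1000 + cid, gene.chrom, a, b,
                                           t_chrom, t_size, "+", F, cid)
                cid += 1
                for c in circs:
                    c.lift[species] = {
                        "status": "mapped", "chrom": t_chrom,
                        "start": F + (c.start - a), "end": F + (c.end - a),
                        "strand": c.strand}
                t_cursor += (b - a) + 10_000
            elif mode == "inverted":
                (c,) = circs
                L = b - a
                F = t_cursor
                ta = t_size - (F + L)
                chain_lines += _chain_text(1000 + cid, gene.chrom, a, b,
                                           t_chrom, t_size, "-", ta, cid)
                cid += 1
                c.lift[species] = {
                    "status": "mapped", "chrom": t_chrom,
                    "start": F + L - (c.end - a), "end": F + L - (c.start - a),
                    "strand": "-" if c.strand == "+" else "+"}
                t_cursor += L + 10_000
            elif mode == "unmapped":
                (c,) = circs
                # gap over the downstream endpoint
                g1 = (a, c.end - 3)
                g2 = (c.end + 2, b)
                F = t_cursor
                chain_lines += _chain_text_blocks(
                    1000 + cid, gene.chrom, t_chrom, t_size, "+",
                    [(g1[0], g1[1] - g1[0], F),
                     (g2[0], g2[1] - g2[0], F + (g1[1] - g1[0]) + 50)], cid)
                cid += 1
                c.lift[species] = {"status": "unmapped"}
                t_cursor += (b - a) + 10_000
            elif mode in ("split", "strand_inconsistent"):
                (c,) = circs
                mid = (c.start + c.end) // 2
                F1, L1 = t_cursor, mid - a
                chain_lines += _chain_text(1000 + cid, gene.chrom, a, mid,
                                           t_chrom, t_size, "+", F1, cid)
                cid += 1
                L2 = b - mid
                if mode == "split":
                    F2 = t_cursor + L1 + 30_000
                    chain_lines += _chain_text(900 + cid, gene.chrom, mid, b,
                                               t_chrom, t_size, "+", F2, cid)
                else:
                    F2 = t_cursor + L1 + 30_000
                    ta2 = t_size - (F2 + L2)
                    chain_lines += _chain_text(900 + cid, gene.chrom, mid, b,
                                               t_chrom, t_size, "-", ta2, cid)
                cid += 1
                c.lift[species] = {"status": mode}
                t_cursor += L1 + L2 + 60_000
        # target-species circ set: planted-conserved subset of mapped circs
        mapped = [c for c in hosted
                  if c.lift.get(species, {}).get("status") == "mapped"]
        n_cons = int(round(cfg.fraction_conserved * len(mapped)))
        n_enr = int(round(cfg.fraction_target_enriched * n_cons))
        # shift the conserved window per species so the species' conserved
        # sets overlap only partially (a realistic Venn structure)
        shift = sp * max(1, n_cons // 2)
        cons_idx = [(shift + t) % len(mapped) for t in range(n_cons)] \
            if mapped else []
        target_rows = []
        for k, c in enumerate(mapped):
            conserved = k in cons_idx
            c.lift[species]["target_expressed"] = conserved
            c.lift[species]["target_enriched"] = (
                conserved and cons_idx.index(k) < n_enr if conserved else False)
            if conserved:
                lf = c.lift[species]
                target_rows.append((lf["chrom"], lf["start"], lf["end"],
                                    lf["strand"],
                                    f"{species}_circ{k}",
                                    int(lf["target_enriched"])))
        Path(outdir / f"{species}.chain").write_text("".join(chain_lines))
        pd.DataFrame(target_rows, columns=["chrom", "start", "end", "strand",
                                           "circ_id", "enriched"]
                     ).to_csv(outdir / f"{species}_circs.tsv", sep="\t",
                              index=False)


def _chain_text(score, s_chrom, a, b, t_chrom, t_size, t_strand, ta, cid
                ) -> list[str]:
    L = b - a
    return [f"chain {score} {s_chrom} {_CHROM_SIZE} + {a} {b} "
            f"{t_chrom} {t_size} {t_strand} {ta} {ta + L} {cid}\n",
            f"{L}\n", "\n"]


def _chain_text_blocks(score, s_chrom, t_chrom, t_size, t_strand,
                       blocks, cid) -> list[str]:
    a = blocks[0][0]
    b = blocks[-1][0] + blocks[-1][1]
    ta = blocks[0][2]
    tb = blocks[-1][2] + blocks[-1][1]
    out = [f"chain {score} {s_chrom} {_CHROM_SIZE} + {a} {b} "
           f"{t_chrom} {t_size} {t_strand} {ta} {tb} {cid}\n"]
    for j, (s0, size, t0) in enumerate(blocks):
        if j + 1 < len(blocks):
            ns, _, nt = blocks[j + 1]
            out.append(f"{size}\t{ns - (s0 + size)}\t{nt - (t0 + size)}\n")
        else:
            out.append(f"{size}\n")
    out.append("\n")
    return out


# ------------------------------------------------------------------ bundle

def simulate_all(cfg: SimulationConfig, outdir) -> SimulationTruth:
    """Generate the complete synthetic study into `outdir` and write the
    truth tables (truth.json + circ_truth.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_annotation(cfg)
    write_gtf(truth, outdir / "annotation.gtf")
    simulate_experiment(cfg, truth, outdir)
    simulate_tracks(cfg, truth, outdir)
    simulate_chains(cfg, truth, outdir)
    write_truth(truth, outdir)
    return truth


def write_truth(truth: SimulationTruth, outdir) -> None:
    outdir = Path(outdir)
    payload = {
        "config": asdict(truth.config),
        "library_sizes": truth.library_sizes,
        "genes": [asdict(g) for g in truth.genes],
        "circs": [asdict(c) for c in truth.circs],
        "mask_intervals": truth.mask_intervals,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1,
                                                  default=list))
    pd.DataFrame([{
        "circ_id": c.circ_id, "host_gene": c.host_gene,
        "localization": c.localization, "enriched": c.enriched,
        "is_aug": c.is_aug, "pass_filter": c.expected_pass_filter,
        "fail_mode": c.fail_mode, "alt_variant": c.alt_variant,
        "n_member_exons": len(c.member_exons),
        "n_included_exons": len(c.included_exons),
        "alu_distance": c.alu_distance,
        "upstream_intron": c.upstream_intron,
        "downstream_intron": c.downstream_intron,
        "ago2_peaks": c.ago2_peaks, "m6a": c.m6a_flag, "ribo": c.ribo_flag,
    } for c in truth.circs]).to_csv(outdir / "circ_truth.tsv", sep="\t",
                                    index=False)
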