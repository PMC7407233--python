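"""Back-splice junction calling and candidate filtering.

A chimeric read whose two segments lie on the same chromosome and strand
with the genomic order inverted relative to linear splicing (acceptor
coordinate upstream of the donor) is evidence for a back-splice junction
(BSJ), the read-level signature unique to a circRNA. Candidates are
aggregated per sample over the (chrom, start, end, strand) identity and
filtered for read support, junction proportion and repeat overlap.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass
class ChimericJunctionRecord:
    """One chimeric read: segment A donor side, segment B acceptor side."""
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    read_id: str
    sample_id: str


@dataclass
class BsjCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    counts: dict[str, int] = field(default_factory=dict)
    linear_counts: dict[str, int] = field(default_factory=dict)
    host_gene: Optional[str] = None
    localization: Optional[str] = None

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class FilterParams:
    min_reads: int = 2
    min_samples: int = 2
    min_junction_proportion: float = 0.01
    mask_intervals: dict[str, IntervalTree] = field(default_factory=dict)
    untreated_samples: Optional[set[str]] = None

    def __post_init__(self):
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.0 <= self.min_junction_proportion <= 1.0:
            raise ValueError("min_junction_proportion must be in [0,1]")


def read_junction_tsv(path, sample_id: Optional[str] = None
                      ) -> Iterable[ChimericJunctionRecord]:
    """Read the 8-column junction dialect (chrom_a, pos_a, strand_a,
    chrom_b, pos_b, strand_b, read_id, sample_id); header optional."""
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "chrom_a":
                continue
            yield ChimericJunctionRecord(
                chrom_a=row[0], pos_a=int(row[1]), strand_a=row[2],
                chrom_b=row[3], pos_b=int(row[4]), strand_b=row[5],
                read_id=row[6], sample_id=sample_id or row[7],
            )


def read_star_chimeric(path, sample_id: str) -> Iterable[ChimericJunctionRecord]:
    """Converter for the STAR Chimeric.out.junction dialect (first 10
    columns; 1-based junction positions)."""
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            yield ChimericJunctionRecord(
                chrom_a=row[0], pos_a=int(row[1]) - 1, strand_a=row[2],
                chrom_b=row[3], pos_b=int(row[4]) - 1, strand_b=row[5],
                read_id=row[9] if len(row) > 9 else f"read{i}",
                sample_id=sample_id,
            )


def call_bsjs(records: Iterable[ChimericJunctionRecord]) -> list[BsjCandidate]:
    """Aggregate chimeric reads into BSJ candidates.

    A record yields a BSJ when both segments share chromosome and strand
    and the acceptor coordinate is upstream of (or equal to) the donor —
    the back-splice orientation. Trans-chromosomal and cross-strand
    chimeras are ignored; unknown strand symbols are rejected with a
    counted warning. Output is sorted by (chrom, start, end, strand) so
    the call is order-invariant over the input stream.
    """
    agg: dict[tuple[str, int, int, str], dict[str, int]] = {}
    n_bad_strand = 0
    for r in records:
        if r.strand_a not in "+-" or r.strand_b not in "+-":
            n_bad_strand += 1
            continue
        if r.chrom_a != r.chrom_b or r.strand_a != r.strand_b:
            continue
        lo, hi = min(r.pos_a, r.pos_b), max(r.pos_a, r.pos_b)
        # back-splice orientation: acceptor (B) not downstream of donor (A)
        if r.strand_a == "+":
            if r.pos_b > r.pos_a:
                continue
        else:
            if r.pos_b < r.pos_a:
                continue
        key = (r.chrom_a, lo, hi + 1, r.strand_a)
        agg.setdefault(key, {})
        agg[key][r.sample_id] = agg[key].get(r.sample_id, 0) + 1
    if n_bad_strand:
        log.warning("rejected %d records with unknown strand symbol", n_bad_strand)
    return [
        BsjCandidate(chrom=c, start=s, end=e, strand=st, counts=agg[(c, s, e, st)])
        for (c, s, e, st) in sorted(agg)
    ]


def load_mask_bed(path) -> dict[str, IntervalTree]:
    """Load a BED mask (e.g. RepeatMasker intervals) into per-chrom trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            trees.setdefault(f[0], IntervalTree()).addi(int(f[1]), int(f[2]))
    return trees


def junction_proportion(cand: BsjCandidate,
                        untreated: Optional[set[str]] = None) -> Optional[float]:
    """circ/(circ+linear) pooled over untreated samples (RNase R destroys
    the linear denominator in treated libraries). None when linear counts
    are absent or the pooled total is zero."""
    if not cand.linear_counts:
        return None
    samples = set(cand.counts) | set(cand.linear_counts)
    if untreated is not None:
        samples &= untreated
    c = sum(cand.counts.get(s, 0) for s in samples)
    l = sum(cand.linear_counts.get(s, 0) for s in samples)
    if c + l == 0:
        return None
    return c / (c + l)


def filter_candidates(cands: Iterable[BsjCandidate],
                      p: FilterParams) -> list[BsjCandidate]:
    """Apply the candidate filters: >= min_reads in >= min_samples,
    junction proportion >= min_junction_proportion in pooled untreated
    samples (skipped with a logged notice when linear counts are absent),
    and no half-open overlap with mask intervals. Sorted output;
    idempotent."""
    kept = []
    notice_logged = False
    for cand in cands:
        n_ok = sum(1 for v in cand.counts.values() if v >= p.min_reads)
        if n_ok < p.min_samples:
            continue
        prop = junction_proportion(cand, p.untreated_samples)
        if prop is None:
            if cand.linear_counts == {} and not notice_logged:
                log.info("linear counts absent; junction-proportion filter skipped")
                notice_logged = True
        elif prop < p.min_junction_proportion:
            continue
        tree = p.mask_intervals.get(cand.chrom)
        if tree is not None and tree.overlap(cand.start, cand.end):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda c: c.key)


def alternative_splicing_rate(cands: list[BsjCandidate],
                              min_variant_reads: int = 4
                              ) -> tuple[float, list[dict]]:
    """Fraction of candidates participating in an alternative-splicing
    variant pair.

    Two candidates of the same host gene are alternative variants when
    they share exactly one BSJ coordinate (same start xor same end); a
    candidate counts only when its total read support is strictly greater
    than 3 (>= min_variant_reads). Returns (rate, variant table)."""
    flagged: set[tuple] = set()
    table: list[dict] = []
    by_gene: dict[str, list[BsjCandidate]] = {}
    for c in cands:
        if c.host_gene is not None:
            by_gene.setdefault(c.host_gene, []).append(c)
    for gene, group in by_gene.items():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if a.strand != b.strand:
                    continue
                shared = (a.start == b.start) + (a.end == b.end)
                if shared != 1:
                    continue
                if (a.total_reads < min_variant_reads
                        or b.total_reads < min_variant_reads):
                    continue
                flagged.add(a.key)
                flagged.add(b.key)
                table.append({
                    "host_gene": gene, "circ_a": a.circ_id, "circ_b": b.circ_id,
                    "shared": "start" if a.start == b.start else "end",
                    "reads_a": a.total_reads, "reads_b": b.total_reads,
                })
    rate = len(flagged) / len(cands) if cands else 0.0
    return rate, table


def circ_per_host_gene(cands: list[BsjCandidate],
                       library_sizes: dict[str, int]) -> "pandas.DataFrame":
    """CircRNAs per host gene with per-million depth normalization.

    normalized = n_candidates / (total library reads / 1e6). Raises on a
    zero library size."""
    import pandas as pd

    total = sum(library_sizes.values())
    if any(v <= 0 for v in library_sizes.values()) or total <= 0:
        raise ValueError("library sizes must be positive")
    counts: dict[str, int] = {}
    for c in cands:
        if c.host_gene is not None:
            counts[c.host_gene] = counts.get(c.host_gene, 0) + 1
    rows = [
        {"gene_id": g, "n_circ": n, "circ_per_million": n / (total / 1e6)}
        for g, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_circ", "circ_per_million"])


def write_candidates_bed(cands: list[BsjCandidate], path) -> None:
    """BED6 export; the name field carries circ_id|host|localization."""
    with open(path, "w") as fh:
        for c in sorted(cands, key=lambda x: x.key):
            name = f"{c.circ_id}|{c.host_gene or '.'}|{c.localization or '.'}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t"
                     f"{c.total_reads}\t{c.strand}\n")
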