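"""Gene annotation model and locus queries.

Parses Ensembl-dialect GTF into an in-memory gene/transcript/exon model
with strand-aware interval indices, and answers the locus questions the
pipeline needs: which gene hosts a BSJ, where a candidate sits relative
to the canonical CDS (localization category), and where the canonical
start codon lies.

Coordinates are 0-based half-open internally; GTF is 1-based inclusive
on disk and converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

LOCALIZATION_CATEGORIES = (
    "CDS",
    "5UTR",
    "3UTR",
    "5UTR-3UTR",
    "noncoding_host",
    "antisense",
    "intergenic",
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class AnnotationError(ValueError):
    """Raised when a structurally invalid annotation is loaded."""


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    tags: tuple[str, ...] = ()

    @property
    def cds_span(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    biotype: str = "protein_coding"

    @property
    def is_coding(self) -> bool:
        return any(t.cds for t in self.transcripts.values())

    @property
    def canonical_transcript_id(self) -> str:
        """Canonical transcript: GTF 'canonical'/'Ensembl_canonical' tag if
        present, else longest CDS, ties by total exon length, then
        lexicographic transcript_id (deterministic)."""
        tagged = [
            t for t in self.transcripts.values()
            if "canonical" in t.tags or "Ensembl_canonical" in t.tags
        ]
        pool = tagged or list(self.transcripts.values())
        return min(
            pool, key=lambda t: (-t.cds_length, -t.exon_length, t.transcript_id)
        ).transcript_id

    @property
    def canonical_transcript(self) -> TranscriptModel:
        return self.transcripts[self.canonical_transcript_id]


class GenomeAnnotation:
    """Gene collection plus interval indices over exons and gene bodies."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self.gene_index: dict[str, IntervalTree] = {}
        self.exon_index: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            if not g.transcripts:
                raise AnnotationError(f"gene {g.gene_id} has zero transcripts")
            for t in g.transcripts.values():
                for s, e in t.exons:
                    if s < g.start or e > g.end:
                        raise AnnotationError(
                            f"exon [{s},{e}) of {t.transcript_id} outside gene "
                            f"body [{g.start},{g.end}) of {g.gene_id}"
                        )
            self.genes[g.gene_id] = g
            self.gene_index.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
            tree = self.exon_index.setdefault((g.chrom, g.strand), IntervalTree())
            for t in g.transcripts.values():
                for s, e in t.exons:
                    tree.addi(s, e, g.gene_id)

    def genes_overlapping(self, chrom: str, start: int, end: int,
                          strand: Optional[str] = None) -> list[GeneModel]:
        tree = self.gene_index.get(chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end)}
        out = [self.genes[g] for g in sorted(hits)]
        if strand is not None:
            out = [g for g in out if g.strand == strand]
        return out

    def exons_overlapping(self, chrom: str, strand: str, start: int,
                          end: int) -> list[tuple[int, int, str]]:
        tree = self.exon_index.get((chrom, strand))
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfParseError(f"line {lineno}: unparseable attribute field: "
                            f"{attr_field[:80]!r}")
    return attrs


def load_annotation(gtf_path) -> GenomeAnnotation:
    """Load an Ensembl-dialect GTF (gene/transcript/exon/CDS/UTR features).

    1-based inclusive GTF coordinates become 0-based half-open. Raises
    :class:`GtfParseError` naming the line for malformed records and
    :class:`AnnotationError` for structural violations (gene without
    transcripts, exon outside its gene body).
    """
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated "
                                    f"fields, got {len(parts)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = parts
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if strand not in "+-":
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr, lineno)
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise GtfParseError(f"line {lineno}: gene feature lacks gene_id")
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=chrom, strand=strand, start=start, end=end,
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                )
                order.append(gid)
                continue
            gid = attrs.get("gene_id")
            tid = attrs.get("transcript_id")
            if gid is None or tid is None:
                raise GtfParseError(
                    f"line {lineno}: {feature} feature lacks gene_id/transcript_id")
            if gid not in genes:
                raise GtfParseError(
                    f"line {lineno}: {feature} references unknown gene {gid} "
                    "(gene feature must precede its children)")
            gene = genes[gid]
            if feature == "transcript":
                tags = tuple(v for k, v in _ATTR_RE.findall(attr) if k == "tag")
                gene.transcripts[tid] = TranscriptModel(transcript_id=tid, tags=tags)
                continue
            if tid not in gene.transcripts:
                gene.transcripts[tid] = TranscriptModel(transcript_id=tid)
            t = gene.transcripts[tid]
            if feature == "exon":
                t.exons.append((start, end))
            elif feature == "CDS":
                t.cds.append((start, end))
            elif feature == "five_prime_utr":
                t.utr5.append((start, end))
            elif feature == "three_prime_utr":
                t.utr3.append((start, end))
            # other features (start_codon, ...) are ignored
    for gid in order:
        for t in genes[gid].transcripts.values():
            t.exons.sort()
            t.cds.sort()
            t.utr5.sort()
            t.utr3.sort()
            # transcription order: minus-strand exons run high-to-low
            if genes[gid].strand == "-":
                t.exons.reverse()
    return GenomeAnnotation(genes[g] for g in order)


def canonical_cds_start(gene: GeneModel) -> Optional[int]:
    """Genomic position of the first base of the canonical start codon.

    On the minus strand the largest CDS coordinate is codon base 1.
    Returns None for noncoding genes.
    """
    t = gene.canonical_transcript
    span = t.cds_span
    if span is None:
        return None
    return span[0] if gene.strand == "+" else span[1] - 1


def assign_host_gene(chrom: str, start: int, end: int, strand: str,
                     ann: GenomeAnnotation) -> Optional[str]:
    """Same-strand gene whose exons overlap both BSJ endpoints.

    Ties go to the gene with greater exonic overlap with the interval,
    then lexicographically smaller gene_id. None when no same-strand
    gene qualifies (the candidate is antisense/intergenic downstream).
    """
    tree = ann.exon_index.get((chrom, strand))
    if tree is None:
        return None
    at_start = {iv.data for iv in tree.overlap(start, start + 1)}
    at_end = {iv.data for iv in tree.overlap(end - 1, end)}
    hosts = at_start & at_end
    if not hosts:
        return None

    def exonic_overlap(gid: str) -> int:
        ivs = []
        for t in ann.genes[gid].transcripts.values():
            for s, e in t.exons:
                s2, e2 = max(s, start), min(e, end)
                if s2 < e2:
                    ivs.append((s2, e2))
        # merge to avoid double counting across transcripts
        ivs.sort()
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    return min(hosts, key=lambda g: (-exonic_overlap(g), g))


def classify_localization(chrom: str, start: int, end: int, strand: str,
                          host_gene: Optional[str],
                          ann: GenomeAnnotation) -> str:
    """Localization category of a BSJ interval within its host gene.

    With a coding host: CDS when fully inside the canonical CDS span,
    5UTR / 3UTR when extending into one UTR only, 5UTR-3UTR when
    reaching both. Noncoding hosts get the dedicated "noncoding_host"
    label. Without a host: "antisense" when an opposite-strand gene
    overlaps, else "intergenic".
    """
    if host_gene is None:
        opposite = "-" if strand == "+" else "+"
        for g in ann.genes_overlapping(chrom, start, end):
            if g.strand == opposite:
                return "antisense"
        return "intergenic"
    gene = ann.genes[host_gene]
    t = gene.canonical_transcript
    span = t.cds_span
    if span is None:
        return "noncoding_host"
    cds_s, cds_e = span
    if start >= cds_s and end <= cds_e:
        return "CDS"
    # which genomic side is the 5' side depends on strand
    before = start < cds_s
    after = end > cds_e
    into5 = before if gene.strand == "+" else after
    into3 = after if gene.strand == "+" else before
    if into5 and into3:
        return "5UTR-3UTR"
    return "5UTR" if into5 else "3UTR"
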