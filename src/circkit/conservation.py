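"""Cross-species positional conservation of BSJs via chain-file liftover.

UCSC chain files describe a pairwise genome alignment as ordered
gap-separated blocks. Both BSJ endpoints of a candidate are mapped
through the highest-scoring chain covering each base; a candidate is
conserved when its lifted interval matches an expressed (and, in strict
mode, RNase R-enriched) circRNA of the target species at both ends.

Chain semantics follow the UCSC standard: header
``chain score tName tSize tStrand tStart tEnd qName qSize qStrand
qStart qEnd id`` followed by ``size dt dq`` block lines; when qStrand is
'-', q coordinates count from the reversed strand and are converted to
forward-strand coordinates here (pos_fwd = qSize - 1 - pos_rev).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bsj import BsjCandidate

MAPPED, UNMAPPED, SPLIT, STRAND_INCONSISTENT = (
    "mapped", "unmapped", "split", "strand_inconsistent")


class ChainParseError(ValueError):
    pass


@dataclass
class Chain:
    chain_id: int
    score: float
    s_chrom: str
    s_size: int
    s_start: int
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str          # '+' or '-' on the target side
    t_start: int           # in t_strand orientation, per the chain standard
    t_end: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    # blocks: (source_start, size, target_start) with target_start in
    # t_strand orientation; colinear and non-overlapping in source coords

    def map_base(self, pos: int) -> Optional[tuple[str, int, str]]:
        """Map one source base to (target_chrom, forward-strand position,
        target_strand), or None when the base falls in a gap / outside."""
        i = bisect_right(self._starts, pos) - 1
        if i < 0:
            return None
        s0, size, t0 = self.blocks[i]
        if pos >= s0 + size:
            return None
        t = t0 + (pos - s0)
        if self.t_strand == "-":
            t = self.t_size - 1 - t
        return (self.t_chrom, t, self.t_strand)

    def __post_init__(self):
        self._starts = [b[0] for b in self.blocks]


@dataclass
class ChainMap:
    chains: list[Chain]

    def __post_init__(self):
        self._by_chrom: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_chrom.setdefault(c.s_chrom, []).append(c)

    def best_chain_for(self, chrom: str, pos: int) -> Optional[Chain]:
        """Highest-scoring chain whose *blocks* cover the base; ties by
        lowest chain id (deterministic)."""
        best = None
        for c in self._by_chrom.get(chrom, []):
            if c.map_base(pos) is None:
                continue
            if best is None or (c.score, -c.chain_id) > (best.score, -best.chain_id):
                best = c
        return best


def parse_chain(path) -> ChainMap:
    """Parse a UCSC chain file, validating block structure."""
    chains: list[Chain] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise ChainParseError(f"expected chain header, got: {line[:60]!r}")
        f = line.split()
        if len(f) != 13:
            raise ChainParseError(f"chain header needs 13 fields: {line[:60]!r}")
        (_, score, s_chrom, s_size, s_strand, s_start, s_end,
         t_chrom, t_size, t_strand, t_start, t_end, cid) = f
        if s_strand != "+":
            raise ChainParseError(f"chain {cid}: source strand must be '+'")
        ch = Chain(
            chain_id=int(cid), score=float(score),
            s_chrom=s_chrom, s_size=int(s_size), s_start=int(s_start),
            s_end=int(s_end), t_chrom=t_chrom, t_size=int(t_size),
            t_strand=t_strand, t_start=int(t_start), t_end=int(t_end),
        )
        s_pos, t_pos = ch.s_start, ch.t_start
        blocks = []
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                break
            parts = row.split()
            size = int(parts[0])
            blocks.append((s_pos, size, t_pos))
            if len(parts) == 3:
                s_pos += size + int(parts[1])
                t_pos += size + int(parts[2])
            elif len(parts) == 1:
                s_pos += size
                t_pos += size
                break
            else:
                raise ChainParseError(f"chain {cid}: bad block line {row!r}")
        if s_pos != ch.s_end or t_pos != ch.t_end:
            raise ChainParseError(
                f"chain {cid}: block lengths do not close the chain "
                f"(source ends at {s_pos}, header says {ch.s_end}; "
                f"target ends at {t_pos}, header says {ch.t_end})")
        ch.blocks = blocks
        ch.__post_init__()
        chains.append(ch)
    return ChainMap(chains)


def write_chain(cm: ChainMap, path) -> None:
    """Serialize back to UCSC chain format (round-trip partner of
    :func:`parse_chain`)."""
    with open(path, "w") as fh:
        for c in cm.chains:
            fh.write(f"chain {c.score:g} {c.s_chrom} {c.s_size} + "
                     f"{c.s_start} {c.s_end} {c.t_chrom} {c.t_size} "
                     f"{c.t_strand} {c.t_start} {c.t_end} {c.chain_id}\n")
            for j, (s0, size, t0) in enumerate(c.blocks):
                if j + 1 < len(c.blocks):
                    ns, _, nt = c.blocks[j + 1]
                    fh.write(f"{size}\t{ns - (s0 + size)}\t{nt - (t0 + size)}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


@dataclass
class LiftResult:
    circ_id: str
    status: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    chain_id: Optional[int] = None


def lift_bsj(cand: BsjCandidate, cm: ChainMap) -> LiftResult:
    """Lift both BSJ endpoints of a candidate through the chain map.

    Endpoints are the first and last base of the circRNA interval
    ([start, end) half-open). Each maps through the highest-scoring chain
    covering it; statuses: unmapped (an endpoint in a gap or uncovered),
    split (endpoints on different chains with compatible orientation),
    strand_inconsistent (different chains disagreeing on target
    chromosome or strand), mapped (same chain). Minus-strand chains
    reverse the coordinate order and flip the candidate strand.
    """
    p1, p2 = cand.start, cand.end - 1
    c1 = cm.best_chain_for(cand.chrom, p1)
    c2 = cm.best_chain_for(cand.chrom, p2)
    if c1 is None or c2 is None:
        return LiftResult(cand.circ_id, UNMAPPED)
    if c1.chain_id != c2.chain_id:
        if c1.t_chrom != c2.t_chrom or c1.t_strand != c2.t_strand:
            return LiftResult(cand.circ_id, STRAND_INCONSISTENT)
        return LiftResult(cand.circ_id, SPLIT)
    m1 = c1.map_base(p1)
    m2 = c1.map_base(p2)
    assert m1 is not None and m2 is not None
    t_chrom, t1, t_strand = m1
    _, t2, _ = m2
    lo, hi = min(t1, t2), max(t1, t2)
    if t_strand == "-":
        strand = "-" if cand.strand == "+" else "+"
    else:
        strand = cand.strand
    return LiftResult(cand.circ_id, MAPPED, t_chrom, lo, hi + 1, strand,
                      c1.chain_id)


@dataclass
class ConservationRecord:
    circ_id: str
    lift: LiftResult
    matched_circ: Optional[str] = None
    target_expressed: bool = False
    target_enriched: bool = False
    conserved: bool = False


def cross_verify(lifted: Sequence[LiftResult],
                 target_cands: Sequence[BsjCandidate],
                 enriched_flags: Optional[dict[str, bool]] = None,
                 slack: int = 0,
                 strict: bool = False) -> list[ConservationRecord]:
    """Match lifted BSJs against the target species' circRNA set.

    A match requires both lifted ends within ±slack of a target BSJ on
    the same strand. Strict mode (the stringent multi-species analysis)
    additionally requires the target circRNA to be RNase R-enriched.
    """
    enriched_flags = enriched_flags or {}
    index: dict[str, list[BsjCandidate]] = {}
    for t in target_cands:
        index.setdefault(t.chrom, []).append(t)
    out = []
    for lr in lifted:
        rec = ConservationRecord(lr.circ_id, lr)
        if lr.status == MAPPED:
            for t in index.get(lr.chrom, []):
                if (t.strand == lr.strand
                        and abs(t.start - lr.start) <= slack
                        and abs(t.end - lr.end) <= slack):
                    rec.matched_circ = t.circ_id
                    rec.target_expressed = True
                    rec.target_enriched = bool(enriched_flags.get(t.circ_id))
                    break
            rec.conserved = rec.target_expressed and (
                rec.target_enriched if strict else True)
        out.append(rec)
    return out


def multi_species_partition(sets: dict[str, set]) -> dict[str, int]:
    """Disjoint Venn-region counts over named circ sets sharing one
    reference coordinate system. Region keys are '+'-joined sorted member
    names; counts sum to the union size and are input-order invariant."""
    names = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    regions: dict[str, int] = {}
    for item in universe:
        members = tuple(n for n in names if item in sets[n])
        key = "+".join(members)
        regions[key] = regions.get(key, 0) + 1
    for r in range(1, 1 << len(names)):
        members = tuple(n for i, n in enumerate(names) if r >> i & 1)
        regions.setdefault("+".join(members), 0)
    return regions


def shared_fraction(total: int, exclusive: int) -> float:
    """Fraction of a set shared with any other set: (total - exclusive) /
    total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (total - exclusive) / total


def load_orthology(path) -> dict[str, str]:
    """Two-column orthology TSV (source_gene_id, target_gene_id)."""
    table = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            s, t = line.split()[:2]
            table[s] = t
    return table
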