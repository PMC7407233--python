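"""Integration of circRNA candidates with external evidence tracks.

Three orthogonal layers of evidence: Ago2 CLIP peaks (candidate
miRNA-interaction sites on the circle), m6A immunoprecipitation counts
(methylation, tested IP vs control with the same beta-binomial machinery
as the RNase R contrast), and ribosome-protected footprint reads
spanning the BSJ (direct ribosome association).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .bsj import BsjCandidate, ChimericJunctionRecord
from .enrichment import CircLinearCounts, run_enrichment


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


@dataclass
class IntegrationFlags:
    circ_id: str
    ago2_peak_count: int = 0
    m6a_flag: bool = False
    ribo_flag: bool = False


def load_peaks_bed(path, source: str = "other") -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            peaks.append(Peak(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                name=f[3] if len(f) > 3 else ".",
                score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                strand=f[5] if len(f) > 5 else ".",
            ))
    return peaks


def overlap_peaks(cands: Sequence[BsjCandidate], peaks: Sequence[Peak],
                  stranded: bool = False
                  ) -> tuple[dict[str, int], dict[int, int]]:
    """Assign peaks to circRNAs by half-open interval overlap (>= 1 bp).

    A peak may land in several circRNAs. Returns (per-circ peak counts,
    per-peak assignment counts keyed by peak index). Strand is ignored by
    default (CLIP peak strand is unreliable)."""
    trees: dict[str, IntervalTree] = {}
    for idx, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, idx)
    per_circ = {c.circ_id: 0 for c in cands}
    per_peak = {i: 0 for i in range(len(peaks))}
    for c in cands:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(c.start, c.end):
            if stranded and peaks[iv.data].strand in "+-" \
                    and peaks[iv.data].strand != c.strand:
                continue
            per_circ[c.circ_id] += 1
            per_peak[iv.data] += 1
    return per_circ, per_peak


def flag_m6a(tables: Sequence[CircLinearCounts], alpha: float = 0.05,
             seed: int = 0, min_boot_draws: int = 300) -> dict[str, bool]:
    """m6A methylation flags from IP-vs-control counts.

    Delegates to the beta-binomial enrichment test with groups control
    (0) / IP (1): circ BSJ reads act as the "circular" numerator and the
    host-gene background reads as the denominator. Flag = enriched at
    q < alpha. Untestable circRNAs are reported unflagged."""
    results = run_enrichment(tables, alpha=alpha, seed=seed,
                             min_boot_draws=min_boot_draws)
    return {r.circ_id: r.enriched for r in results}


def flag_ribosome(cands: Sequence[BsjCandidate],
                  footprints: Iterable[ChimericJunctionRecord],
                  min_reads: int = 2) -> dict[str, bool]:
    """Ribosome association: >= min_reads footprint reads spanning the
    exact BSJ (same chrom/strand, breakpoints at the circ boundaries)."""
    from .bsj import call_bsjs

    fp = {c.key: c.total_reads for c in call_bsjs(footprints)}
    return {c.circ_id: fp.get(c.key, 0) >= min_reads for c in cands}


def set_overlap_report(set_a: set, set_b: set) -> dict:
    """Exact set arithmetic between two circ-identity sets.

    fraction_a = |A∩B|/|A| (None when A is empty), symmetrically for B."""
    inter = set_a & set_b
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_intersection": len(inter),
        "fraction_a": len(inter) / len(set_a) if set_a else None,
        "fraction_b": len(inter) / len(set_b) if set_b else None,
    }


def integrate(cands: Sequence[BsjCandidate],
              ago2_peaks: Sequence[Peak] = (),
              m6a_tables: Sequence[CircLinearCounts] = (),
              footprints: Iterable[ChimericJunctionRecord] = (),
              alpha: float = 0.05,
              min_ribo_reads: int = 2,
              seed: int = 0) -> list[IntegrationFlags]:
    """Compute all three evidence flags for every candidate."""
    per_circ, _ = overlap_peaks(cands, list(ago2_peaks))
    m6a = flag_m6a(list(m6a_tables), alpha=alpha, seed=seed) \
        if m6a_tables else {}
    ribo = flag_ribosome(cands, footprints, min_reads=min_ribo_reads)
    return [IntegrationFlags(
        circ_id=c.circ_id,
        ago2_peak_count=per_circ.get(c.circ_id, 0),
        m6a_flag=bool(m6a.get(c.circ_id, False)),
        ribo_flag=bool(ribo.get(c.circ_id, False)),
    ) for c in cands]
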