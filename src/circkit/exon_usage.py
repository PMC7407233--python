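"""Exon-level differential usage under RNase R and circRNA composition.

RNase R degrades linear transcripts; exons included in a circRNA are
protected and gain *relative* abundance under treatment. For each exon e
of gene g the per-sample count y_ej is modelled negative-binomial with a
log-linear mean containing an offset for the per-sample gene total T_gj
and a treatment-group effect:

    y_ej ~ NB(mu_ej, dispersion_e),  log mu_ej = log T_gj + b0 + b1 [treated]

The offset makes the test target relative exon usage, so gene-level
RNase R depletion cancels. The group effect is tested by LRT (1 df
chi-square); exons with significantly positive change are called RNase
R-resistant, significantly negative depleted, otherwise inconclusive.
Dispersion is per-exon method of moments (Pearson-based, floored at
1e-4); no information sharing across exons.

Compositions: the annotated exons of a candidate are the canonical-
transcript exons fully inside its BSJ interval; the resistant subset is
those flagged resistant. An empty resistant subset is the fully-depleted
pattern (a circRNA not expressed in that system).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotation import GenomeAnnotation
from .bsj import BsjCandidate
from .enrichment import adjust_fdr

_DISP_FLOOR = 1e-4

RESISTANT, DEPLETED, INCONCLUSIVE = "resistant", "depleted", "inconclusive"


@dataclass
class ExonUsageResult:
    gene_id: str
    exon_id: str
    chrom: str
    start: int
    end: int
    rel_logFC: float      # log2 change in relative usage, treated vs untreated
    dispersion: float
    p_value: Optional[float]
    q_value: Optional[float] = None
    status: str = INCONCLUSIVE


@dataclass
class CircExonComposition:
    circ_id: str
    annotated_exons: list[tuple[int, int]]
    resistant_exons: list[tuple[int, int]]
    approximate: bool = False

    @property
    def annotated_exon_count(self) -> int:
        return len(self.annotated_exons)

    @property
    def resistant_exon_count(self) -> int:
        return len(self.resistant_exons)

    @property
    def resistant_indices(self) -> set[int]:
        """1-based indices of resistant exons within the circRNA."""
        return {i + 1 for i, ex in enumerate(self.annotated_exons)
                if ex in set(self.resistant_exons)}


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Pearson method-of-moments NB dispersion alpha (Var = mu + alpha mu^2)."""
    df = max(len(y) - n_params, 1)
    num = float(np.sum(((y - mu) ** 2 - mu) / np.maximum(mu, 1e-8) ** 2))
    return max(num / df, _DISP_FLOOR)


def _nb_lrt(y: np.ndarray, offset: np.ndarray, g: np.ndarray,
            alpha: Optional[float] = None) -> tuple[float, float, float]:
    """Fit NB GLMs with and without the group effect; return
    (log2 fold change, dispersion, p). `alpha` fixes the dispersion
    (otherwise per-exon method of moments)."""
    X_alt = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
    X_null = X_alt[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha is None:
            # pilot Poisson fit to anchor the dispersion estimate
            pois = sm.GLM(y, X_alt, family=sm.families.Poisson(),
                          offset=offset).fit()
            alpha = _moment_dispersion(y, pois.fittedvalues, X_alt.shape[1])
        fam = sm.families.NegativeBinomial(alpha=alpha)
        fit_alt = sm.GLM(y, X_alt, family=fam, offset=offset).fit()
        fit_null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
    lrt = max(0.0, 2.0 * (fit_alt.llf - fit_null.llf))
    p = float(stats.chi2.sf(lrt, df=1))
    lfc = float(fit_alt.params[1] / np.log(2.0))
    return lfc, alpha, p


def test_exon_usage(table: pd.DataFrame, alpha: float = 0.05
                    ) -> list[ExonUsageResult]:
    """Differential exon usage between treated and untreated samples.

    `table` is long format with columns gene_id, exon_id, chrom, start,
    end, sample_id, group ('untreated'/'treated'), count. Per-sample gene
    totals are the summed exon counts of the gene; samples where a gene
    total is zero are dropped for that gene's exons. All-zero exons are
    skipped. BH correction runs across all tested exons.
    """
    req = {"gene_id", "exon_id", "sample_id", "group", "count"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"exon count table lacks columns: {sorted(missing)}")
    n_per_group = table.groupby("group")["sample_id"].nunique()
    if n_per_group.reindex(["untreated", "treated"]).fillna(0).min() < 2:
        raise ValueError("need >= 2 samples per group")

    totals = (table.groupby(["gene_id", "sample_id"])["count"].sum()
              .rename("gene_total"))
    tab = table.merge(totals, on=["gene_id", "sample_id"])
    results: list[ExonUsageResult] = []
    for (gene, exon), sub in tab.groupby(["gene_id", "exon_id"], sort=True):
        sub = sub[sub["gene_total"] > 0]
        y = sub["count"].to_numpy(dtype=float)
        if len(y) < 4 or y.sum() == 0:
            continue
        g = (sub["group"] == "treated").to_numpy()
        if g.all() or (~g).all():
            continue
        offset = np.log(sub["gene_total"].to_numpy(dtype=float))
        lfc, disp, p = _nb_lrt(y, offset, g)
        chrom = str(sub["chrom"].iloc[0]) if "chrom" in sub else "."
        start = int(sub["start"].iloc[0]) if "start" in sub else -1
        end = int(sub["end"].iloc[0]) if "end" in sub else -1
        results.append(ExonUsageResult(
            gene_id=str(gene), exon_id=str(exon), chrom=chrom,
            start=start, end=end, rel_logFC=lfc, dispersion=disp, p_value=p))
    qs = adjust_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
        if q is not None and q < alpha:
            r.status = RESISTANT if r.rel_logFC > 0 else DEPLETED
    return results


def compose_circular_exons(cand: BsjCandidate,
                           results: Sequence[ExonUsageResult],
                           ann: GenomeAnnotation) -> CircExonComposition:
    """Reconstruct the internal exon composition of one circRNA.

    Annotated exons are the host gene's canonical-transcript exons fully
    inside [start, end), in transcription order; the resistant subset is
    those whose usage result is 'resistant'. A candidate without any
    annotated exon inside its interval yields a zero-exon composition
    (single-exon/intronic candidate, flagged approximate).
    """
    if cand.host_gene is None:
        raise ValueError(f"{cand.circ_id}: host gene not assigned")
    gene = ann.genes[cand.host_gene]
    exons = [(s, e) for s, e in gene.canonical_transcript.exons
             if s >= cand.start and e <= cand.end]
    by_iv = {(r.start, r.end): r for r in results if r.gene_id == cand.host_gene}
    resistant = [ex for ex in exons
                 if by_iv.get(ex) is not None and by_iv[ex].status == RESISTANT]
    return CircExonComposition(
        circ_id=cand.circ_id, annotated_exons=exons, resistant_exons=resistant,
        approximate=(len(exons) == 0),
    )


IDENTICAL, DIFFERENTIAL, NOT_COMPARABLE = "identical", "differential", "not_comparable"


def compare_compositions(a: CircExonComposition,
                         b: CircExonComposition) -> str:
    """identical / differential / not_comparable between two systems.

    Comparable only for the same BSJ identity; differential iff the
    resistant subsets differ."""
    if a.circ_id != b.circ_id:
        return NOT_COMPARABLE
    return DIFFERENTIAL if set(a.resistant_exons) != set(b.resistant_exons) \
        else IDENTICAL


def annotation_vs_resistant_summary(
        compositions: Sequence[CircExonComposition]) -> dict:
    """Paired annotated vs resistant exon counts with a rank-sum test.

    The annotation overestimates circRNA exon content whenever exons
    inside the BSJ interval are not exonuclease-resistant; the summary
    quantifies that gap."""
    if len(compositions) < 2:
        raise ValueError("nothing to summarize: need >= 2 compositions")
    annotated = np.array([c.annotated_exon_count for c in compositions])
    resistant = np.array([c.resistant_exon_count for c in compositions])
    if np.array_equal(annotated, resistant):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ranksums(annotated, resistant)
    return {
        "n": len(compositions),
        "median_annotated": float(np.median(annotated)),
        "median_resistant": float(np.median(resistant)),
        "statistic": float(stat),
        "p_value": float(p),
    }


def write_compositions_bed12(compositions: Sequence[CircExonComposition],
                             cands: dict[str, BsjCandidate], path) -> None:
    """BED12 export; blocks are the resistant exons."""
    with open(path, "w") as fh:
        for comp in compositions:
            c = cands[comp.circ_id]
            blocks = sorted(comp.resistant_exons) or [(c.start, c.start + 1)]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - c.start) for s, _ in blocks)
            fh.write("\t".join(map(str, [
                c.chrom, c.start, c.end, comp.circ_id, c.total_reads, c.strand,
                c.start, c.end, "0,0,0", len(blocks), sizes, starts,
            ])) + "\n")
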