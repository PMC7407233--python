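# Methods

circkit implements the computational workflow of a CircleSeq-style
circRNA study: an rRNA-depleted RNA pool is split into an RNase
R-treated and a mock-treated half before library preparation, so that
covalently closed circRNAs — which the 3'→5' exonuclease cannot degrade
— stand out against their linear host transcripts. Everything downstream
of read alignment is covered: back-splice junction (BSJ) calling from
chimeric-alignment records, candidate filtering, enrichment testing,
exon-level resistance analysis, AUG-class genomics, cross-species
liftover, and evidence-track integration. All stages are exercised
end-to-end on synthetic data with planted truth.

## BSJ calling and candidate filtering

A chimeric read supports a BSJ when its two segments lie on one
chromosome and strand with the splice order inverted relative to linear
splicing: on the plus strand the acceptor breakpoint is upstream of the
donor (and mirrored on the minus strand). Reads are aggregated per
sample over the (chrom, start, end, strand) identity; the candidate
interval is the genomic span of the circle, 0-based half-open.

Filters, applied in sequence:

1. **Read support** — at least `min_reads` (default 2) BSJ reads in at
   least `min_samples` (default 2) samples.
2. **Junction proportion** — circular/(circular + linear) ≥ 1% where the
   linear count is the number of linearly spliced reads sharing either
   splice site, pooled over *untreated* samples only (RNase R destroys
   the linear denominator in treated libraries). Skipped with a logged
   notice when linear counts are unavailable.
3. **Repeat mask** — any half-open overlap with a masked interval (BED,
   e.g. RepeatMasker) removes the candidate. Masking is interval
   exclusion, not sequence masking, since no alignment happens here.

Filtering is idempotent and its output is order-canonical. A
treated-only mode (heart-tissue designs without untreated libraries)
applies the read-support filter alone and skips enrichment testing.

Host genes are assigned to the same-strand gene whose exons overlap both
BSJ endpoints; ties go to larger exonic overlap, then lexicographically
smaller gene id. Localization relative to the canonical transcript's CDS
span yields the categories CDS / 5UTR / 3UTR / 5UTR-3UTR /
noncoding_host / antisense / intergenic. The canonical transcript is the
GTF-tagged one when present, else longest CDS, then longest exonic
length, then lexicographic id — annotation formats rarely pin this down,
so the rule is explicit and deterministic.

Two candidates of one host gene are alternative-splicing variants when
they share exactly one BSJ coordinate; a candidate only counts with
more than 3 supporting reads. The reported rate is the fraction of
candidates participating in at least one variant pair.

## Beta-binomial enrichment test

For one circRNA with per-sample circular counts c_j and linear counts
l_j (totals n_j = c_j + l_j), the circular fraction is modelled

    c_j ~ BetaBinomial(n_j, mu_j, rho),  logit(mu_j) = b0 + b1·[treated],

with a shared intra-class correlation rho ∈ [1e-6, 0.999] capturing
replicate overdispersion (rho → 0 recovers the binomial GLM; the suite
checks that limit against statsmodels). Parameters are fitted by maximum
likelihood (Nelder-Mead on (b0, b1, logit rho); method-of-moments
initialization; no random restarts), and the group effect is tested by a
likelihood-ratio statistic against the b1 = 0 null.

With 2-4 replicates per group the 1-df chi-square reference is
anti-conservative (empirically ~8-10% type-I error at nominal 5% under
the default conditions). The family-level procedure therefore replaces
the chi-square p with a **pooled parametric-bootstrap p**: for every
testable circRNA a few datasets are drawn from its fitted null model and
refitted; the null LRT draws are pooled across the family (at least
~1,500 draws by default) and each circRNA's p-value is the pooled
exceedance probability of its observed statistic. This is exchangeable
under label permutation and deterministic given the seed. The assumption
it adds is homogeneity of the null LRT distribution across the family;
the suite's calibration check (1,000 null circRNAs, totals ~100, rho
0.01, 3 vs 3) verifies the resulting type-I error empirically.

Benjamini-Hochberg correction runs within one contrast (one cell
model). The **enriched** call requires q < alpha (default 0.05) *and* a
positive effect — the directional claim the RNase R design makes.
Untestable circRNAs (a group without coverage, or non-convergence)
carry a missing p, never a silent 1.0. The same machinery tests m6A
IP-vs-control counts; the m6A flag is the enriched call of that
contrast.

## Exon-level RNase R resistance and composition

Exons included in a circRNA are protected from RNase R and gain
*relative* abundance under treatment. Per exon e of gene g:

    y_ej ~ NB(mu_ej, alpha_e),  log mu_ej = log T_gj + b0 + b1·[treated],

where T_gj is the per-sample gene total (the summed exon counts), so
gene-level depletion cancels and the test targets relative exon usage.
Dispersion alpha_e is per-exon Pearson method of moments around a pilot
Poisson fit, floored at 1e-4 and not shared across exons; GLM fits go
through statsmodels, the group effect through a 1-df LRT, and BH runs
across all tested exons. Significant positive relative change =
**resistant**, negative = **depleted**, else inconclusive.

A circRNA's composition is the set of canonical-transcript exons fully
inside its interval that are resistant. An empty resistant set is the
fully-depleted pattern — a circRNA of that locus is not expressed in
this system. Compositions of the same BSJ from two systems are
*differential* when their resistant sets differ.

Two structural limits are worth stating. First, relative-usage testing
is zero-sum: if circRNA exons carry weight share W of a gene, an
absolute protection factor f appears as a relative shift of only
f/(1+(f−1)W); genes almost fully covered by circRNAs cannot show exon
resistance by construction, whatever the depth. Second, exact
composition recovery across a study is limited by the exon-level FDR: at
q < 0.05 a handful of false resistant/depleted calls per few hundred
exons is expected, so study-wide exact-match rates plateau around
95-98% rather than 100%; the acceptance report states the measured rate.

## AUG circRNAs and flank features

An **AUG circRNA** contains the first base of its host gene's canonical
start codon inside the BSJ interval (on the minus strand, codon base 1
is the largest coordinate of the codon). The classification depends on
annotation and interval only — never on exon composition.

Flank features:

- **Flanking intron lengths** — the introns adjacent to the circle's
  first and last exon in transcription order; missing at terminal
  exons; computed from nearest enclosing exon boundaries (flagged
  approximate) when a BSJ does not coincide with annotated boundaries.
- **Alu pair distance** — inverted (reverse-complementary) Alu pairs in
  the flanks promote back-splicing by looping the locus. Among pairs of
  (upstream Alu ending within 100 kb of the start, downstream Alu
  starting within 100 kb of the end) with opposite strands, the distance
  is the summed flank gap; the minimum over pairs is reported, missing
  when no opposite-orientation pair exists. The metric and window are
  configuration, and changing them never alters AUG calls.
- **Host translation** — per-gene ribosome-profiling P-site counts,
  normalized to counts per million per library, averaged per gene, and
  compared between AUG-host and non-AUG-host genes by Wilcoxon rank-sum
  with the direction reported.

Distribution comparisons use the two-sided KS test (asymptotic) or the
rank-sum test (exact for small samples, so toy examples match hand
enumeration). For mRNAs hosting no circRNA, the flank anchor is the span
of the gene's longest internal consecutive exon pair — a placeholder
choice, labelled as such.

## Cross-species conservation

UCSC chain files are parsed with full block validation (source strand
'+', block lengths closing both coordinate ranges; reverse-strand target
coordinates are converted to forward-strand internally). Both BSJ
endpoints (first and last base of the interval) map through the
highest-scoring chain covering each base, ties to the lowest chain id.
Statuses: **mapped** (same chain, coordinates re-ordered and strand
flipped for reverse-strand chains), **unmapped** (an endpoint in a gap
or uncovered), **split** (different chains, compatible target),
**strand_inconsistent** (different chains disagreeing on target
chromosome or strand).

Cross-verification matches a lifted interval against the target
species' circRNA set within ±slack bp (default 0: exact BSJ equality) at
both ends, same strand; strict mode additionally requires the target
circRNA to be RNase R-enriched — the stringent multi-species analysis.
Named sets are reduced to disjoint Venn-region counts that sum to the
union size. Both "mapped at all" and "shared after verification" counts
are reported separately, since the two definitions genuinely differ.

## Track integration

Ago2 CLIP peaks are assigned to candidates by ≥1 bp half-open overlap,
strand-agnostic by default (CLIP peak strand is unreliable); a peak may
belong to several circRNAs and both per-circ and per-peak counts are
reported. Ribosome association requires at least 2 footprint reads
spanning exactly the BSJ. Set overlaps are exact set arithmetic with
|A∩B|/|A| fractions.

## Synthetic data and what it does (not) show

The generator emulates the paired design: 3 treated + 3 untreated
libraries, a 30-gene two-chromosome toy genome (10-14 exons per gene,
every fifth gene with a second shorter isoform, one in ten noncoding),
60 planted circRNAs plus 8 filter-failure decoys (low support,
single-sample support, sub-1% proportion, repeat overlap), Alu/Ago2
tracks, m6A IP counts, ribosome footprints, P-site tables, and two
extra species with chain files planting every liftover status.

Key planted conditions (defaults, chosen to mirror the emulated study):
circular fraction 0.1 untreated rising to 0.6 for enriched circRNAs
(60% of circs), rho 0.01, junction totals ~150 per sample; exon-table
gene depth 1,000 per sample with relative uplift 4 for included exons
(solved per gene against the zero-sum constraint above) and 20% exon
dropout; 30% AUG circRNAs whose host genes draw 3-8 kb introns versus
0.3-1.5 kb and whose planted Alu pairs sit ~6 kb versus ~2 kb out; an
alternative-splicing regime of ~3.4% at the default size; 40% planted
conservation with 70% of targets enriched. Truth fields that geometry
can perturb (realized Alu distance, variant participation, peak counts,
filter survival) are recomputed from the emitted records by independent
brute-force restatements of the definitions, so truth always matches
the files actually written.

Randomness is organized as sub-streams keyed by (seed, domain, record
index): adding records never reshuffles existing ones, and identical
config+seed gives byte-identical output files.

What passing on this generator shows: the statistical procedures are
calibrated and powerful under their own model assumptions, and the
deterministic machinery (filters, liftover, overlap, classification) is
exactly correct against brute force. What it does not show: robustness
to misalignment artifacts, PCR duplicates, annotation errors, Alu
annotation incompleteness, or count distributions departing from
beta-binomial/NB — real-data concerns that no simulation of this kind
can certify.

## Problem sizes and numerics

The default study (30 genes / 60 circRNAs / 3+3 samples / 2 species)
runs the full pipeline in well under a minute; the calibration and
recovery studies use 1,000-circRNA families and 500-exon tables, sized
so the whole suite completes in minutes on one CPU. Optimizer
tolerances: Nelder-Mead xatol 1e-6 / fatol 1e-9; a rho estimate pinned
at its boundary leaves a flat simplex direction, which is accepted as
converged when the final simplex spread is below 1e-7. The LRT is
clamped at 0 (the alternative nests the null). BH is implemented as the
standard step-up with missing values passed through untouched.
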