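# circkit

Detection and characterization of circular RNAs (circRNAs) from
CircleSeq-style experiments — paired RNase R-treated / untreated RNA-seq
libraries — aimed at cardiovascular transcriptomics but generic in its
inputs.

circRNAs are covalently closed rings produced by back-splicing; the only
read-level signature unique to a circRNA is a read spanning its
back-splice junction (BSJ), and the only assay-level signature is
resistance to the 3'→5' exonuclease RNase R. circkit covers the
computational workflow downstream of read alignment:

- **BSJ calling** from chimeric-alignment junction records, with the
  candidate filters: ≥2 supporting reads in ≥2 samples, ≥1% junction
  proportion circ/(circ+linear) in pooled untreated samples, and
  repeat-mask exclusion.
- **RNase R enrichment testing** of the circular fraction
  c/(c+l) by a beta-binomial model with logit-linear mean,
  `logit(mu_j) = b0 + b1·[treated]`, shared intra-class correlation rho,
  a likelihood-ratio test with pooled parametric-bootstrap calibration,
  and Benjamini-Hochberg correction. The same test flags
  m6A-methylated circRNAs from IP-vs-control counts.
- **RNase R-resistant exons** by a negative-binomial log-linear model of
  exon counts with a gene-total offset (relative exon usage), giving
  each circRNA's internal exon composition and cross-system composition
  differences.
- **AUG circRNA analysis**: circRNAs containing their host gene's
  canonical start codon, compared with non-AUG circRNAs for expression,
  inverted-Alu-pair distance, flanking intron length (KS tests) and
  host-gene translation from ribosome-profiling P-site counts.
- **Cross-species conservation** by UCSC chain-file liftover of BSJ
  coordinates with cross-verification against target-species
  expressed/enriched circRNA sets and multi-species Venn partitions.
- **Evidence tracks**: Ago2 CLIP peak overlap and
  BSJ-spanning ribosome footprints.
- A **synthetic-data generator** that emulates the full study design
  with planted ground truth, so every stage is testable end to end
  without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic data; each writes its tables under `results/`.

```bash
python analysis/01_simulate.py
python analysis/02_detect_filter.py
python analysis/03_enrichment.py
python analysis/04_exon_usage.py
python analysis/05_aug_features.py
python analysis/06_conservation.py
python analysis/07_track_integration.py
```

Output of the detection and enrichment steps (seed 20260927):

```
14462 chimeric reads -> 68 called BSJs -> 60 candidates after filtering
localization distribution:
CDS           38
5UTR          17
antisense      2
3UTR           2
intergenic     1
alternative-splicing variants: 1 pairs, rate 3.3%

68 circRNAs tested, 41 enriched (q < 0.05, positive effect)
planted enriched: 39; recovered: 39 (100%); false calls: 2
median fitted treated fraction of enriched circRNAs: 0.60
```

Reading this: of 68 aggregated junction candidates, the 8 planted
filter decoys are removed (low support, single-sample support, sub-1%
junction proportion, repeat overlap). Most survivors originate inside
the CDS of their host genes, a smaller share reaches into a UTR, and a
few lie antisense to or between genes. The beta-binomial test recovers
all 39 circRNAs planted with a treated circular fraction of 0.6
(untreated 0.1), and the fitted fractions land on the planted value.

The exon, AUG, conservation and track steps continue the same study:

```
324 exons tested, 70 RNase R-resistant
composition reconstruction: 55/57 exact (96%)
annotated vs resistant exons per circRNA: medians 2 vs 1, rank-sum p = 0.004

17 AUG vs 40 non-AUG circRNAs
  alu_pair_distance: medians 5443 (AUG) vs 1810 (non-AUG), KS p = 0
  upstream_intron: medians 4977 (AUG) vs 839 (non-AUG), KS p = 0
  host translation: AUG < non-AUG, rank-sum p = 3.1e-05

pig: {'mapped': 54, 'unmapped': 1, 'split': 1, 'strand_inconsistent': 1}
circRNAs conserved and enriched in all species: 4
```

The annotation overestimates circRNA exon content relative to the
RNase R-resistant exons (medians 2 vs 1); AUG circRNAs show the larger
Alu-pair distances, longer flanking introns and lower host-gene
translation that were planted; and liftover recovers every planted
conservation status.

A `circkit` CLI exposes the same stages
(`simulate / detect / enrich / exons / aug / conserve / integrate /
run / report`); `circkit run --config pipeline.yaml` drives them from
one YAML file. See `docs/methods.md` for models, parameter defaults and
limitations.

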