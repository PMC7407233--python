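"""End-to-end orchestration: detect -> enrich -> exons -> aug -> conserve
-> integrate -> report.

The pipeline is a thin, explicitly-ordered driver over the library
modules. It reads a single config (YAML or constructed in code), logs a
per-stage attrition table, and writes machine-readable JSON plus TSVs
for every figure-analog (localization distribution, enrichment results,
exon compositions, AUG feature tests, conservation partition). A
treated-only mode supports designs where no untreated libraries exist
(heart tissue): the enrichment test is skipped and candidates pass on
the read-support filter alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, annotation as ann_mod, aug as aug_mod, bsj
from . import conservation as cons_mod
from . import enrichment as enr_mod
from . import exon_usage as exu_mod
from . import tracks as trk_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    gtf: Optional[str] = None
    junctions: Optional[str] = None
    circ_linear_counts: Optional[str] = None
    exon_counts: Optional[str] = None
    mask_bed: Optional[str] = None
    alu_bed: Optional[str] = None
    ago2_bed: Optional[str] = None
    m6a_counts: Optional[str] = None
    ribo_junctions: Optional[str] = None
    psites: Optional[str] = None
    chains: dict = field(default_factory=dict)        # species -> chain path
    target_circs: dict = field(default_factory=dict)  # species -> TSV path
    seed: int = 0
    alpha: float = 0.05
    min_reads: int = 2
    min_samples: int = 2
    min_junction_proportion: float = 0.01
    lift_slack: int = 0
    strict_conservation: bool = True
    alu_window: int = 100_000
    min_ribo_reads: int = 2
    treated_only: bool = False
    stages: tuple[str, ...] = ("detect", "enrich", "exons", "aug",
                               "conserve", "integrate")

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")

    def validate_paths(self) -> None:
        for name in ("gtf", "junctions", "circ_linear_counts", "exon_counts",
                     "mask_bed", "alu_bed", "ago2_bed", "m6a_counts",
                     "ribo_junctions", "psites"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for d in (self.chains, self.target_circs):
            for p in d.values():
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def attach_linear_counts(cands: list[bsj.BsjCandidate],
                         counts: pd.DataFrame) -> None:
    """Attach per-sample linear splice counts from the circ/linear count
    table (columns circ_id, sample_id, linear_count) to candidates in
    place; candidates absent from the table keep empty linear counts."""
    by_circ: dict[str, dict[str, int]] = {}
    for row in counts.itertuples(index=False):
        by_circ.setdefault(row.circ_id, {})[row.sample_id] = int(row.linear_count)
    for c in cands:
        if c.circ_id in by_circ:
            c.linear_counts = by_circ[c.circ_id]


def load_target_circs(path) -> tuple[list[bsj.BsjCandidate], dict[str, bool]]:
    """Target-species circ set TSV (chrom, start, end, strand, circ_id,
    enriched) -> candidates + enrichment flags keyed by circ_id."""
    df = pd.read_csv(path, sep="\t")
    cands, flags = [], {}
    for row in df.itertuples(index=False):
        c = bsj.BsjCandidate(chrom=str(row.chrom), start=int(row.start),
                             end=int(row.end), strand=str(row.strand))
        cands.append(c)
        flags[c.circ_id] = bool(row.enriched)
    return cands, flags


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the run
    report (also written to <out_dir>/report.json)."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "artifacts": {},
    }
    if not cfg.stages:
        _finish(report, out)
        return report

    ann = ann_mod.load_annotation(cfg.gtf) if cfg.gtf else None
    cands: list[bsj.BsjCandidate] = []
    enr_results: list[enr_mod.EnrichmentResult] = []
    exon_results: list[exu_mod.ExonUsageResult] = []

    if "detect" in cfg.stages:
        records = list(bsj.read_junction_tsv(cfg.junctions))
        cands = bsj.call_bsjs(records)
        n_called = len(cands)
        counts_df = (pd.read_csv(cfg.circ_linear_counts, sep="\t")
                     if cfg.circ_linear_counts else None)
        if counts_df is not None:
            attach_linear_counts(cands, counts_df)
            untreated = set(counts_df.loc[counts_df["group"] == "untreated",
                                          "sample_id"])
        else:
            untreated = None
        params = bsj.FilterParams(
            min_reads=cfg.min_reads, min_samples=cfg.min_samples,
            min_junction_proportion=cfg.min_junction_proportion,
            mask_intervals=(bsj.load_mask_bed(cfg.mask_bed)
                            if cfg.mask_bed else {}),
            untreated_samples=untreated or None,
        )
        cands = bsj.filter_candidates(cands, params)
        if ann is not None:
            for c in cands:
                c.host_gene = ann_mod.assign_host_gene(
                    c.chrom, c.start, c.end, c.strand, ann)
                c.localization = ann_mod.classify_localization(
                    c.chrom, c.start, c.end, c.strand, c.host_gene, ann)
        loc_counts = pd.Series([c.localization for c in cands]
                               ).value_counts().to_dict()
        report["stages"]["detect"] = {
            "n_records": len(records), "n_called": n_called,
            "n_filtered": len(cands), "localization": loc_counts,
        }
        bsj.write_candidates_bed(cands, out / "candidates.bed")
        report["artifacts"]["candidates_bed"] = "candidates.bed"

    if "enrich" in cfg.stages and not cfg.treated_only \
            and cfg.circ_linear_counts:
        counts_df = pd.read_csv(cfg.circ_linear_counts, sep="\t")
        keep = {c.circ_id for c in cands} if cands else None
        if keep is not None:
            counts_df = counts_df[counts_df["circ_id"].isin(keep)]
        tables = enr_mod.counts_from_frame(counts_df)
        enr_results = enr_mod.run_enrichment(tables, alpha=cfg.alpha,
                                             seed=cfg.seed,
                                             min_boot_draws=300)
        enr_frame = enr_mod.results_to_frame(enr_results)
        enr_frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["stages"]["enrich"] = {
            "n_tested": int(enr_frame["p_value"].notna().sum()),
            "n_enriched": int(enr_frame["enriched"].sum()),
        }
        report["artifacts"]["enrichment_tsv"] = "enrichment.tsv"

    compositions: list[exu_mod.CircExonComposition] = []
    if "exons" in cfg.stages and cfg.exon_counts and not cfg.treated_only:
        exon_table = pd.read_csv(cfg.exon_counts, sep="\t")
        exon_results = exu_mod.test_exon_usage(exon_table, alpha=cfg.alpha)
        n_res = sum(1 for r in exon_results if r.status == exu_mod.RESISTANT)
        hosted = [c for c in cands if c.host_gene]
        for c in hosted:
            compositions.append(
                exu_mod.compose_circular_exons(c, exon_results, ann))
        report["stages"]["exons"] = {
            "n_exons_tested": len(exon_results),
            "n_resistant": n_res,
            "n_compositions": len(compositions),
        }
        if len(compositions) >= 2:
            report["stages"]["exons"]["annotation_vs_resistant"] = \
                exu_mod.annotation_vs_resistant_summary(compositions)
        exu_mod.write_compositions_bed12(
            compositions, {c.circ_id: c for c in cands},
            out / "compositions.bed12")
        report["artifacts"]["compositions_bed12"] = "compositions.bed12"

    if "aug" in cfg.stages and ann is not None:
        alu = aug_mod.load_alu_bed(cfg.alu_bed) if cfg.alu_bed else {}
        rows = []
        for c in cands:
            call = aug_mod.classify_aug(c, ann)
            feat = {"circ_id": c.circ_id, "is_aug": call.is_aug,
                    "total_reads": c.total_reads}
            if c.host_gene:
                up, down, approx = aug_mod.flanking_intron_lengths(c, ann)
                feat.update(upstream_intron=up, downstream_intron=down,
                            approximate=approx)
                feat["alu_pair_distance"] = (
                    aug_mod.alu_pair_distance(c, alu, window=cfg.alu_window)
                    if alu else None)
            rows.append(feat)
        aug_frame = pd.DataFrame(rows)
        aug_frame.to_csv(out / "aug_features.tsv", sep="\t", index=False)
        stage = {"n_aug": int(aug_frame["is_aug"].sum()),
                 "n_nonaug": int((~aug_frame["is_aug"]).sum())}
        if stage["n_aug"] and stage["n_nonaug"]:
            a = aug_frame[aug_frame["is_aug"]]
            b = aug_frame[~aug_frame["is_aug"]]
            for col, label in (("alu_pair_distance", "alu"),
                               ("upstream_intron", "upstream_intron"),
                               ("total_reads", "expression")):
                if col not in aug_frame:
                    continue
                x = a[col].dropna()
                y = b[col].dropna()
                if len(x) and len(y):
                    st, p = aug_mod.compare_distributions(x, y, test="ks")
                    stage[f"ks_{label}"] = {"statistic": st, "p_value": p}
            if cfg.psites:
                psites = pd.read_csv(cfg.psites, sep="\t")
                aug_hosts = {c.host_gene for c in cands if c.host_gene
                             and aug_mod.classify_aug(c, ann).is_aug}
                non_hosts = {c.host_gene for c in cands
                             if c.host_gene} - aug_hosts
                if aug_hosts and non_hosts:
                    tc = aug_mod.compare_host_translation(
                        psites, aug_hosts, non_hosts)
                    stage["translation"] = asdict(tc)
        report["stages"]["aug"] = stage
        report["artifacts"]["aug_features_tsv"] = "aug_features.tsv"

    if "conserve" in cfg.stages and cfg.chains:
        stage = {}
        conserved_by_species: dict[str, set[str]] = {}
        lift_rows = []
        for species, chain_path in sorted(cfg.chains.items()):
            cm = cons_mod.parse_chain(chain_path)
            lifted = [cons_mod.lift_bsj(c, cm) for c in cands]
            target_path = cfg.target_circs.get(species)
            if target_path:
                targets, flags = load_target_circs(target_path)
                recs = cons_mod.cross_verify(
                    lifted, targets, flags, slack=cfg.lift_slack,
                    strict=cfg.strict_conservation)
                conserved_by_species[species] = {
                    r.circ_id for r in recs if r.conserved}
            statuses = pd.Series([lr.status for lr in lifted]).value_counts()
            stage[species] = {
                "statuses": statuses.to_dict(),
                "n_mapped_at_all": int(statuses.get("mapped", 0)),
                "n_conserved": len(conserved_by_species.get(species, ())),
            }
            for lr in lifted:
                lift_rows.append({"species": species, **asdict(lr)})
        pd.DataFrame(lift_rows).to_csv(out / "liftover.tsv", sep="\t",
                                       index=False)
        report["artifacts"]["liftover_tsv"] = "liftover.tsv"
        if conserved_by_species:
            sets = dict(conserved_by_species)
            sets["source"] = {c.circ_id for c in cands}
            stage["partition"] = cons_mod.multi_species_partition(sets)
        report["stages"]["conserve"] = stage

    if "integrate" in cfg.stages:
        peaks = (trk_mod.load_peaks_bed(cfg.ago2_bed, "ago2")
                 if cfg.ago2_bed else [])
        m6a_tables = []
        if cfg.m6a_counts:
            m6a_df = pd.read_csv(cfg.m6a_counts, sep="\t")
            m6a_tables = enr_mod.counts_from_frame(m6a_df)
        footprints = (list(bsj.read_junction_tsv(cfg.ribo_junctions))
                      if cfg.ribo_junctions else [])
        flags = trk_mod.integrate(
            cands, peaks, m6a_tables, footprints, alpha=cfg.alpha,
            min_ribo_reads=cfg.min_ribo_reads, seed=cfg.seed)
        flag_frame = pd.DataFrame([asdict(f) for f in flags])
        flag_frame.to_csv(out / "integration.tsv", sep="\t", index=False)
        report["stages"]["integrate"] = {
            "n_with_ago2": int((flag_frame["ago2_peak_count"] > 0).sum())
            if len(flag_frame) else 0,
            "n_m6a": int(flag_frame["m6a_flag"].sum()) if len(flag_frame) else 0,
            "n_ribo": int(flag_frame["ribo_flag"].sum()) if len(flag_frame) else 0,
        }
        report["artifacts"]["integration_tsv"] = "integration.tsv"

    _finish(report, out)
    return report


def _finish(report: dict, out: Path) -> None:
    # attrition monotonicity is a structural guarantee; re-check it
    det = report["stages"].get("detect")
    enr = report["stages"].get("enrich")
    if det and enr:
        assert det["n_called"] >= det["n_filtered"] >= 0
        assert enr["n_enriched"] <= det["n_filtered"]
    for name, rel in report["artifacts"].items():
        p = out / rel
        if p.exists():
            report["artifacts"][name] = {
                "path": rel,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest()[:16],
            }
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=str))


def write_report(report: dict, out_dir) -> None:
    """Re-serialize a report bundle (JSON + per-section TSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    det = report.get("stages", {}).get("detect", {})
    if det.get("localization"):
        pd.Series(det["localization"]).rename_axis("category").rename(
            "count").reset_index().to_csv(out / "localization.tsv", sep="\t",
                                          index=False)
    cons = report.get("stages", {}).get("conserve", {})
    if isinstance(cons.get("partition"), dict):
        pd.Series(cons["partition"]).rename_axis("region").rename(
            "count").reset_index().to_csv(out / "partition.tsv", sep="\t",
                                          index=False)
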