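"""Shared fixtures: one default synthetic study per session, plus the
loaded annotation and a full pipeline run over it."""

from __future__ import annotations

import pytest

from circkit.annotation import load_annotation
from circkit.pipeline import PipelineConfig, run_pipeline
from circkit.simulate import SimulationConfig, simulate_all

DEFAULT_SEED = 20260927


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("simstudy")
    cfg = SimulationConfig(seed=DEFAULT_SEED)
    truth = simulate_all(cfg, out)
    return out, truth


@pytest.fixture(scope="session")
def truth(sim_dir):
    return sim_dir[1]


@pytest.fixture(scope="session")
def annotation(sim_dir):
    out, _ = sim_dir
    return load_annotation(out / "annotation.gtf")


@pytest.fixture(scope="session")
def pipeline_run(sim_dir, tmp_path_factory):
    out, _ = sim_dir
    run_dir = tmp_path_factory.mktemp("pipelinerun")
    cfg = PipelineConfig(
        out_dir=str(run_dir),
        gtf=str(out / "annotation.gtf"),
        junctions=str(out / "junctions.tsv"),
        circ_linear_counts=str(out / "circ_linear_counts.tsv"),
        exon_counts=str(out / "exon_counts.tsv"),
        mask_bed=str(out / "mask.bed"),
        alu_bed=str(out / "alu.bed"),
        ago2_bed=str(out / "ago2_peaks.bed"),
        m6a_counts=str(out / "m6a_counts.tsv"),
        ribo_junctions=str(out / "ribo_junctions.tsv"),
        psites=str(out / "psites.tsv"),
        chains={"pig": str(out / "pig.chain"),
                "mouse": str(out / "mouse.chain")},
        target_circs={"pig": str(out / "pig_circs.tsv"),
                      "mouse": str(out / "mouse_circs.tsv")},
        seed=DEFAULT_SEED,
    )
    report = run_pipeline(cfg)
    return run_dir, report
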