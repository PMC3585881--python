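"""Shared fixtures: one synthetic dataset and one full pipeline run per session."""

from __future__ import annotations

import pytest

import finchsmallrna as f
from finchsmallrna.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def sim_cfg() -> f.SimConfig:
    # depth 12,000 per library over 12 loci ~ 1,000 reads per locus per sample
    return f.SimConfig(seed=1, depth_per_sample=12_000)


@pytest.fixture(scope="session")
def sim_genome(sim_cfg):
    return f.make_genome(sim_cfg)


@pytest.fixture(scope="session")
def sim_reads(sim_cfg, sim_genome):
    return f.make_reads(sim_cfg, sim_genome)


@pytest.fixture(scope="session")
def sim_paths(sim_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return f.write_all(sim_cfg, outdir)


@pytest.fixture(scope="session")
def pipeline_cfg(sim_paths, tmp_path_factory) -> PipelineConfig:
    out = tmp_path_factory.mktemp("pipeline_out")
    return PipelineConfig(
        fastq=str(sim_paths["fastq"]),
        barcodes=str(sim_paths["barcodes"]),
        genome=str(sim_paths["genome"]),
        known_matures=str(sim_paths["known_matures"]),
        known_ncrna=str(sim_paths["known_ncrna"]),
        repeats_bed=str(sim_paths["repeats_bed"]),
        species_dir=str(sim_paths["species_dir"]),
        utrs=str(sim_paths["utrs"]),
        outdir=str(out),
    )


@pytest.fixture(scope="session")
def pipeline_report(pipeline_cfg):
    return run_all(pipeline_cfg)
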