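"""Shared fixtures: one genome system exercised by every pipeline stage.

The session-scoped system models the full study design at desk scale:

- a 12-kb mtDNA reference with an internal 400-bp repeat and a 300-bp
  plastid-homologous block;
- two nuclear "lines" sharing a 30-kb chromosome backbone, line A carrying
  a 1,000-bp numt (cognate mtDNA 4,001-5,000) whose interior holds 12
  divergent substitutions, line B lacking it entirely;
- 12 true heteroplasmic sites at 5% allele frequency in coupling phase
  (positions 7,000-7,110), present regardless of line;
- paired-end reads for line A at ~1,200x mtDNA depth with an mt:nu copy
  ratio of 50:1.
"""

from __future__ import annotations

import numpy as np
import pytest

from numtscan import homology, pileup, simulate

MT_LEN = 12_000
NUMT_COGNATE = (4_001, 5_000)
#: mtDNA positions of the numt's divergent substitutions (interior of the
#: cognate interval, >300 bp from either end so cross-mapping is unimpeded)
NUMT_SITE_OFFSETS = (350, 373, 401, 428, 460, 487, 509, 530, 561, 590, 615, 640)
NUMT_SITES = tuple(NUMT_COGNATE[0] - 1 + off for off in NUMT_SITE_OFFSETS)
HET_SITES = tuple(7_000 + 10 * i for i in range(12))
HET_FREQ = 0.05
REPEAT_COGNATE = (401, 800)
REPEAT_COPY_AT = 10_001
PT_BLOCK_COGNATE = (1_501, 1_800)


def transversion(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


@pytest.fixture(scope="session")
def sim_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=11,
        mt_depth=1_200,
        error_rate=0.002,
        copy_ratio_mt_nu=50.0,
        copy_ratio_pt_nu=50.0,
    )


@pytest.fixture(scope="session")
def genome_system(sim_config) -> simulate.GenomeSystem:
    plan = simulate.GenomePlan(
        mt_len=MT_LEN,
        pt_len=2_000,
        nuclear_lens={"chr1": 30_000},
        lines=("lineA", "lineB"),
        features=[],
    )
    backbone = simulate.build_genome_system(sim_config, plan)
    src = backbone.mt_seq[NUMT_COGNATE[0] - 1 : NUMT_COGNATE[1]]
    edits = tuple(
        simulate.Edit(offset=off, op="sub", ref=src[off - 1],
                      alt=transversion(src[off - 1]))
        for off in NUMT_SITE_OFFSETS
    )
    plan.features = [
        simulate.PlantedFeature(
            kind="mt_repeat", host="mt", start=REPEAT_COPY_AT,
            cognate_start=REPEAT_COGNATE[0], cognate_end=REPEAT_COGNATE[1],
            name="repeat1",
        ),
        simulate.PlantedFeature(
            kind="pt_homolog_in_mt", host="pt", start=501,
            cognate_start=PT_BLOCK_COGNATE[0], cognate_end=PT_BLOCK_COGNATE[1],
            name="ptblock",
        ),
        simulate.PlantedFeature(
            kind="numt", host="lineA:chr1", start=8_001,
            cognate_start=NUMT_COGNATE[0], cognate_end=NUMT_COGNATE[1],
            edits=edits, name="numt1",
        ),
    ]
    system = simulate.build_genome_system(sim_config, plan)
    het = [
        (p, transversion(system.mt_seq[p - 1]), HET_FREQ) for p in HET_SITES
    ]
    return simulate.inject_heteroplasmy(system, het, molecule_class="hetV")


@pytest.fixture(scope="session")
def line_a_reads(genome_system, sim_config) -> simulate.ReadSet:
    return simulate.simulate_reads(genome_system, "lineA", sim_config)


@pytest.fixture(scope="session")
def line_a_alignments(genome_system, line_a_reads) -> list[pileup.Alignment]:
    return pileup.map_reads_lightweight(line_a_reads, genome_system.mt_seq)


@pytest.fixture(scope="session")
def line_a_pileup(genome_system, line_a_alignments) -> pileup.PileupTable:
    return pileup.base_composition(line_a_alignments, genome_system.mt_seq)


@pytest.fixture(scope="session")
def line_a_sites(line_a_pileup) -> list[pileup.PolymorphicSite]:
    return pileup.call_intraindividual_sites(line_a_pileup)


def _partition_against(system, line: str) -> homology.CategoryPartition:
    mt = system.mt_seq
    self_hits = homology.find_local_homologies(mt, mt, subject_name="mt")
    nu_hits = homology.find_local_homologies(
        mt, system.nuclear[line]["chr1"], subject_name=f"{line}:chr1"
    )
    pt_hits = homology.find_local_homologies(mt, system.pt_seq, subject_name="pt")
    return homology.classify_categories(len(mt), self_hits, nu_hits, pt_hits)


@pytest.fixture(scope="session")
def partition_vs_line_a(genome_system) -> homology.CategoryPartition:
    """Partition computed against the numt-bearing nuclear reference."""
    return _partition_against(genome_system, "lineA")


@pytest.fixture(scope="session")
def partition_vs_line_b(genome_system) -> homology.CategoryPartition:
    """Partition computed against the numt-lacking nuclear reference."""
    return _partition_against(genome_system, "lineB")


@pytest.fixture(scope="session")
def read_truth(line_a_reads) -> dict[str, tuple[str, int, str]]:
    """read id -> (origin host, 1-based start, truth kind)."""
    truth = {}
    for p in line_a_reads.pairs:
        truth[p.id + "/1"] = (p.origin_host, p.start1, p.truth_kind)
        truth[p.id + "/2"] = (p.origin_host, p.start2, p.truth_kind)
    return truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
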