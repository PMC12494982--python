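import pytest

from tnseqmap.genome import compute_repeat_mask
from tnseqmap.insertions import merge_samples
from tnseqmap.metrics import metrics_table
from tnseqmap.simulate import (
    SimConfig,
    generate_annotation,
    generate_genome,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(genome_length=50_000, n_genes=60, seed=7)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Genome + annotation + repeat mask for a small default simulation."""
    genome, plants = generate_genome(small_cfg)
    annot = generate_annotation(small_cfg, genome)
    mask = compute_repeat_mask(genome)
    return small_cfg, genome, annot, mask, plants


@pytest.fixture(scope="session")
def merged_pt1(small_world):
    """Merged passage-1 P+T dataset on the small world."""
    cfg, genome, annot, mask, _ = small_world
    samples = simulate_library(cfg, genome, annot, "P", [1], 2)
    samples += simulate_library(cfg, genome, annot, "T", [1], 2)
    return merge_samples(samples, trim=0.05)


@pytest.fixture(scope="session")
def gene_ld_pt1(small_world, merged_pt1):
    cfg, genome, annot, mask, _ = small_world
    table = metrics_table(merged_pt1, annot, mask=mask)
    return table[table["ftype"] == "gene"]["ld"].dropna()


def simulate_ld_by_passage(cfg, genome, annot, mask, passages=(1, 2, 3, 4, 6, 8, 10)):
    """Per-passage merged-PT gene LD maps (helper shared by decay tests)."""
    ld = {}
    for p in passages:
        samples = simulate_library(cfg, genome, annot, "P", [p], 2)
        samples += simulate_library(cfg, genome, annot, "T", [p], 2)
        merged = merge_samples(samples, trim=0.05)
        table = metrics_table(merged, annot, mask=mask)
        ld[p] = table[table["ftype"] == "gene"]["ld"].dropna().to_dict()
    return ld
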