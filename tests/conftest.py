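import numpy as np
import pytest

from modcaller.features import build_dataset
from modcaller.pipeline import anchor_reads
from modcaller.simulate import (
    PoreModel,
    SimConfig,
    alignments_to_pysam,
    generate_genome,
    plant_modifications,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated study shared across tests.

    6 kb genome, ~6x coverage, half the CpG sites modified.
    """
    reference = {"sim1": generate_genome(6000, 0.5, seed=11)}
    truth = plant_modifications(reference, "CG", 0, 0.5, seed=12)
    pore = PoreModel(seed=13)
    cfg = SimConfig(genome_length=6000, read_length=1200, coverage=6.0, seed=14)
    reads, alignments = simulate_dataset(reference, truth, pore, cfg)
    records, header = alignments_to_pysam(alignments, reference)
    return {
        "reference": reference,
        "truth": truth,
        "pore": pore,
        "config": cfg,
        "reads": reads,
        "alignments": alignments,
        "records": records,
        "header": header,
    }


@pytest.fixture(scope="session")
def small_anchored(small_sim):
    return anchor_reads(small_sim["reads"], small_sim["records"], small_sim["reference"])


@pytest.fixture(scope="session")
def small_windows(small_sim, small_anchored):
    return build_dataset(
        small_anchored,
        small_sim["truth"],
        target_base="C",
        motif_restriction=("CG", 0),
        reference=small_sim["reference"],
        w=21,
    )
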