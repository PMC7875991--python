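"""Shared fixtures: a tiny hand-built reference and a simulated study.

All fixture data is generated programmatically; nothing is read from disk.
"""

import pytest

from mirtail.refio import HairpinRecord, MatureAnnotation
from mirtail.simulate import SimulationConfig, generate_reference, simulate_reads


@pytest.fixture(scope="session")
def tiny_reference():
    """One hand-built hairpin with a 5p and a 3p mature.

    The bases flanking each mature 3' end are C/G so that U/A tails are
    unambiguously nontemplated.
    """
    m5 = "ATGCCGTAGCATGCGATCGGTC"  # [20, 42)
    m3 = "TACGGATCCATTGCAGTACG"  # [46, 66)
    seq = "GGGGCCCCGGGGCCCCGGGG" + m5 + "CAGG" + m3 + "CGGC"
    hp = HairpinRecord(
        "hp-1",
        seq,
        [
            MatureAnnotation("mir-1-5p", "5p", 20, 42, m5),
            MatureAnnotation("mir-1-3p", "3p", 46, 66, m3),
        ],
    ).validate()
    return [hp]


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_hairpins=12, mean_depth=40_000, seed=7)


@pytest.fixture(scope="session")
def sim_reference(sim_config):
    return generate_reference(sim_config)


@pytest.fixture(scope="session")
def sim_study(sim_config, sim_reference):
    """A small simulated two-condition study with ground truth."""
    samples, truth = simulate_reads(sim_reference, sim_config)
    return samples, truth


def records_of(sample):
    """Raw-read records (seq, qual, count) of a simulated sample."""
    return [(seq, "I" * len(seq), count) for seq, count, _ in sample.records]
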