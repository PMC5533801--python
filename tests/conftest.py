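"""Shared fixtures: small simulated experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from radcapkit.records import ReadPair, SeqRead
from radcapkit.simdata import SimulationConfig, emit_reads, simulate_truth


def make_read(seq: str, q: int = 37, rid: str = "r") -> SeqRead:
    return SeqRead(rid, seq, np.full(len(seq), q, dtype=np.uint8))


def make_pair(seq1: str, seq2: str, q: int = 37, rid: str = "p",
              i5: str = "", i7: str = "") -> ReadPair:
    return ReadPair(make_read(seq1, q, rid + "/1"),
                    make_read(seq2, q, rid + "/2"), i5=i5, i7=i7)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_capture_experiment():
    """Three-species capture run with PCR duplicates, reused read-only."""
    cfg = SimulationConfig(seed=202, n_loci=40, n_individuals_per_species=4,
                           species_divergences={"A": 0.02, "B": 0.05,
                                                "C": 0.08},
                           duplicate_fraction=0.30)
    truth = simulate_truth(cfg)
    pairs, sheet = emit_reads(truth, cfg, "capture")
    return cfg, truth, pairs, sheet
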