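"""Core in-memory records shared by more than one pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SeqRead:
    """An identified nucleotide sequence with optional per-base quality.

    Qualities are Phred scores as a uint8 numpy array (not ASCII), same
    length as the sequence when present.
    """

    id: str
    seq: str
    qual: np.ndarray | None = None

    def __post_init__(self):
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_qual(self) -> float:
        if self.qual is None or len(self.qual) == 0:
            return 0.0
        return float(np.mean(self.qual))


@dataclass
class ReadPair:
    """A dual-indexed paired-end read; mates share an id stem."""

    read1: SeqRead
    read2: SeqRead
    i5: str = ""
    i7: str = ""

    @property
    def id(self) -> str:
        return self.read1.id.rsplit("/", 1)[0]


@dataclass
class SampleMeta:
    """Per-sample lab metadata as carried on the sample sheet."""

    sample: str
    species: str
    year: int | None = None
    a260_a280: float | None = None
    conc_ng_ul: float | None = None
    era: str = "modern"


def phred_to_ascii(qual: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in qual)


def ascii_to_phred(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 93:
        raise ValueError("quality string outside Phred+33 range")
    return arr.astype(np.uint8)
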