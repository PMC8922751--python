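"""Shared containers and conventions.

Channel order is fixed throughout the package: A, T, C, G, N at indices
0..4. Kernel matrices keep all five rows; position weight matrices (PWMs)
drop the N row and keep A, T, C, G at indices 0..3, every column summing
to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ATCGN"
NUCLEOTIDES = "ATCG"
CHANNEL_INDEX = {c: i for i, c in enumerate(ALPHABET)}
N_CHANNEL = 4

LABEL_EXPRESSED = "expressed"
LABEL_LOW = "low"
LABEL_CODES = {LABEL_LOW: 0, LABEL_EXPRESSED: 1}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A labeled TSS-centered sequence window."""

    gene_id: str
    sequence: str
    label: str  # "expressed" | "low"
    stage: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABEL_CODES:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def label_code(self) -> int:
        return LABEL_CODES[self.label]


@dataclass
class KernelMatrix:
    """First-layer convolution kernel: a 5 x L real matrix.

    Rows follow the package channel order A, T, C, G, N; row 4 is the
    cryptic-nucleotide (N) channel used as the bias control in the
    N-adjusted transformation.
    """

    matrix: np.ndarray
    stage: str = ""
    fold: int = -1
    kernel_index: int = -1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 5:
            raise ValueError(f"kernel must be 5 x L, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("kernel contains non-finite entries")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Pwm:
    """Column-stochastic 4 x L position weight matrix over A, T, C, G."""

    matrix: np.ndarray
    name: str = ""
    nsites: int = 20
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"PWM must be 4 x L, got {self.matrix.shape}")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError("PWM entries must lie in [0, 1]")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]
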