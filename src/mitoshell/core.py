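"""Shared sequence primitives.

Sequences are handled in two representations: plain Python strings over
``ACGTN`` at module boundaries, and compact ``uint8`` code arrays
(A=0, C=1, G=2, T=3, N=4) inside numerical kernels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement under the same coding; N stays N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string into a uint8 code array."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an ACGTN string."""
    return _DECODE[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array."""
    return _COMPLEMENT[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


@dataclass
class ReferenceGenome:
    """A (typically circular) mitochondrial reference sequence."""

    id: str
    sequence: str
    circular: bool = True
    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("reference sequence must be non-empty")
        self.codes = encode(self.sequence)
        if (self.codes >= 4).any():
            raise ValueError("reference alphabet restricted to ACGT")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceRead:
    """A sequencing read with Phred+33 qualities."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: bases and quals lengths differ "
                f"({len(self.bases)} vs {len(self.quals)})"
            )

    def __len__(self) -> int:
        return len(self.bases)
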