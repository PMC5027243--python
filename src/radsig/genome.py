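"""Reference-genome access: in-memory sequences and FASTA-backed genomes.

Both flavours expose ``fetch(chrom, start, end)`` with 1-based closed
coordinates and a ``lengths`` mapping, which is all the analysis code needs.
"""

from __future__ import annotations

from typing import Mapping, Protocol

import numpy as np
import pyfaidx

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


class GenomeSequence(Protocol):
    @property
    def lengths(self) -> Mapping[str, int]: ...

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class InMemoryGenome:
    """A genome held as plain strings; used by the simulator and tests."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        self._arrays: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"span {chrom}:{start}-{end} outside reference (len {len(seq)})")
        return seq[start - 1 : end]

    def base_codes(self, chrom: str) -> np.ndarray:
        """Sequence as int8 codes A=0 C=1 G=2 T=3 (-1 for anything else), cached."""
        if chrom not in self._arrays:
            raw = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._arrays[chrom] = _BASE_CODE[raw]
        return self._arrays[chrom]


class FastaGenome:
    """A genome read from an (indexed) FASTA file via pyfaidx."""

    def __init__(self, path: str):
        self._fa = pyfaidx.Fasta(str(path))

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fa.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._fa.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > len(self._fa[chrom]) or start > end:
            raise IndexError(f"span {chrom}:{start}-{end} outside reference")
        return str(self._fa[chrom][start - 1 : end]).upper()

    def base_codes(self, chrom: str) -> np.ndarray:
        raw = np.frombuffer(
            str(self._fa[chrom][:]).upper().encode("ascii"), dtype=np.uint8
        )
        return _BASE_CODE[raw]


def write_fasta(genome: InMemoryGenome | Mapping[str, str], path: str, width: int = 60) -> None:
    seqs = genome._seqs if isinstance(genome, InMemoryGenome) else dict(genome)
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
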