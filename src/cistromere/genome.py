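"""In-memory genome sequences with FASTA I/O.

Sequences are stored as mutable ASCII ``bytearray`` objects so synthetic
generators can plant motif sites in place. Coordinates are 0-based
half-open everywhere.
"""
from __future__ import annotations

import os
from typing import Dict, Iterator, Mapping, Tuple

__all__ = ["Genome"]

_VALID = set(b"ACGTN")


class Genome:
    """A named collection of chromosome sequences."""

    def __init__(self, sequences: Mapping[str, str | bytes | bytearray]):
        self._seqs: Dict[str, bytearray] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if isinstance(seq, str):
                raw = bytearray(seq.upper().encode("ascii"))
            else:
                raw = bytearray(bytes(seq).upper())
            bad = set(raw) - _VALID
            if bad:
                raise ValueError(
                    f"invalid bases in {name!r}: {sorted(chr(b) for b in bad)}"
                )
            self._seqs[name] = raw

    # -- accessors ---------------------------------------------------------
    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def fetch(self, chrom: str, start: int, end: int, clip: bool = True) -> str:
        """Return the sequence of ``[start, end)`` on ``chrom``.

        With ``clip`` (default) the window is truncated at chromosome
        bounds; otherwise out-of-range coordinates raise.
        """
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._seqs[chrom]
        if clip:
            start, end = max(0, start), min(len(seq), end)
            if start >= end:
                return ""
        elif start < 0 or end > len(seq) or start >= end:
            raise ValueError(f"window [{start},{end}) outside {chrom}")
        return seq[start:end].decode("ascii")

    def set_sequence(self, chrom: str, start: int, seq: str) -> None:
        """Overwrite bases starting at ``start`` (in place)."""
        raw = seq.upper().encode("ascii")
        target = self._seqs[chrom]
        if start < 0 or start + len(raw) > len(target):
            raise ValueError("replacement runs off the chromosome")
        target[start:start + len(raw)] = raw

    # -- I/O ---------------------------------------------------------------
    def write_fasta(self, path: str | os.PathLike, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                text = seq.decode("ascii")
                for i in range(0, len(text), width):
                    fh.write(text[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        seqs: Dict[str, list] = {}
        order: list[Tuple[str, list]] = []
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    current = []
                    order.append((name, current))
                    seqs[name] = current
                else:
                    if current is None:
                        raise ValueError("FASTA sequence before first header")
                    current.append(line)
        return cls({name: "".join(parts) for name, parts in order})
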