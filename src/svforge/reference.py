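"""Uniform access to a reference genome (FASTA file or in-memory dict)."""

from __future__ import annotations

from typing import Mapping, Union

import pyfaidx

__all__ = ["Reference"]


class Reference:
    """Read-only genome: contig order, lengths, and subsequence fetch.

    Accepts a FASTA path (indexed lazily via pyfaidx) or a mapping of contig
    name to sequence string (used by tests and small fixtures). Fetched
    sequence is uppercased.
    """

    def __init__(self, source: Union[str, Mapping[str, str]]):
        if isinstance(source, (str, bytes)):
            self._fasta = pyfaidx.Fasta(str(source))
            self._seqs = None
            self.contigs = list(self._fasta.keys())
            self.lengths = {name: len(self._fasta[name]) for name in self.contigs}
        else:
            self._fasta = None
            self._seqs = {k: v.upper() for k, v in source.items()}
            self.contigs = list(self._seqs)
            self.lengths = {name: len(seq) for name, seq in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if not (0 <= start <= end <= self.lengths[chrom]):
            raise ValueError(
                f"fetch [{start},{end}) outside contig {chrom} "
                f"(length {self.lengths[chrom]})"
            )
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()

    def close(self) -> None:
        if self._fasta is not None:
            self._fasta.close()
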