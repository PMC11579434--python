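"""Per-locus alignment container and FASTA I/O.

Sequences are stored as uint8 matrices (rows = taxa) with the encoding
A=0, C=1, G=2, T=3, gap=4, ambiguity/other=5, which the site-pattern and
divergence code consumes directly.  FASTA reading goes through Biopython.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentFormatError

GAP = 4
AMBIG = 5
_DECODE = np.frombuffer(b"ACGT-N", dtype=np.uint8)

_ENCODE = np.full(256, AMBIG, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _ENCODE[base] = i
    _ENCODE[base + 32] = i  # lowercase
_ENCODE[ord("-")] = GAP
_ENCODE[ord("?")] = GAP


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(row: np.ndarray) -> str:
    return _DECODE[row].tobytes().decode("ascii")


class Alignment:
    """One locus: an ordered taxon list and a (n_taxa, length) uint8 matrix."""

    def __init__(self, taxa: Sequence[str], data: np.ndarray) -> None:
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2 or data.shape[0] != len(taxa):
            raise AlignmentFormatError("data must be (n_taxa, length)")
        if len(set(taxa)) != len(taxa):
            raise AlignmentFormatError("duplicate taxon labels in alignment")
        self.taxa: List[str] = list(taxa)
        self.data = data
        self._index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self._index[taxon]]

    def sequence(self, taxon: str) -> str:
        return decode(self.row(taxon))

    @classmethod
    def from_sequences(cls, seqs: Dict[str, str]) -> "Alignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError("ragged alignment: unequal sequence lengths")
        data = np.vstack([encode(seqs[t]) for t in taxa]) if taxa else np.zeros((0, 0), np.uint8)
        return cls(taxa, data)

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        seqs = {}
        for rec in SeqIO.parse(path, "fasta"):
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise AlignmentFormatError(f"no sequences in {path}")
        return cls.from_sequences(seqs)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{self.sequence(taxon)}\n")
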