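"""Protein alignment container with FASTA round-tripping."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import MISSING_CODE, decode, encode

__all__ = ["ProteinAlignment"]


class ProteinAlignment:
    """Aligned protein sequences over the 20 amino acids plus '-' and 'X'.

    Rows are equal-length strings; ids are unique.  The integer encoding
    (``codes``, shape n_sequences x length, missing = 20) is computed once
    and shared by the likelihood machinery.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]) -> None:
        ids = list(ids)
        rows = [str(r).upper() for r in rows]
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if not ids:
            raise ValueError("empty alignment")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        L = len(rows[0])
        for sid, row in zip(ids, rows):
            if len(row) != L:
                raise ValueError(
                    f"sequence {sid!r} has length {len(row)}, expected {L}"
                )
        self.ids = ids
        self.rows = rows
        self.codes = np.stack([encode(r) for r in rows])
        self._index = {sid: k for k, sid in enumerate(ids)}

    # ------------------------------------------------------------------ io
    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    # ------------------------------------------------------------- queries
    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    def row_codes(self, seq_id: str) -> np.ndarray:
        return self.codes[self._index[seq_id]]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def subset(self, ids: Iterable[str]) -> "ProteinAlignment":
        ids = list(ids)
        return ProteinAlignment(ids, [self.row(i) for i in ids])

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ProteinAlignment {self.n_sequences} x {self.length}>"

    @staticmethod
    def decode_codes(codes: np.ndarray, missing_char: str = "-") -> str:
        return decode(codes, missing_char)

    def column_has_gap(self) -> np.ndarray:
        """Boolean per column: any sequence gapped/unknown there."""
        return np.any(self.codes == MISSING_CODE, axis=0)
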