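"""Amino-acid alphabet shared by every module.

The state ordering follows the PAML ``.dat`` convention (A R N D C Q E G H
I L K M F P S T W Y V) so that bundled exchangeability files can be read
without reindexing.  ``-`` and ``X`` are the two missing-data characters.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
N_STATES: int = 20
GAP: str = "-"
UNKNOWN: str = "X"
MISSING_CODE: int = N_STATES  # integer code for '-' and 'X'

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_ENCODE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = _i
    _ENCODE[ord(_aa.lower())] = _i
_ENCODE[ord(GAP)] = MISSING_CODE
_ENCODE[ord(UNKNOWN)] = MISSING_CODE
_ENCODE[ord("x")] = MISSING_CODE


def encode(sequence: str) -> np.ndarray:
    """Encode a protein string into integer state codes (missing -> 20).

    Raises ``ValueError`` on characters outside the 20 amino acids, '-', 'X'.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if np.any(codes < 0):
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"illegal character {bad!r} in protein sequence")
    return codes.astype(np.int64)


def decode(codes: np.ndarray, missing_char: str = GAP) -> str:
    """Inverse of :func:`encode`; missing states render as *missing_char*."""
    return "".join(
        missing_char if c == MISSING_CODE else AMINO_ACIDS[c] for c in codes
    )
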