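"""The 20-letter amino-acid alphabet and sequence validation helpers.

All matrices in this package (PWMs, substitution matrices, logo heights)
use the fixed alphabetical residue order :data:`AA20`.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order for every 20-wide axis in this package.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residue -> column index in :data:`AA20`.
AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: Ambiguity codes tolerated during scanning (scored as zero contribution).
AMBIGUOUS = set("XBZJUO*")

# byte -> index lookup; unknown residues map to sentinel 20
_LUT = np.full(256, 20, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _LUT[ord(_a)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a protein sequence as int indices into :data:`AA20`.

    Unknown/ambiguous residues become the sentinel value 20.
    """
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def validate_sequence(seq: str, *, allow_ambiguous: bool = False) -> str:
    """Return ``seq`` uppercased, raising ``ValueError`` on bad residues."""
    s = seq.upper()
    allowed = set(AA20) | (AMBIGUOUS if allow_ambiguous else set())
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)!r}")
    return s
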