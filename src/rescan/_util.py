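"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 lookup: ASCII code -> base index (4 = unknown/N)
ASCII_TO_INDEX = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    ASCII_TO_INDEX[ord(_b)] = _i
    ASCII_TO_INDEX[ord(_b.lower())] = _i

COMPLEMENT_INDEX = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_sites(seq: str, site: str) -> list[int]:
    """All start positions of `site` in `seq`, overlapping occurrences included."""
    hits = []
    pos = seq.find(site)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(site, pos + 1)
    return hits


def phred_char(q: int) -> str:
    return chr(min(int(q), 41) + 33)


def error_rate_to_q(error_rate: float) -> int:
    """Uniform per-base quality implied by a substitution rate, capped at Q41."""
    if error_rate <= 0:
        return 41
    return min(41, int(round(-10.0 * np.log10(error_rate))))


def seq_to_indices(seq: str) -> np.ndarray:
    return ASCII_TO_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
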