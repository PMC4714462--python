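"""Small shared helpers: sequence alphabet ops and interval arithmetic."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """I.i.d. DNA of the given length and GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA))[rng.choice(4, size=length, p=p)])


def interval_len(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0] + 1


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def check_interval(iv: tuple[int, int], length: int, what: str = "interval") -> None:
    s, e = iv
    if not (1 <= s <= e <= length):
        raise ValueError(f"{what} ({s}, {e}) outside [1, {length}]")


def slice1(seq: str, iv: tuple[int, int]) -> str:
    """Extract a 1-based inclusive interval from a string."""
    return seq[iv[0] - 1 : iv[1]]
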