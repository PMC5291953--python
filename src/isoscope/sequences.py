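"""Sequence-level primitives: adapters, barcodes, Hamming scans, homopolymers.

The STRT/PacBio read grammar places a 16 bp sample barcode and the Illumina
adapter at each end of every pre-circularization molecule; matching is
substitution-only (Hamming) because circular-consensus reads are dominated by
substitution errors, which keeps the mismatch threshold well-defined.
"""
from __future__ import annotations

import re

import numpy as np

from .types import AdapterMatch

ILLUMINA_ADAPTER = "AATGATACGGCGACCACCGAT"

# Fixed 16 bp sample barcode panel. Pairwise Hamming distance >= 5, distance
# >= 5 to every 16-window of the Illumina adapter (both orientations) and to
# every barcode's reverse complement, so 2-mismatch matching is unambiguous.
BARCODES: dict[str, str] = {
    "bc1": "GTAGCGTCCACAAGCG",
    "bc2": "GTTGGGTTAACGGCGT",
    "bc3": "GTTACAGGGATTGCAT",
    "bc4": "TTACTAATCCTACCGT",
    "bc5": "TGCGTCGAATGAGAGC",
    "bc6": "ACACTGGGCATAATAG",
    "bc7": "CAACTTGCGGTGGTCA",
    "bc8": "ATCTGAGCTCTTCACG",
}

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def scan_pattern(seq: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where pattern matches seq with <= max_mm
    substitutions. Vectorized sliding-window Hamming scan."""
    m = len(pattern)
    if m == 0 or len(seq) < m:
        return []
    arr = _seq_to_array(seq)
    pat = _seq_to_array(pattern)
    win = np.lib.stride_tricks.sliding_window_view(arr, m)
    mism = (win != pat).sum(axis=1)
    pos = np.nonzero(mism <= max_mm)[0]
    return [(int(p), int(mism[p])) for p in pos]


def find_adapters(
    seq: str,
    adapters: dict[str, str],
    max_mm: int = 2,
) -> list[AdapterMatch]:
    """Locate every adapter (and its reverse complement) in seq.

    Overlapping hits of the same adapter/orientation are resolved by keeping
    the lower-mismatch hit (ties: leftmost). Output sorted by position.
    """
    if not adapters:
        raise ValueError("adapter set must be non-empty")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    out: list[AdapterMatch] = []
    for name, aseq in adapters.items():
        for which, pattern in ((name, aseq), (name + "_rc", revcomp(aseq))):
            hits = scan_pattern(seq, pattern, max_mm)
            # suppress overlapping self-matches: best (mm, position) first
            hits.sort(key=lambda h: (h[1], h[0]))
            taken: list[tuple[int, int]] = []
            m = len(pattern)
            for p, mm in hits:
                if all(p + m <= q or r + m <= p for q, r in taken):
                    taken.append((p, p))
                    out.append(AdapterMatch(p, which, m, mm))
    out.sort(key=lambda a: (a.position, a.which))
    return out


def homopolymer_runs(seq: str, base: str, min_len: int) -> list[tuple[int, int]]:
    """Half-open intervals of runs of `base` with length >= min_len."""
    return [
        (m.start(), m.end())
        for m in re.finditer(f"{base}{{{min_len},}}", seq)
    ]


def has_homopolymer(seq: str, base: str, min_len: int) -> bool:
    return base * min_len in seq
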