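"""Low-level sequence helpers shared across the package.

Coordinates are 0-based half-open throughout the library; conversion to and
from the 1-based VCF convention is centralized in :mod:`top1tam.io`.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(unit: str) -> bool:
    """True if ``unit`` is not itself a whole-number repeat of a shorter unit.

    "CT" is primitive; "CTCT" (period 2) and "AA" (period 1) are not.
    """
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def equivalent_deletion_range(seq: str, pos: int, length: int) -> tuple[int, int]:
    """Range of start positions producing an identical post-deletion sequence.

    Deleting ``seq[p:p+length]`` yields the same string for every ``p`` in the
    contiguous range ``[left, right]`` returned here; ``left`` is the
    left-aligned (VCF-normalized) register and ``right`` the right-aligned one.
    """
    left = pos
    while left > 0 and seq[left - 1] == seq[left + length - 1]:
        left -= 1
    right = pos
    while right + length < len(seq) and seq[right] == seq[right + length]:
        right += 1
    return left, right


def homopolymer_run_length(seq: str, start: int) -> int:
    """Length of the maximal homopolymer run beginning at ``start``."""
    base = seq[start]
    end = start + 1
    while end < len(seq) and seq[end] == base:
        end += 1
    return end - start


def max_homopolymer_run(seq: str) -> int:
    best = 0
    i = 0
    n = len(seq)
    while i < n:
        run = homopolymer_run_length(seq, i)
        if seq[i] in DNA and run > best:
            best = run
        i += run
    return best
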