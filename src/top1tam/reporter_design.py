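"""In silico reporter redesign: synonymous recoding to maximize dinucleotide
tandem repeats, then removal of +2-frame stop codons.

A 5-codon window slides one codon at a time over the coding sequence; within
each window every synonymous codon combination is enumerated and ranked by
(longest tandem dinucleotide run in bp, total dinucleotide-repeat bp, longest
mononucleotide run), higher better, final ties broken lexicographically.  A
strictly better permutation replaces whole codons, which are then censored
from later windows.  A second pass removes TAA/TAG/TGA triplets from the +2
reading frame (the frame exposed by a 2 bp deletion) by further synonymous
substitutions chosen to preserve repeat content, reporting positions where no
synonymous fix exists.  Protein identity under the standard nuclear code is
preserved by construction throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .sequence import DNA, max_homopolymer_run

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_SYNONYMS: dict[str, tuple[str, ...]] = {}
_aa_to_codons: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _aa_to_codons.setdefault(_aa, []).append(_codon)
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYNONYMS[_codon] = tuple(sorted(_aa_to_codons[_aa]))
for _stop in STOP_CODONS:
    _SYNONYMS[_stop] = (_stop,)  # terminal stop is never recoded


@dataclass
class RedesignResult:
    input_cds: str
    output_cds: str
    edited_codon_indices: set[int]
    sstr_fraction: float
    frameshift_stop_free: bool
    unresolved_stop_positions: list[int] = field(default_factory=list)


def _validate_cds(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not set(cds) <= DNA:
        raise ValueError("CDS contains ambiguous bases")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        raise ValueError("CDS has an internal stop codon")
    return codons


def _dinucleotide_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal tandem runs of primitive 2 bp units with >= 2 full copies."""
    runs = []
    n = len(seq)
    j = 0
    while j + 2 < n:
        if seq[j] == seq[j + 2]:
            a = j
            while j + 2 < n and seq[j] == seq[j + 2]:
                j += 1
            copies = (j - a + 2) // 2
            if copies >= 2 and seq[a] != seq[a + 1]:
                runs.append((a, a + copies * 2))
        else:
            j += 1
    return runs


def _union_bp(runs: list[tuple[int, int]]) -> int:
    total = 0
    prev_end = -1
    for s, e in sorted(runs):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
    return total


def dinucleotide_repeat_key(seq: str) -> tuple[int, int, int]:
    """(longest dinucleotide run bp, total dinucleotide-repeat bp, longest
    mononucleotide run) — the window ranking key, higher better."""
    runs = _dinucleotide_runs(seq)
    longest = max((e - s for s, e in runs), default=0)
    return (longest, _union_bp(runs), max_homopolymer_run(seq))


def repeat_content(cds: str) -> float:
    """Fraction of bases inside maximal 2 bp tandem repeats (>= 2 copies)."""
    if not cds:
        return 0.0
    return _union_bp(_dinucleotide_runs(cds)) / len(cds)


def maximize_dinucleotide_repeats(
    cds: str, window_codons: int = 5
) -> RedesignResult:
    """Greedy left-to-right synonymous recoding maximizing the window key."""
    codons = _validate_cds(cds)
    censored: set[int] = set()
    edited: set[int] = set()
    n = len(codons)
    for start in range(0, max(1, n - window_codons + 1)):
        idx = list(range(start, min(start + window_codons, n)))
        options = [
            (codons[i],) if i in censored else _SYNONYMS[codons[i]] for i in idx
        ]
        if all(len(o) == 1 for o in options):
            continue
        current = tuple(codons[i] for i in idx)
        cur_full = dinucleotide_repeat_key("".join(current))
        cur_di = cur_full[:2]
        best_combo = current
        best_key = (cur_full, _neg_lex(current))
        for combo in itertools.product(*options):
            full = dinucleotide_repeat_key("".join(combo))
            if full[:2] <= cur_di:
                continue  # mononucleotide runs alone never justify an edit
            key = (full, _neg_lex(combo))
            if key > best_key:
                best_key, best_combo = key, combo
        if best_combo != current:
            for i, codon in zip(idx, best_combo):
                if codons[i] != codon:
                    codons[i] = codon
                    edited.add(i)
                    censored.add(i)
    out = "".join(codons)
    assert str(Seq(out).translate()) == str(Seq(cds).translate())
    return RedesignResult(
        input_cds=cds,
        output_cds=out,
        edited_codon_indices=edited,
        sstr_fraction=repeat_content(out),
        frameshift_stop_free=not _frame_stops(out, 2),
    )


class _neg_lex(str):
    """Wrapper giving lexicographically *smaller* strings higher rank."""

    def __new__(cls, codons: tuple[str, ...]):
        return super().__new__(cls, "".join(codons))

    def __lt__(self, other) -> bool:  # reversed ordering
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:
        return str.__lt__(self, other)


def _frame_stops(cds: str, frame: int) -> list[int]:
    """Start offsets of stop triplets in the shifted reading frame."""
    return [
        t
        for t in range(frame, len(cds) - 2, 3)
        if cds[t : t + 3] in STOP_CODONS
    ]


def purge_frameshift_stops(cds: str, frames: tuple[int, ...] = (2,)) -> RedesignResult:
    """Synonymously remove stop codons from shifted reading frames.

    Each shifted-frame stop triplet overlaps two in-frame codons; all
    synonymous substitutions of that codon pair are tried and, among those
    that remove the stop, the one best preserving dinucleotide-repeat content
    is applied.  Positions with no synonymous fix are reported, not fatal.
    """
    codons = _validate_cds(cds)
    edited: set[int] = set()
    unresolved: list[int] = []
    for _ in range(10):  # fixes can expose new stops; iterate to a fixpoint
        out = "".join(codons)
        stops = [t for f in frames for t in _frame_stops(out, f)]
        stops = [t for t in stops if t not in unresolved]
        if not stops:
            break
        changed = False
        for t in stops:
            if "".join(codons)[t : t + 3] not in STOP_CODONS:
                continue  # already removed by an earlier fix this sweep
            i = t // 3
            j = min((t + 2) // 3, len(codons) - 1)
            pair = sorted({i, j})
            options = [_SYNONYMS[codons[k]] for k in pair]
            best = None
            for combo in itertools.product(*options):
                trial = codons.copy()
                for k, c in zip(pair, combo):
                    trial[k] = c
                trial_seq = "".join(trial)
                if trial_seq[t : t + 3] in STOP_CODONS:
                    continue
                local = trial_seq[max(0, t - 12) : t + 15]
                key = (dinucleotide_repeat_key(local), _neg_lex(combo))
                if best is None or key > best[0]:
                    best = (key, combo)
            if best is None:
                unresolved.append(t)
                continue
            for k, c in zip(pair, best[1]):
                if codons[k] != c:
                    codons[k] = c
                    edited.add(k)
                    changed = True
        if not changed:
            break
    out = "".join(codons)
    assert str(Seq(out).translate()) == str(Seq(cds).translate())
    remaining = [t for f in frames for t in _frame_stops(out, f)]
    return RedesignResult(
        input_cds=cds,
        output_cds=out,
        edited_codon_indices=edited,
        sstr_fraction=repeat_content(out),
        frameshift_stop_free=not remaining,
        unresolved_stop_positions=sorted(set(remaining)),
    )
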