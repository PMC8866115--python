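"""Repeat, microhomology and TNT-motif annotation of genome sequences.

The central objects are short tandem repeats (STRs: ``(unit)_n`` with ``n >= 2``
copies of a primitive unit of 1-5 bp) and single-base microhomology (MH) sites
(``B . N^(d-1) . B``: a base matched ``d`` positions downstream, supporting a
d-bp deletion with 1 bp of flanking homology).  A d-bp deletion is
TNT-compliant when thymidines bracket the deleted bases: the motif
``T . N^(d-1) . T``, the substrate for sequential TOP1 cleavage and strand
realignment at genome-embedded ribonucleotides.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .sequence import DNA, is_primitive

UNIT_LENGTHS = frozenset({1, 2, 3, 4, 5})


@dataclass(frozen=True)
class RepeatRegion:
    """An STR run or an MH anchor-pair interval.

    For STRs ``span`` covers ``copies`` full units (length ``r * copies``).
    For MH sites ``span`` covers the motif ``B N^(r-1) B`` (length ``r + 1``)
    and ``copies`` is None.
    """

    sequence_name: str
    start: int
    end: int
    kind: str  # "STR" | "MH"
    unit_length: int
    unit_sequence: str
    copies: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("STR", "MH"):
            raise ValueError(f"kind must be STR or MH, got {self.kind!r}")
        if self.kind == "STR":
            if self.copies is None or self.copies < 2:
                raise ValueError("STR requires copies >= 2")
            if self.end - self.start != self.unit_length * self.copies:
                raise ValueError("STR span must equal unit_length * copies")
        else:
            if self.end - self.start != self.unit_length + 1:
                raise ValueError("MH span must equal unit_length + 1")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TntMotifSpec:
    """The TNT motif for a d-bp deletion: T, d-1 arbitrary bases, T."""

    deletion_length: int

    def __post_init__(self) -> None:
        if not 2 <= self.deletion_length <= 5:
            raise ValueError("deletion length must be in 2..5")

    @property
    def motif_length(self) -> int:
        return self.deletion_length + 1

    def matches(self, window: str) -> bool:
        return (
            len(window) == self.motif_length
            and window[0] == "T"
            and window[-1] == "T"
            and all(b in DNA for b in window)
        )


@dataclass
class MappabilityMask:
    """Sorted, non-overlapping half-open mappable intervals per sequence."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ivs in self.intervals.items():
            prev_end = -1
            for s, e in ivs:
                if s < 0 or e <= s:
                    raise ValueError(f"bad interval ({s},{e}) on {name}")
                if s < prev_end:
                    raise ValueError(f"intervals overlap/unsorted on {name}")
                prev_end = e

    @classmethod
    def full(cls, sequences: dict[str, str]) -> "MappabilityMask":
        return cls({name: [(0, len(seq))] for name, seq in sequences.items()})

    @property
    def total_mappable_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def contains(self, name: str, start: int, end: int) -> bool:
        for s, e in self.intervals.get(name, []):
            if s <= start and end <= e:
                return True
        return False

    def sample_positions(
        self, length: int, n: int, rng: np.random.Generator
    ) -> list[tuple[str, int]]:
        """Draw ``n`` uniform start positions of ``length``-bp windows fully
        inside the mask."""
        slots: list[tuple[str, int, int]] = []  # (name, iv_start, n_starts)
        for name, ivs in self.intervals.items():
            for s, e in ivs:
                n_starts = (e - s) - length + 1
                if n_starts > 0:
                    slots.append((name, s, n_starts))
        if not slots:
            raise ValueError(f"no mappable window of length {length}")
        weights = np.array([c for _, _, c in slots], dtype=float)
        choice = rng.choice(len(slots), size=n, p=weights / weights.sum())
        offsets = rng.integers(0, weights[choice].astype(int))
        return [
            (slots[i][0], slots[i][1] + int(off)) for i, off in zip(choice, offsets)
        ]


def find_tandem_repeats(
    sequence: str,
    sequence_name: str = "seq",
    unit_lengths: frozenset[int] | set[int] = UNIT_LENGTHS,
    min_copies: int = 2,
) -> list[RepeatRegion]:
    """Maximal tandem-repeat runs with primitive units.

    A run is reported once, at its primitive unit length (``CTCTCT`` appears as
    r=2, n=3, never as r=4); partial trailing copies are trimmed so the span is
    exactly ``r * n``.  Any non-ACGT base breaks a run.
    """
    bad = frozenset(u for u in unit_lengths if u not in UNIT_LENGTHS)
    if bad:
        raise ValueError(f"unsupported unit lengths: {sorted(bad)}")
    regions: list[RepeatRegion] = []
    n = len(sequence)
    for r in sorted(unit_lengths):
        j = 0
        while j + r < n:
            if sequence[j] in DNA and sequence[j] == sequence[j + r]:
                a = j
                while j + r < n and sequence[j] in DNA and sequence[j] == sequence[j + r]:
                    j += 1
                # matches at a..j-1 -> repeated region [a, j+r)
                copies = (j - a + r) // r
                unit = sequence[a : a + r]
                if copies >= min_copies and is_primitive(unit) and set(unit) <= DNA:
                    regions.append(
                        RepeatRegion(
                            sequence_name=sequence_name,
                            start=a,
                            end=a + copies * r,
                            kind="STR",
                            unit_length=r,
                            unit_sequence=unit,
                            copies=copies,
                        )
                    )
            else:
                j += 1
    regions.sort(key=lambda reg: (reg.start, reg.unit_length))
    return regions


def find_mh_sites(
    sequence: str, d: int, sequence_name: str = "seq"
) -> list[RepeatRegion]:
    """Single-base microhomology anchor pairs for d-bp deletions.

    Reports every position ``i`` with ``sequence[i] == sequence[i+d]`` (motif
    ``B N^(d-1) B``), excluding positions whose supported deletion lies in a
    tandem array of >= 2 unit copies (those are STR context; STR precedence).
    """
    if not 2 <= d <= 5:
        raise ValueError("d must be in 2..5")
    sites: list[RepeatRegion] = []
    n = len(sequence)
    for i in range(n - d):
        window = sequence[i : i + d + 1]
        if sequence[i] != sequence[i + d] or not set(window) <= DNA:
            continue
        # the anchors support deleting sequence[i:i+d]; left-align that
        # deletion and test whether its unit tandemly repeats (STR context)
        left = i
        while left > 0 and sequence[left - 1] == sequence[left + d - 1]:
            left -= 1
        unit = sequence[left : left + d]
        if sequence[left : left + 2 * d] == unit * 2:
            continue  # subsumed by a tandem repeat of the deleted unit
        sites.append(
            RepeatRegion(
                sequence_name=sequence_name,
                start=i,
                end=i + d + 1,
                kind="MH",
                unit_length=d,
                unit_sequence=window,
            )
        )
    return sites


def region_contains_tnt(sequence: str, region: RepeatRegion, d: int) -> bool:
    """True if the region's span contains the motif ``T N^(d-1) T``."""
    s, e = region.span
    for j in range(s, e - d):
        if sequence[j] == "T" and sequence[j + d] == "T":
            return True
    return False


def tnt_background_fraction(
    sequences: dict[str, str],
    mask: MappabilityMask,
    d: int,
    context: str = "all",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Background fraction of d-bp deletion sites that are TNT-compliant.

    ``context="all"``: Monte-Carlo fraction over ``n_samples`` uniformly placed
    deletions in the mappable genome (with a binomial 95% CI).
    ``context="STR"``/``"MH"``: the deterministic fraction of annotated STR/MH
    sequence that contains the ``T N^(d-1) T`` motif (CI degenerate).
    """
    from .indel_classify import deletion_is_tnt_compliant  # cycle guard

    if not 2 <= d <= 5:
        raise ValueError("d must be in 2..5")
    if mask.total_mappable_bp < 1000:
        raise ValueError("mappable genome under 1 kb; fraction would be unstable")
    if context == "all":
        rng = np.random.default_rng(seed)
        positions = mask.sample_positions(d, n_samples, rng)
        hits = sum(
            deletion_is_tnt_compliant(sequences[name], pos, d)
            for name, pos in positions
        )
        frac = hits / n_samples
        lo, hi = proportion_confint(hits, n_samples, alpha=0.05, method="wilson")
        return frac, (float(lo), float(hi))
    if context in ("STR", "MH"):
        total_bp = 0
        motif_bp = 0
        for name, seq in sequences.items():
            if context == "STR":
                regions = find_tandem_repeats(seq, name)
            else:
                regions = find_mh_sites(seq, d, name)
            for reg in regions:
                if not mask.contains(name, reg.start, reg.end):
                    continue
                width = reg.end - reg.start
                total_bp += width
                if region_contains_tnt(seq, reg, d):
                    motif_bp += width
        if total_bp == 0:
            return 0.0, (0.0, 0.0)
        frac = motif_bp / total_bp
        return frac, (frac, frac)
    raise ValueError(f"unknown context {context!r}")


DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


def context_relative_rates(
    site_positions: list[tuple[str, int, str]],
    sequences: dict[str, str],
) -> dict[str, float]:
    """Composition-adjusted relative rates of dinucleotide site contexts.

    The context of a site is the reported base plus its 5' neighbour, resolved
    to the given strand.  rate(c) = (sites in c / genome occurrences of c),
    normalized to sum to 1, so that unbiased sites give every context a rate
    close to 1/n.  Genome occurrences are counted on both strands.
    """
    from .sequence import revcomp

    genome_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for seq in sequences.values():
        for i in range(len(seq) - 1):
            di = seq[i : i + 2]
            if set(di) <= DNA:
                genome_counts[di] += 1
                genome_counts[revcomp(di)] += 1

    site_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for name, pos, strand in site_positions:
        seq = sequences[name]
        if strand == "+":
            if pos < 1:
                raise ValueError(f"site at {name}:{pos} lacks a 5' neighbour")
            di = seq[pos - 1 : pos + 1]
        else:
            if pos + 2 > len(seq):
                raise ValueError(f"site at {name}:{pos} lacks a 5' neighbour (-)")
            di = revcomp(seq[pos : pos + 2])
        if set(di) <= DNA:
            site_counts[di] += 1

    raw: dict[str, float] = {}
    for di in DINUCLEOTIDES:
        if site_counts[di] and not genome_counts[di]:
            raise ValueError(f"context {di} absent from genome but observed")
        raw[di] = site_counts[di] / genome_counts[di] if genome_counts[di] else 0.0
    total = sum(raw.values())
    if total == 0:
        raise ValueError("no classifiable sites")
    return {di: v / total for di, v in raw.items()}
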