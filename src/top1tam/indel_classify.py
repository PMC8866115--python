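"""Indel normalization, deletion context classification and ID-83 spectra.

Deletions are classified by repeat context (STR when the deleted unit is part
of a tandem array of >= 2 copies; single-base microhomology, MH/SNMH, when the
deleted sequence shares flanking homology without a full extra copy; otherwise
"other") and scored for TNT compliance: for a d-bp deletion, thymidines
bracketing the deleted bases as ``T . N^(d-1) . T`` at some equivalent
placement of the deletion.  Because a deletion inside repetitive sequence has
many equivalent representations, all placement registers between the left- and
right-aligned forms are considered.

2 bp deletions additionally receive one of six canonical dinucleotide classes
that group strand-complementary deleted pairs (the CT class contains CT, TC,
GA and AG; AT and TA are their own reverse complements and remain distinct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import DNA, equivalent_deletion_range

# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class IndelCall:
    """A deletion or insertion in internal coordinates.

    ``position`` is the 0-based start of the deleted bases (deletion) or the
    0-based index of the reference base *before* which bases are inserted
    (insertion).  ``ref_allele`` holds the deleted bases (empty for an
    insertion); ``alt_allele`` the inserted bases (empty for a deletion).
    Anchor-base VCF conversion lives in :mod:`top1tam.io`.
    """

    sequence_name: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele and self.alt_allele:
            raise ValueError("call is not parsimonious: both alleles non-empty")
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("empty indel")
        if self.position < 0:
            raise ValueError("negative position")

    @property
    def type(self) -> str:
        return "deletion" if self.ref_allele else "insertion"

    @property
    def length(self) -> int:
        return len(self.ref_allele) or len(self.alt_allele)


@dataclass(frozen=True)
class ClassifiedDeletion:
    call: IndelCall
    context: str  # "STR" | "MH" | "other"
    repeat_copies: int  # tandem copies of the deleted unit incl. the deleted one
    mh_length: int  # bp of flanking homology (0 if none)
    canonical_class: str | None  # six-class label, 2 bp deletions only
    tnt_compliant: bool
    right_aligned_start: int
    ambiguous_register: bool = False
    warning: str | None = None


@dataclass
class SpectrumVector:
    """Ordered indel-category counts under a fixed labelling scheme."""

    labels: tuple[str, ...]
    counts: np.ndarray
    scheme: str = "ID-83"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.labels),):
            raise ValueError("counts length must match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.counts.tolist()))


# --------------------------------------------------------------------------
# ID-83 scheme (COSMIC layout: type x length x repeat/microhomology context)


def _id83_labels() -> tuple[str, ...]:
    labels: list[str] = []
    for base in "CT":
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for d in range(2, 6):
        labels += [f"{d}:Del:R:{i}" for i in range(6)]
    for d in range(2, 6):
        labels += [f"{d}:Ins:R:{i}" for i in range(6)]
    for d, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        labels += [f"{d}:Del:M:{i}" for i in range(1, max_mh + 1)]
    return tuple(labels)


ID83_LABELS: tuple[str, ...] = _id83_labels()
assert len(ID83_LABELS) == 83

#: Indel categories whose net length change shifts the downstream reading
#: frame by +2 (deletions of 3k+2 bp, insertions of 3k+1 bp) — the mutations a
#: +2-frameshift reporter selects for.
FRAMESHIFT_PLUS2_LABELS: tuple[str, ...] = tuple(
    lab
    for lab in ID83_LABELS
    if (lab.split(":")[1] == "Del" and int(lab[0]) % 3 == 2)
    or (lab.split(":")[1] == "Ins" and int(lab[0]) % 3 == 1)
)

_CANONICAL_CLASSES: dict[str, str] = {}
for _cls, _members in (
    ("AT", ("AT",)),
    ("TA", ("TA",)),
    ("CC", ("CC", "GG")),
    ("CG", ("CG", "GC")),
    ("CT", ("CT", "TC", "AG", "GA")),
    ("AC", ("AC", "CA", "GT", "TG")),
):
    for _m in _members:
        _CANONICAL_CLASSES[_m] = _cls

CANONICAL_CLASS_LABELS = ("AT", "TA", "CC", "CG", "CT", "AC")


def canonical_dinucleotide_class(dinucleotide: str) -> str:
    """Map a deleted dinucleotide onto one of six strand-collapsed classes.

    The classes partition the 14 dinucleotides with two distinct bases; AA and
    TT deletions occur within homopolymer runs rather than dinucleotide
    repeats and lie outside the six-class scheme (ValueError).
    """
    di = dinucleotide.upper()
    if len(di) != 2 or not set(di) <= DNA:
        raise ValueError(f"not a dinucleotide over ACGT: {dinucleotide!r}")
    if di in ("AA", "TT"):
        raise ValueError(
            "AA/TT deletions are homopolymer events outside the six classes"
        )
    return _CANONICAL_CLASSES[di]


# --------------------------------------------------------------------------
# normalization


def normalize_indel(call: IndelCall, sequences: dict[str, str]) -> IndelCall:
    """Parsimonious, left-aligned representation of an indel (idempotent)."""
    seq = sequences[call.sequence_name]
    ref, alt, pos = call.ref_allele, call.alt_allele, call.position
    # trim shared suffix then shared prefix (handles non-minimal inputs)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref and alt:
        raise ValueError("call is not a pure indel after trimming")
    if not ref and not alt:
        raise ValueError("call is a no-op")
    if ref:  # deletion
        if seq[pos : pos + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at {call.sequence_name}:{pos}: "
                f"expected {ref}, genome has {seq[pos:pos + len(ref)]}"
            )
        left, _ = equivalent_deletion_range(seq, pos, len(ref))
        return IndelCall(call.sequence_name, left, seq[left : left + len(ref)], "")
    # insertion: shift left while the last inserted base equals the base 5'
    ins = alt
    while pos > 0 and seq[pos - 1] == ins[-1]:
        ins = seq[pos - 1] + ins[:-1]
        pos -= 1
    return IndelCall(call.sequence_name, pos, "", ins)


# --------------------------------------------------------------------------
# TNT scoring and classification


def _count_forward_copies(seq: str, start: int, unit: str) -> int:
    d = len(unit)
    k = 0
    while seq[start + k * d : start + (k + 1) * d] == unit:
        k += 1
    return k


def _mh_lengths(seq: str, right_pos: int, d: int) -> tuple[int, int]:
    """(5'-anchored, 3'-anchored) flanking homology of the deleted sequence
    at its right-aligned register."""
    unit = seq[right_pos : right_pos + d]
    five = 0
    while (
        five < d
        and right_pos - five - 1 >= 0
        and seq[right_pos - five - 1] == unit[d - five - 1]
    ):
        five += 1
    three = 0
    while (
        three < d
        and right_pos + d + three < len(seq)
        and seq[right_pos + d + three] == unit[three]
    ):
        three += 1
    return five, three


def _tnt_compliant(
    seq: str, pos: int, d: int, context: str, left: int, right: int, copies: int
) -> bool:
    """Strand-collapsed TNT compliance given precomputed registers/context.

    d=2 (and deletions outside repeats for any d): some register places the
    deleted bases as N^(d-1),T with T immediately 5' — or, reading the
    complementary strand, A as the first deleted base with A immediately 3'.
    d=3..5 at STR: the maximal repeat run contains T N^(d-1) T on either
    strand; at MH: some register's anchor pair reads T...T on either strand.
    A deletion is a duplex event, so both strand presentations are scored
    (the complementary-strand condition is written mirrored on the forward
    string: T,T spaced d becomes A,A spaced d).
    """
    if not 2 <= d <= 5:
        return False
    n = len(seq)
    if d == 2 or context == "other":
        for p in range(left, right + 1):
            if p >= 1 and seq[p - 1] == "T" and seq[p + d - 1] == "T":
                return True
            if p + d < n and seq[p] == "A" and seq[p + d] == "A":
                return True
        return False
    if context == "STR":
        # full maximal run of the repeat's primitive unit around the deletion
        unit = seq[left : left + d]
        rp = next(
            p for p in range(1, d + 1) if d % p == 0 and unit == unit[:p] * (d // p)
        )
        start, end = left, left + copies * d
        while start - 1 >= 0 and seq[start - 1] == seq[start - 1 + rp]:
            start -= 1
        while end < n and seq[end] == seq[end - rp]:
            end += 1
        return any(
            seq[j] == seq[j + d] and seq[j] in "AT" for j in range(start, end - d)
        )
    # MH: anchor pair of some register is T...T (or A...A on the other strand)
    for p in range(left, right + 1):
        if p >= 1 and seq[p - 1] == seq[p + d - 1] and seq[p - 1] in "AT":
            return True
        if p + d < n and seq[p] == seq[p + d] and seq[p] in "AT":
            return True
    return False


def _logo_register(seq: str, left: int, right: int, d: int) -> int:
    """Right-alignment register for logos: the most 3' placement whose deleted
    window reaches the most 3' T of the ambiguity range, else the range limit."""
    if d == 2:
        for p in range(right, left - 1, -1):
            if seq[p + 1] == "T":
                return p
        for p in range(right, left - 1, -1):
            if seq[p] == "T":
                return p
    return right


def classify_deletion(
    call: IndelCall, sequences: dict[str, str]
) -> ClassifiedDeletion:
    """Classify a normalized deletion by repeat context, homology and TNT."""
    if call.type != "deletion":
        raise ValueError("classify_deletion requires a deletion")
    seq = sequences[call.sequence_name]
    pos, d = call.position, call.length
    if seq[pos : pos + d] != call.ref_allele:
        raise ValueError(f"reference mismatch at {call.sequence_name}:{pos}")

    if not set(seq[max(0, pos - 1) : pos + d + 1]) <= DNA:
        return ClassifiedDeletion(
            call=call,
            context="other",
            repeat_copies=1,
            mh_length=0,
            canonical_class=None,
            tnt_compliant=False,
            right_aligned_start=pos,
            warning="deletion overlaps non-ACGT sequence",
        )

    left, right = equivalent_deletion_range(seq, pos, d)
    unit = seq[left : left + d]
    copies = _count_forward_copies(seq, left, unit)
    five, three = _mh_lengths(seq, right, d)
    mh = max(five, three)
    if copies >= 2:
        context = "STR"
    elif mh >= 1:
        context = "MH"
    else:
        context = "other"

    tnt = _tnt_compliant(seq, pos, d, context, left, right, copies)
    logo_start = _logo_register(seq, left, right, d)
    canonical = None
    if d == 2:
        di = seq[logo_start : logo_start + 2]
        if di not in ("AA", "TT"):  # homopolymer pairs have no class
            canonical = canonical_dinucleotide_class(di)
    return ClassifiedDeletion(
        call=call,
        context=context,
        repeat_copies=copies,
        mh_length=mh,
        canonical_class=canonical,
        tnt_compliant=tnt,
        right_aligned_start=logo_start,
        ambiguous_register=right > left,
    )


def score_tnt(classified: ClassifiedDeletion, sequences: dict[str, str]) -> bool:
    """TNT compliance of a classified deletion (recomputed from sequence)."""
    call = classified.call
    seq = sequences[call.sequence_name]
    left, right = equivalent_deletion_range(seq, call.position, call.length)
    unit = seq[left : left + call.length]
    copies = _count_forward_copies(seq, left, unit)
    return _tnt_compliant(
        seq, call.position, call.length, classified.context, left, right, copies
    )


def deletion_is_tnt_compliant(seq: str, pos: int, d: int) -> bool:
    """TNT compliance of the deletion of ``seq[pos:pos+d]`` (classifies
    context internally); convenience entry point for samplers."""
    if not set(seq[max(0, pos - 1) : pos + d + 1]) <= DNA:
        return False
    left, right = equivalent_deletion_range(seq, pos, d)
    unit = seq[left : left + d]
    copies = _count_forward_copies(seq, left, unit)
    if copies >= 2:
        context = "STR"
    else:
        five, three = _mh_lengths(seq, right, d)
        context = "MH" if max(five, three) >= 1 else "other"
    return _tnt_compliant(seq, pos, d, context, left, right, copies)


# --------------------------------------------------------------------------
# spectra


def _deletion_id83_label(c: ClassifiedDeletion) -> str:
    d = c.call.length
    if d == 1:
        base = c.call.ref_allele
        base = {"A": "T", "G": "C"}.get(base, base)
        if base not in "CT":  # N or malformed
            base = "T"
        return f"1:Del:{base}:{min(c.repeat_copies - 1, 5)}"
    dd = min(d, 5)
    if c.repeat_copies >= 2:
        return f"{dd}:Del:R:{min(c.repeat_copies - 1, 5)}"
    if c.mh_length >= 1:
        max_mh = {2: 1, 3: 2, 4: 3, 5: 5}[dd]
        return f"{dd}:Del:M:{min(c.mh_length, max_mh)}"
    return f"{dd}:Del:R:0"


def _insertion_id83_label(call: IndelCall, sequences: dict[str, str]) -> str:
    seq = sequences[call.sequence_name]
    ins = call.alt_allele
    d = len(ins)
    pos = call.position
    copies = _count_forward_copies(seq, pos, ins)
    if d == 1:
        base = {"A": "T", "G": "C"}.get(ins, ins)
        if base not in "CT":
            base = "T"
        return f"1:Ins:{base}:{min(copies, 5)}"
    return f"{min(d, 5)}:Ins:R:{min(copies, 5)}"


def spectrum_from_indels(
    indels: list[IndelCall],
    sequences: dict[str, str],
    scheme: str | tuple[str, ...] = "ID-83",
) -> SpectrumVector:
    """Bin normalized indels into a fixed-order category spectrum.

    ``scheme`` is either ``"ID-83"`` (the full COSMIC-style layout) or an
    explicit ordered subset of ID-83 labels; indels falling outside a subset
    scheme are dropped.
    """
    if scheme == "ID-83":
        labels = ID83_LABELS
        name = "ID-83"
    elif isinstance(scheme, str):
        raise ValueError(f"unknown scheme {scheme!r}")
    else:
        unknown = set(scheme) - set(ID83_LABELS)
        if unknown:
            raise ValueError(f"labels outside ID-83: {sorted(unknown)}")
        labels = tuple(scheme)
        name = f"subset-{len(labels)}"
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros(len(labels))
    for call in indels:
        if call.type == "deletion":
            lab = _deletion_id83_label(classify_deletion(call, sequences))
        else:
            lab = _insertion_id83_label(call, sequences)
        if lab in index:
            counts[index[lab]] += 1
    return SpectrumVector(labels=labels, counts=counts, scheme=name)


def subtract_background(
    ko_spectrum: SpectrumVector, wt_spectra: list[SpectrumVector]
) -> SpectrumVector:
    """Per-category ``max(0, ko - mean(wt))`` background subtraction."""
    if not wt_spectra:
        raise ValueError("need at least one background spectrum")
    for wt in wt_spectra:
        if wt.labels != ko_spectrum.labels:
            raise ValueError("spectra use different schemes")
    wt_mean = np.mean([wt.counts for wt in wt_spectra], axis=0)
    return SpectrumVector(
        labels=ko_spectrum.labels,
        counts=np.maximum(0.0, ko_spectrum.counts - wt_mean),
        scheme=ko_spectrum.scheme,
    )
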