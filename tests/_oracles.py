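"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library's internals: registers are found by
global string equality of post-deletion sequences, repeats by testing every
(start, unit length, copies) triple, and motif rules by literal pattern
matching.
"""

from __future__ import annotations

COMP = str.maketrans("ACGT", "TGCA")
DNA = set("ACGT")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


# -- repeat scanning --------------------------------------------------------


def oracle_tandem_repeats(seq: str, max_unit: int = 5) -> set[tuple[int, int, int, int]]:
    """All maximal primitive tandem runs as (start, end, unit_length, copies),
    found by testing every (start, r, n) triple."""
    found = set()
    n = len(seq)
    for r in range(1, max_unit + 1):
        for start in range(n):
            unit = seq[start : start + r]
            if len(unit) < r or not set(unit) <= DNA:
                continue
            # primitive unit?
            if any(r % p == 0 and unit == unit[:p] * (r // p) for p in range(1, r)):
                continue
            copies = 1
            while seq[start + copies * r : start + (copies + 1) * r] == unit:
                copies += 1
            if copies < 2:
                continue
            # left-anchored maximal run: no single-base shift extension 5'
            if start >= 1 and seq[start - 1] == seq[start - 1 + r]:
                continue
            found.add((start, start + copies * r, r, copies))
    return found


def oracle_mh_sites(seq: str, d: int) -> set[int]:
    """Anchor positions i with seq[i] == seq[i+d] whose supported deletion is
    not part of a tandem array of >= 2 unit copies (STR precedence)."""
    out = set()
    n = len(seq)
    for i in range(n - d):
        if not set(seq[i : i + d + 1]) <= DNA:
            continue
        if seq[i] != seq[i + d]:
            continue
        if _oracle_fields(seq, i, d)["copies"] >= 2:
            continue
        out.add(i)
    return out


# -- deletion classification ------------------------------------------------


def oracle_registers(seq: str, pos: int, d: int) -> list[int]:
    """Every start p whose deletion yields the identical post-deletion
    string (global comparison, independent of shift logic)."""
    target = seq[:pos] + seq[pos + d :]
    return [p for p in range(len(seq) - d + 1) if seq[:p] + seq[p + d :] == target]


def _oracle_fields(seq: str, pos: int, d: int) -> dict:
    regs = oracle_registers(seq, pos, d)
    left, right = min(regs), max(regs)

    unit = seq[left : left + d]
    copies = 1
    while seq[left : left + (copies + 1) * d] == unit * (copies + 1):
        copies += 1

    runit = seq[right : right + d]
    five = max(
        (k for k in range(d + 1) if k <= right and seq[right - k : right] == runit[d - k :]),
        default=0,
    )
    three = max(
        (
            k
            for k in range(d + 1)
            if right + d + k <= len(seq) and seq[right + d : right + d + k] == runit[:k]
        ),
        default=0,
    )
    mh = max(five, three)
    if copies >= 2:
        context = "STR"
    elif mh >= 1:
        context = "MH"
    else:
        context = "other"
    return {
        "regs": regs,
        "left": left,
        "copies": copies,
        "mh_length": mh,
        "context": context,
        "unit": unit,
    }


def _oracle_tnt_one_strand(seq: str, pos: int, d: int) -> bool:
    """Forward-strand-only TNT rule, literal pattern matching."""
    f = _oracle_fields(seq, pos, d)
    regs, left, copies, unit, context = (
        f["regs"], f["left"], f["copies"], f["unit"], f["context"],
    )
    if d == 2 or context == "other":
        return any(
            p >= 1
            and p + d - 1 < len(seq)
            and seq[p - 1] == "T"
            and seq[p + d - 1] == "T"
            for p in regs
        )
    if context == "STR":
        rp = next(
            p for p in range(1, d + 1) if d % p == 0 and unit == unit[:p] * (d // p)
        )
        s = left
        while s - 1 >= 0 and seq[s - 1] == seq[s - 1 + rp]:
            s -= 1
        e = left + copies * d
        while e < len(seq) and seq[e] == seq[e - rp]:
            e += 1
        return any(seq[j] == "T" and seq[j + d] == "T" for j in range(s, e - d))
    return any(
        (p >= 1 and seq[p - 1] == "T" and seq[p + d - 1] == "T")
        or (p + d < len(seq) and seq[p] == "T" and seq[p + d] == "T")
        for p in regs
    )


def oracle_classify(seq: str, pos: int, d: int) -> dict:
    """Field-by-field deletion classification by literal string matching.

    TNT compliance is strand-collapsed: the rule is evaluated on the forward
    string and again on the reverse complement at the mirrored position.
    """
    if not set(seq[max(0, pos - 1) : pos + d + 1]) <= DNA:
        return {
            "context": "other",
            "repeat_copies": 1,
            "mh_length": 0,
            "tnt": False,
        }
    f = _oracle_fields(seq, pos, d)
    tnt = _oracle_tnt_one_strand(seq, pos, d) or _oracle_tnt_one_strand(
        rc(seq), len(seq) - pos - d, d
    )
    return {
        "context": f["context"],
        "repeat_copies": f["copies"],
        "mh_length": f["mh_length"],
        "tnt": tnt,
    }


# -- logo canonicalization --------------------------------------------------


def oracle_canonical_window(seq: str, pos: int, flank: int) -> str:
    """Rule-literal canonicalized window for a 2 bp deletion: reverse
    complement when the deleted pair contains A (except AT/TA), then right
    align to the most 3' T of the ambiguity range, else to its limit."""
    di = seq[pos : pos + 2]
    if "A" in di and di not in ("AT", "TA"):
        work = rc(seq)
        pos = len(seq) - pos - 2
    else:
        work = seq
    regs = oracle_registers(work, pos, 2)
    with_t3 = [p for p in regs if work[p + 1] == "T"]
    with_t5 = [p for p in regs if work[p] == "T"]
    if with_t3:
        p = max(with_t3)
    elif with_t5:
        p = max(with_t5)
    else:
        p = max(regs)
    lo, hi = p - flank, p + 2 + flank
    window = work[max(0, lo) : min(len(work), hi)]
    return "N" * max(0, -lo) + window + "N" * max(0, hi - len(work))


# -- reporter design --------------------------------------------------------


def oracle_dinucleotide_key(s: str) -> tuple[int, int, int]:
    """(longest dinucleotide-run bp, total dinucleotide-repeat bp, longest
    homopolymer run), each by exhaustive substring testing."""
    n = len(s)
    covered = set()
    longest = 0
    for start in range(n):
        for end in range(start + 4, n + 1):
            sub = s[start:end]
            unit = sub[:2]
            if unit[0] == unit[1]:
                continue
            length = end - start
            if length % 2 == 0 and sub == unit * (length // 2):
                # maximal: no single-base shift 5', no whole extra copy 3'
                if start >= 1 and s[start - 1] == s[start + 1]:
                    continue
                if s[end : end + 2] == unit:
                    continue
                covered.update(range(start, end))
                longest = max(longest, length)
    mono = 0
    for start in range(n):
        k = 1
        while start + k < n and s[start + k] == s[start]:
            k += 1
        mono = max(mono, k)
    return (longest, len(covered), mono)
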