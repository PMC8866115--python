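"""File formats: FASTA, BED, VCF v4.2, and the package's TSV tables.

All in-memory coordinates are 0-based half-open; this module is the single
place converting to and from 1-based anchored VCF records.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_context import MappabilityMask, RepeatRegion
from .indel_classify import ClassifiedDeletion, IndelCall, SpectrumVector


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# BED (0-based half-open)


def write_bed_mask(mask: MappabilityMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, ivs in mask.intervals.items():
            for s, e in ivs:
                fh.write(f"{name}\t{s}\t{e}\n")


def read_bed_mask(path: str | Path) -> MappabilityMask:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            name, s, e = line.split("\t")[:3]
            intervals.setdefault(name, []).append((int(s), int(e)))
    for ivs in intervals.values():
        ivs.sort()
    return MappabilityMask(intervals)


def write_bed_repeats(regions: list[RepeatRegion], path: str | Path) -> None:
    """Repeat/MH annotation BED with name field ``kind:unit:copies``."""
    with open(path, "w") as fh:
        for r in regions:
            copies = r.copies if r.copies is not None else "."
            fh.write(
                f"{r.sequence_name}\t{r.start}\t{r.end}\t"
                f"{r.kind}:{r.unit_sequence}:{copies}\n"
            )


def write_bed_gene_spans(spans: dict[str, tuple[int, int]], path: str | Path,
                         chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for gene, (s, e) in sorted(spans.items(), key=lambda kv: kv[1]):
            fh.write(f"{chrom}\t{s}\t{e}\t{gene}\n")


def read_bed_gene_spans(path: str | Path) -> dict[str, tuple[int, int]]:
    spans: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            spans[parts[3]] = (int(parts[1]), int(parts[2]))
    return spans


# --------------------------------------------------------------------------
# VCF v4.2


def write_vcf(
    calls: list[IndelCall], sequences: dict[str, str], path: str | Path
) -> None:
    """Anchored VCF v4.2 (REF carries the base 5' of the event)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TID,Number=1,Type=Integer,Description="Truth id">\n')
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            seq = sequences[c.sequence_name]
            if c.position < 1:
                raise ValueError("cannot anchor an event at position 0")
            anchor = seq[c.position - 1]
            if c.type == "deletion":
                ref = anchor + c.ref_allele
                alt = anchor
            else:
                ref = anchor
                alt = anchor + c.alt_allele
            fh.write(
                f"{c.sequence_name}\t{c.position}\t.\t{ref}\t{alt}\t.\tPASS\tTID={i}\n"
            )


def vcf_record_to_call(chrom: str, pos1: int, ref: str, alt: str) -> IndelCall:
    """Convert one VCF allele pair to an internal (unanchored) call."""
    ref, alt = ref.upper(), alt.upper()
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    ref_t, alt_t = ref[k:], alt[k:]
    while ref_t and alt_t and ref_t[-1] == alt_t[-1]:
        ref_t, alt_t = ref_t[:-1], alt_t[:-1]
    return IndelCall(chrom, pos1 - 1 + k, ref_t, alt_t)


def read_vcf(path: str | Path) -> list[IndelCall]:
    from cyvcf2 import VCF

    calls = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            calls.append(vcf_record_to_call(v.CHROM, v.POS, v.REF, alt))
    return calls


# --------------------------------------------------------------------------
# TSV tables


def write_deletions_tsv(calls: list[IndelCall], path: str | Path) -> None:
    """Internal 0-based half-open deletion table."""
    rows = [
        {
            "truth_id": i,
            "chrom": c.sequence_name,
            "start": c.position,
            "end": c.position + c.length,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "type": c.type,
        }
        for i, c in enumerate(calls)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_deletions_tsv(path: str | Path) -> list[IndelCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        IndelCall(str(r.chrom), int(r.start), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]


def write_classified_tsv(classified: list[ClassifiedDeletion], path: str | Path) -> None:
    rows = [
        {
            "chrom": c.call.sequence_name,
            "start": c.call.position,
            "end": c.call.position + c.call.length,
            "ref": c.call.ref_allele,
            "context": c.context,
            "repeat_copies": c.repeat_copies,
            "mh_length": c.mh_length,
            "canonical_class": c.canonical_class or "",
            "tnt_compliant": c.tnt_compliant,
            "right_aligned_start": c.right_aligned_start,
            "ambiguous_register": c.ambiguous_register,
            "warning": c.warning or "",
        }
        for c in classified
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_spectrum_tsv(spectrum: SpectrumVector, path: str | Path) -> None:
    pd.DataFrame(
        {"category": spectrum.labels, "count": spectrum.counts}
    ).to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path: str | Path, scheme: str = "ID-83") -> SpectrumVector:
    df = pd.read_csv(path, sep="\t")
    return SpectrumVector(
        labels=tuple(df["category"]), counts=df["count"].to_numpy(), scheme=scheme
    )


def write_counts_tsv(counts: list[int], n_final: float, path: str | Path) -> None:
    pd.DataFrame(
        {
            "culture_id": [f"c{i + 1}" for i in range(len(counts))],
            "mutant_count": counts,
            "n_final": n_final,
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> tuple[list[int], float]:
    df = pd.read_csv(path, sep="\t")
    return [int(c) for c in df["mutant_count"]], float(df["n_final"].iloc[0])


def write_expression_tsv(
    tpm: pd.DataFrame, tissue_labels: dict[str, str], path: str | Path
) -> None:
    long = tpm.reset_index(names="gene").melt(
        id_vars="gene", var_name="sample", value_name="tpm"
    )
    long["tissue"] = long["sample"].map(tissue_labels)
    long[["gene", "tissue", "sample", "tpm"]].to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    long = pd.read_csv(path, sep="\t")
    tpm = long.pivot(index="gene", columns="sample", values="tpm")
    labels = dict(long.drop_duplicates("sample")[["sample", "tissue"]].values)
    return tpm, labels


def write_signal_tsv(signal: pd.DataFrame, path: str | Path) -> None:
    signal.to_csv(path, sep="\t", index=False)


def read_signal_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
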