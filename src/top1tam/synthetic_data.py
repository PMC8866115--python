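"""Synthetic inputs with machine-readable truth labels.

Every input the pipeline consumes can be generated here: genomes with planted
short tandem repeats and microhomology motifs, deletion sets with a tunable
TNT-motif placement bias, Luria-Delbruck colony-count distributions,
expression tables with tissue-restricted genes and expression-coupled
mutation placement, and binned TOP1-activity-like signal tracks.  All
generators are deterministic functions of (seed, parameters).

Background sequence is i.i.d. per base at a stated GC fraction (no
higher-order Markov structure); planted repeats are guarded by fix-up bases so
that the planted run is exactly the maximal run an annotation scan recovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluctuation import FluctuationExperiment
from .genome_context import MappabilityMask, RepeatRegion
from .indel_classify import IndelCall, deletion_is_tnt_compliant, normalize_indel
from .sequence import is_primitive

#: Deletion length mix used by default: 2 bp deletions predominate, as in
#: TOP1-associated (ID4-like) mutagenesis.
DEFAULT_DELETION_LENGTHS: dict[int, float] = {2: 0.55, 3: 0.20, 4: 0.15, 5: 0.10}


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    mappability_mask: MappabilityMask
    truth_repeats: list[RepeatRegion]
    seed: int

    def __post_init__(self) -> None:
        for reg in self.truth_repeats:
            n = len(self.sequences[reg.sequence_name])
            if not 0 <= reg.start < reg.end <= n:
                raise ValueError(f"truth repeat {reg} outside sequence bounds")


@dataclass
class PlantedDeletionSet:
    deletions: list[IndelCall]
    truth_tnt_flags: list[bool]
    tnt_bias: float
    length_distribution: dict[int, float]

    def __post_init__(self) -> None:
        if len(self.deletions) != len(self.truth_tnt_flags):
            raise ValueError("flags must parallel deletions")
        if not 0.0 <= self.tnt_bias <= 1.0:
            raise ValueError("tnt_bias must be in [0,1]")
        if self.tnt_bias == 1.0 and not all(self.truth_tnt_flags):
            raise ValueError("tnt_bias=1 requires all truth flags true")


@dataclass
class SyntheticExpressionDataset:
    gene_spans: dict[str, tuple[int, int]]  # on a single synthetic chromosome
    tpm: pd.DataFrame  # genes x samples, non-negative
    tissue_labels: dict[str, str]  # sample -> tissue
    mutation_rate_model: dict[str, float]  # gene -> expected deletions/individual
    truth_hetr: dict[str, str]  # HETR gene -> home tissue
    n_individuals: int
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM entries must be non-negative")
        missing = set(self.mutation_rate_model) - set(self.gene_spans)
        if missing:
            raise ValueError(f"mutated genes without spans: {sorted(missing)[:5]}")


# --------------------------------------------------------------------------
# genome generation


def _random_bases(rng: np.random.Generator, n: int, gc_fraction: float) -> np.ndarray:
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _pick_position(
    rng: np.random.Generator, length: int, width: int, occupied: list[tuple[int, int]]
) -> int:
    """Uniform non-overlapping placement with a 2 bp guard margin."""
    for _ in range(10_000):
        pos = int(rng.integers(2, length - width - 2))
        if all(pos >= e + 2 or pos + width <= s - 2 for s, e in occupied):
            occupied.append((pos, pos + width))
            return pos
    raise ValueError("could not place repeat without overlap; plan too dense")


def generate_genome(
    length: int,
    seed: int,
    gc_fraction: float = 0.4,
    repeat_plan: list[tuple] | None = None,
) -> SyntheticGenome:
    """i.i.d. background sequence with deliberately planted repeats.

    ``repeat_plan`` entries are ``(kind, unit_length, copies, count)`` or
    ``(kind, unit_length, copies, count, unit_sequence)``; kind is "STR" or
    "MH" (for MH, ``copies`` is ignored and the planted element is the motif
    ``B N^(r-1) B``).  Planted elements are placed at uniform non-overlapping
    positions and guarded against accidental extension by the background.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    base = _random_bases(rng, length, gc_fraction)

    plan = repeat_plan or []
    planted_bp = 0
    for entry in plan:
        kind, r, copies, count = entry[:4]
        width = r * copies if kind == "STR" else r + 1
        planted_bp += width * count
    if planted_bp > length / 2:
        raise ValueError(
            f"repeat plan infeasible: {planted_bp} planted bp > {length}/2"
        )

    occupied: list[tuple[int, int]] = []
    truth: list[RepeatRegion] = []
    name = "chr1"
    for entry in plan:
        kind, r, copies, count = entry[:4]
        unit_fixed = entry[4] if len(entry) > 4 else None
        for _ in range(count):
            if kind == "STR":
                if unit_fixed is not None:
                    unit = unit_fixed
                else:
                    while True:
                        unit = "".join(rng.choice(np.array(list("ACGT")), size=r))
                        if is_primitive(unit):
                            break
                width = r * copies
                pos = _pick_position(rng, length, width, occupied)
                base[pos : pos + width] = list(unit * copies)
                # guard bases: block single-base run extension on both sides
                base[pos - 1] = _other_base(rng, base[pos + r - 1])
                base[pos + width] = _other_base(rng, base[pos + width - r])
                truth.append(
                    RepeatRegion(name, pos, pos + width, "STR", r, unit, copies)
                )
            elif kind == "MH":
                if unit_fixed is not None:
                    motif = unit_fixed
                else:
                    anchor = str(rng.choice(np.array(list("ACGT"))))
                    interior = "".join(rng.choice(np.array(list("ACGT")), size=r - 1))
                    motif = anchor + interior + anchor
                width = r + 1
                pos = _pick_position(rng, length, width, occupied)
                base[pos : pos + width] = list(motif)
                # block same-register tandem copies around the candidate unit
                base[pos + width] = _other_base(rng, base[pos + 1])
                base[pos - 1] = _other_base(rng, base[pos + r - 1])
                truth.append(RepeatRegion(name, pos, pos + width, "MH", r, motif))
            else:
                raise ValueError(f"unknown repeat kind {kind!r}")

    seq = "".join(base)
    genome = SyntheticGenome(
        sequences={name: seq},
        mappability_mask=MappabilityMask.full({name: seq}),
        truth_repeats=sorted(truth, key=lambda t: t.start),
        seed=seed,
    )
    return genome


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return str(rng.choice(np.array(choices)))


# --------------------------------------------------------------------------
# deletion planting


def _candidate_sites(
    genome: SyntheticGenome, d: int
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """(all mappable sites, TNT-compliant subset) for d-bp deletions."""
    all_sites: list[tuple[str, int]] = []
    tnt_sites: list[tuple[str, int]] = []
    for name, ivs in genome.mappability_mask.intervals.items():
        seq = genome.sequences[name]
        for s, e in ivs:
            # require 1 bp of 5' flank (motif scoring) and full containment
            for pos in range(max(s, 1), min(e, len(seq)) - d + 1):
                all_sites.append((name, pos))
                if deletion_is_tnt_compliant(seq, pos, d):
                    tnt_sites.append((name, pos))
    return all_sites, tnt_sites


def plant_deletions(
    genome: SyntheticGenome,
    n: int,
    tnt_bias: float,
    length_distribution: dict[int, float] | None = None,
    seed: int = 0,
) -> PlantedDeletionSet:
    """Place ``n`` deletions; with probability ``tnt_bias`` at a TNT-compliant
    site, else uniformly over mappable sites.  Truth flags record the
    placement branch (a uniformly placed deletion may still be compliant by
    chance, so the observed compliant fraction converges to
    ``bias + (1-bias) * background``)."""
    if not 0.0 <= tnt_bias <= 1.0:
        raise ValueError("tnt_bias must be in [0,1]")
    dist = dict(length_distribution or DEFAULT_DELETION_LENGTHS)
    total_w = sum(dist.values())
    lengths = sorted(dist)
    probs = np.array([dist[d] / total_w for d in lengths])

    rng = np.random.default_rng(seed)
    sites: dict[int, tuple[list, list]] = {}
    for d in lengths:
        all_s, tnt_s = _candidate_sites(genome, d)
        if len(all_s) < n:
            raise ValueError(f"fewer than {n} candidate sites of length {d}")
        if tnt_bias > 0 and not tnt_s:
            raise ValueError(f"no TNT-compliant site of length {d} exists")
        sites[d] = (all_s, tnt_s)

    deletions: list[IndelCall] = []
    flags: list[bool] = []
    for _ in range(n):
        d = lengths[rng.choice(len(lengths), p=probs)]
        all_s, tnt_s = sites[d]
        forced = bool(rng.random() < tnt_bias)
        pool = tnt_s if forced else all_s
        name, pos = pool[int(rng.integers(len(pool)))]
        seq = genome.sequences[name]
        call = normalize_indel(
            IndelCall(name, pos, seq[pos : pos + d], ""), genome.sequences
        )
        deletions.append(call)
        flags.append(forced)
    if tnt_bias == 1.0:
        flags = [True] * len(flags)
    return PlantedDeletionSet(
        deletions=deletions,
        truth_tnt_flags=flags,
        tnt_bias=tnt_bias,
        length_distribution=dist,
    )


# --------------------------------------------------------------------------
# fluctuation assay simulation


def simulate_fluctuation(
    mu_per_division: float,
    n_start: int = 1,
    n_final: float = 1e7,
    n_cultures: int = 16,
    seed: int = 0,
    target_bp: int = 1032,
    reporter_copies: int = 1,
    name: str = "",
) -> FluctuationExperiment:
    """Synchronized-doubling Luria-Delbruck culture simulation.

    Populations double generation by generation from ``n_start`` until
    reaching ``n_final``; each wild-type division yields a mutant daughter
    with probability ``mu_per_division`` and mutants breed true.  The
    per-generation mutation probability matches the rate definition of the
    Lea-Coulson estimator.
    """
    if not 0.0 <= mu_per_division <= 0.01:
        raise ValueError("mu_per_division must be in [0, 0.01]")
    if n_final < n_start or n_start < 1:
        raise ValueError("need n_final >= n_start >= 1")
    rng = np.random.default_rng(seed)
    wt = np.full(n_cultures, n_start, dtype=np.int64)
    mut = np.zeros(n_cultures, dtype=np.int64)
    pop = n_start
    while pop < n_final:
        new_mut = rng.binomial(wt, mu_per_division)
        mut = 2 * mut + new_mut
        wt = 2 * wt - new_mut
        pop *= 2
    return FluctuationExperiment(
        mutant_counts=[int(c) for c in mut],
        n_final=float(pop),
        target_bp=target_bp,
        reporter_copies=reporter_copies,
        name=name,
    )


# --------------------------------------------------------------------------
# expression dataset


def simulate_expression_dataset(
    n_genes: int = 200,
    n_tissues: int = 4,
    hetr_fraction: float = 0.1,
    coupling: float = 1.0,
    seed: int = 0,
    samples_per_tissue: int = 3,
    gene_length: int = 5000,
    deletions_per_gene_baseline: float = 2.0,
    n_individuals: int = 50,
) -> tuple[SyntheticExpressionDataset, PlantedDeletionSet]:
    """Expression table with tissue-restricted (HETR) genes and deletions
    placed with expectation proportional to ``TPM ** coupling``.

    HETR genes receive within-home-tissue expression above every baseline
    value (hence above the tissue q90) and exactly zero elsewhere, so the
    q90 / q90*0.1 rule recovers the truth set exactly; non-HETR genes share a
    gene-level mean across tissues with tight multiplicative noise, so highly
    expressed non-HETR genes fail the tissue-restriction condition.
    """
    if n_genes < 20:
        raise ValueError("need at least 20 genes")
    if not 0.0 <= hetr_fraction <= 0.5:
        raise ValueError("hetr_fraction must be in [0, 0.5]")
    n_hetr = round(hetr_fraction * n_genes)
    if n_hetr > 0 and n_tissues < 2:
        raise ValueError("HETR genes require at least 2 tissues")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    tissues = [f"tissue{t}" for t in range(n_tissues)]
    samples = [f"{tis}_s{k}" for tis in tissues for k in range(samples_per_tissue)]
    tissue_labels = {s: s.rsplit("_", 1)[0] for s in samples}

    gene_mean = rng.lognormal(mean=np.log(10.0), sigma=1.5, size=n_genes)
    noise = rng.lognormal(mean=0.0, sigma=0.1, size=(n_genes, len(samples)))
    tpm = pd.DataFrame(gene_mean[:, None] * noise, index=genes, columns=samples)

    hetr_genes = list(rng.choice(genes, size=n_hetr, replace=False))
    truth_hetr: dict[str, str] = {}
    high = float(gene_mean.max()) * 2.0
    for i, g in enumerate(hetr_genes):
        home = tissues[i % n_tissues]
        truth_hetr[g] = home
        for s in samples:
            tpm.loc[g, s] = (
                high * float(rng.uniform(1.0, 2.0)) if tissue_labels[s] == home else 0.0
            )

    gap = 100
    spans = {
        g: (i * (gene_length + gap), i * (gene_length + gap) + gene_length)
        for i, g in enumerate(genes)
    }
    total_len = n_genes * (gene_length + gap) + gap
    chrom = "".join(_random_bases(rng, total_len, 0.4))
    sequences = {"chr1": chrom}

    med = tpm.median(axis=1)
    rel = (med / float(med.median())).clip(lower=0.0) ** coupling
    lam = deletions_per_gene_baseline * rel
    rate_model = dict(zip(genes, lam.tolist()))

    len_dist = dict(DEFAULT_DELETION_LENGTHS)
    dlens = sorted(len_dist)
    dprobs = np.array([len_dist[d] for d in dlens])
    dprobs = dprobs / dprobs.sum()
    deletions: list[IndelCall] = []
    flags: list[bool] = []
    for g in genes:
        count = int(rng.poisson(lam[g]))
        s, e = spans[g]
        for _ in range(count):
            d = dlens[rng.choice(len(dlens), p=dprobs)]
            pos = int(rng.integers(max(s, 1), e - d))
            call = normalize_indel(
                IndelCall("chr1", pos, chrom[pos : pos + d], ""), sequences
            )
            deletions.append(call)
            flags.append(deletion_is_tnt_compliant(chrom, call.position, d))

    dataset = SyntheticExpressionDataset(
        gene_spans=spans,
        tpm=tpm,
        tissue_labels=tissue_labels,
        mutation_rate_model=rate_model,
        truth_hetr=truth_hetr,
        n_individuals=n_individuals,
        sequences=sequences,
    )
    planted = PlantedDeletionSet(
        deletions=deletions,
        truth_tnt_flags=flags,
        tnt_bias=0.0,
        length_distribution=len_dist,
    )
    return dataset, planted


# --------------------------------------------------------------------------
# binned signal track


def simulate_signal_track(
    genome: SyntheticGenome,
    deletion_set: PlantedDeletionSet,
    coupling: float,
    seed: int = 0,
    bin_size: int = 1000,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Two replicate binned signal tracks coupled to planted deletion density.

    Signal per bin = baseline gamma noise + coupling x local deletion density
    (deletion starts per mappable bp in the bin); the replicates share the
    coupling term and differ only by independent noise.  Partial terminal bins
    keep their true mappable width.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    del_starts: dict[str, np.ndarray] = {}
    for name in genome.sequences:
        starts = np.array(
            [c.position for c in deletion_set.deletions if c.sequence_name == name]
        )
        del_starts[name] = starts
    for name, seq in genome.sequences.items():
        n = len(seq)
        for s in range(0, n, bin_size):
            e = min(s + bin_size, n)
            mappable = sum(
                max(0, min(e, ie) - max(s, is_))
                for is_, ie in genome.mappability_mask.intervals.get(name, [])
            )
            starts = del_starts[name]
            count = int(((starts >= s) & (starts < e)).sum()) if starts.size else 0
            density = count / mappable if mappable else 0.0
            signal = coupling * density
            rep1 = signal + rng.gamma(2.0, noise_scale / 2.0)
            rep2 = signal + rng.gamma(2.0, noise_scale / 2.0)
            rows.append((name, s, e, mappable, rep1, rep2))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mappable_bp", "rep1", "rep2"]
    )
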