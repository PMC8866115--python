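"""Deletion burden stratified by gene expression and TOP1 activity.

Implements expression-group assignment (decile, housekeeping-like decile, and
the collapsed four-group germline scheme), per-stratum deletion rates
``c / (g n)`` (count over union genomic span over mutated genomes) with
gene-selection bootstrap CIs, highly-expressed tissue-restricted (HETR) gene
calling with enrichment odds ratios, TOP1-signal decile relative rates, and
per-individual total-count outlier filtering.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .indel_classify import IndelCall
from .null_enrichment import adjust_pvalues


@dataclass
class StratumRate:
    stratum: str
    count: int
    span_bp: int
    n_genomes: int
    rate: float  # per bp per genome
    ci_low: float
    ci_high: float
    undefined: bool = False


@dataclass
class TissueExpressionSummary:
    """Per-tissue per-gene medians, q90 thresholds and other-tissue medians."""

    within_median: pd.DataFrame  # genes x tissues
    other_median: pd.DataFrame  # genes x tissues
    q90: pd.Series  # per tissue: 90th quantile of within-tissue gene medians

    @classmethod
    def from_expression(
        cls, tpm: pd.DataFrame, tissue_labels: dict[str, str]
    ) -> "TissueExpressionSummary":
        tissues = sorted(set(tissue_labels.values()))
        if len(tissues) < 2:
            raise ValueError("need at least 2 tissues")
        within = {}
        other = {}
        for t in tissues:
            own = [s for s in tpm.columns if tissue_labels[s] == t]
            rest = [s for s in tpm.columns if tissue_labels[s] != t]
            within[t] = tpm[own].median(axis=1)
            other[t] = tpm[rest].median(axis=1)
        within_df = pd.DataFrame(within)
        return cls(
            within_median=within_df,
            other_median=pd.DataFrame(other),
            q90=within_df.quantile(0.9),
        )


@dataclass
class HetrResult:
    cancer: str
    tissue: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    q_value: float | None
    display_value: float  # reciprocal 1/r for depletion (r < 1)
    undefined_or: bool = False


# --------------------------------------------------------------------------
# expression groups

GERMLINE_COLLAPSE = {
    1: "unexpressed",
    2: "low",
    3: "low",
    4: "low",
    5: "mid",
    6: "mid",
    7: "mid",
    8: "high",
    9: "high",
}


def resolve_overlapping_genes(
    tpm: pd.DataFrame, gene_spans: dict[str, tuple[int, int]]
) -> list[str]:
    """Drop the less-expressed gene of each overlapping pair, hierarchically
    from the most abundant (highest median, mean breaking ties)."""
    med = tpm.median(axis=1)
    mean = tpm.mean(axis=1)
    order = sorted(
        [g for g in tpm.index if g in gene_spans],
        key=lambda g: (-med[g], -mean[g], g),
    )
    kept: list[str] = []
    kept_ivs: list[tuple[int, int]] = []
    for g in order:
        s, e = gene_spans[g]
        if all(e <= ks or s >= ke for ks, ke in kept_ivs):
            kept.append(g)
            kept_ivs.append((s, e))
    return kept


def assign_expression_groups(
    expr,
    scheme: str = "deciles",
    gene_spans: dict[str, tuple[int, int]] | None = None,
) -> dict[str, str]:
    """Deterministic gene -> expression-group assignment.

    ``deciles``: decile bins (1..10) of per-gene median TPM. ``housekeeping-
    deciles``: the same after restricting to housekeeping-like genes (maximal
    expression below ten times median expression). ``germline-4``: collapse
    of precomputed groups 1..9 into unexpressed / low / mid / high.  With
    ``gene_spans``, overlapping genes are resolved by retaining the most
    abundantly expressed.
    """
    if scheme == "germline-4":
        groups = pd.Series(expr)
        bad = set(groups.unique()) - set(GERMLINE_COLLAPSE)
        if bad:
            raise ValueError(f"germline groups must be 1..9, got {sorted(bad)}")
        return {g: GERMLINE_COLLAPSE[int(v)] for g, v in groups.items()}

    if scheme not in ("deciles", "housekeeping-deciles"):
        raise ValueError(f"unknown scheme {scheme!r}")
    tpm: pd.DataFrame = expr
    if gene_spans is not None:
        tpm = tpm.loc[resolve_overlapping_genes(tpm, gene_spans)]
    med = tpm.median(axis=1)
    if scheme == "housekeeping-deciles":
        keep = tpm.max(axis=1) < 10.0 * med
        med = med[keep]
    if len(med) < 10:
        raise ValueError("need at least 10 genes for decile assignment")
    if (med == 0).all():
        raise ValueError("all-zero expression cannot be decile-binned")
    deciles = pd.qcut(med.rank(method="first"), 10, labels=range(1, 11))
    return {g: str(d) for g, d in deciles.items()}


# --------------------------------------------------------------------------
# stratum rates


def _count_in_spans(
    positions: np.ndarray, spans: list[tuple[int, int]]
) -> np.ndarray:
    """Deletion count per span (containment of the leftmost deleted base)."""
    counts = np.zeros(len(spans), dtype=int)
    if positions.size == 0:
        return counts
    positions = np.sort(positions)
    for i, (s, e) in enumerate(spans):
        counts[i] = np.searchsorted(positions, e) - np.searchsorted(positions, s)
    return counts


def stratum_rates(
    indels: list[IndelCall],
    gene_spans: dict[str, tuple[int, int]],
    groups: dict[str, str],
    n_genomes: int,
    bootstrap_B: int = 100,
    seed: int = 0,
    sequence_name: str | None = None,
) -> list[StratumRate]:
    """Per-group deletion rates c/(g n) with gene-selection bootstrap CIs.

    The bootstrap resamples each group's genes with replacement to the same
    number, recomputing both the count and the union span, and takes the
    0.025/0.975 quantiles of the resampled rates.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.array(
        [
            c.position
            for c in indels
            if sequence_name is None or c.sequence_name == sequence_name
        ]
    )
    results = []
    for label in sorted(set(groups.values())):
        genes = [g for g, grp in groups.items() if grp == label and g in gene_spans]
        spans = [gene_spans[g] for g in genes]
        g_total = sum(e - s for s, e in spans)
        if g_total == 0:
            results.append(
                StratumRate(label, 0, 0, n_genomes, float("nan"), float("nan"),
                            float("nan"), undefined=True)
            )
            continue
        counts = _count_in_spans(positions, spans)
        widths = np.array([e - s for s, e in spans])
        c_total = int(counts.sum())
        rate = c_total / (g_total * n_genomes)
        if c_total == 0:
            ci = (0.0, 0.0)
        else:
            boot = np.empty(bootstrap_B)
            for b in range(bootstrap_B):
                idx = rng.integers(0, len(spans), size=len(spans))
                gb = widths[idx].sum()
                boot[b] = counts[idx].sum() / (gb * n_genomes) if gb else np.nan
            ci = (
                float(np.nanquantile(boot, 0.025)),
                float(np.nanquantile(boot, 0.975)),
            )
        results.append(
            StratumRate(label, c_total, g_total, n_genomes, rate, ci[0], ci[1])
        )
    return results


# --------------------------------------------------------------------------
# HETR genes and enrichment


def hetr_genes(summary: TissueExpressionSummary, tissue: str) -> set[str]:
    """Highly expressed tissue-restricted genes: within-tissue median at or
    above the tissue q90, other-tissue median below 0.1 x q90."""
    if tissue not in summary.within_median.columns:
        raise ValueError(f"unknown tissue {tissue!r}")
    q90 = float(summary.q90[tissue])
    w = summary.within_median[tissue]
    o = summary.other_median[tissue]
    return set(w.index[(w >= q90) & (o < 0.1 * q90)])


def hetr_enrichment(
    deletions_by_cancer: dict[str, list[IndelCall]],
    hetr_sets: dict[str, set[str]],
    gene_spans: dict[str, tuple[int, int]],
    correction: str = "bonferroni",
) -> list[HetrResult]:
    """Per cancer-tissue 2x2 Fisher tests of HETR vs non-HETR deletion counts
    against all other cancers, corrected over all pairs tested."""
    if len(deletions_by_cancer) < 2:
        raise ValueError("need at least 2 cancer types")
    gene_list = sorted(gene_spans)
    starts = [gene_spans[g][0] for g in gene_list]
    ends = [gene_spans[g][1] for g in gene_list]
    order = np.argsort(starts)
    starts_sorted = np.array(starts)[order]
    ends_sorted = np.array(ends)[order]
    genes_sorted = [gene_list[i] for i in order]

    def genes_hit(calls: list[IndelCall]) -> list[str]:
        out = []
        for c in calls:
            i = bisect_right(starts_sorted, c.position) - 1
            if i >= 0 and c.position < ends_sorted[i]:
                out.append(genes_sorted[i])
        return out

    hits = {cancer: genes_hit(calls) for cancer, calls in deletions_by_cancer.items()}
    results: list[HetrResult] = []
    for cancer in sorted(deletions_by_cancer):
        others = [c for c in deletions_by_cancer if c != cancer]
        for tissue in sorted(hetr_sets):
            hetr = hetr_sets[tissue]
            a = sum(g in hetr for g in hits[cancer])
            b_ = len(hits[cancer]) - a
            c_ = sum(g in hetr for o in others for g in hits[o])
            d_ = sum(len(hits[o]) for o in others) - c_
            table = ((a, b_), (c_, d_))
            if min(a + b_, c_ + d_) == 0 or min(a + c_, b_ + d_) == 0:
                results.append(
                    HetrResult(cancer, tissue, table, float("nan"), 1.0, None,
                               float("nan"), undefined_or=True)
                )
                continue
            orr, p = fisher_exact([[a, b_], [c_, d_]], alternative="two-sided")
            display = 1.0 / orr if 0 < orr < 1 else float(orr)
            results.append(
                HetrResult(cancer, tissue, table, float(orr), float(p), None, display,
                           undefined_or=not np.isfinite(orr))
            )
    ps = [r.p_value for r in results]
    qs = adjust_pvalues(ps, method="bonferroni" if correction == "bonferroni" else "bh")
    for r, q in zip(results, qs):
        r.q_value = q
    return results


# --------------------------------------------------------------------------
# TOP1-signal decile relative rates


@dataclass
class DecileRate:
    decile: int
    count: int
    mappable_bp: int
    relative_rate: float
    ci_low: float
    ci_high: float
    undefined: bool = False


def signal_decile_rates(
    signal: pd.DataFrame,
    deletions: list[IndelCall],
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> list[DecileRate]:
    """Relative deletion rates across signal deciles, decile 1 fixed at 1.

    ``signal`` carries one row per bin (chrom, start, end, mappable_bp, and
    two replicate columns rep1/rep2).  Bins are decile-ranked on mean
    replicate signal per mappable bp; deletions are counted by start position
    into bins; per-decile rates (count / mappable bp) are normalized to the
    first decile, with bin-resampling bootstrap CIs.
    """
    df = signal.copy()
    df = df[df["mappable_bp"] > 0].reset_index(drop=True)
    if len(df) < 10:
        raise ValueError("need at least 10 mappable bins")
    per_bp = (df["rep1"] + df["rep2"]) / 2.0 / df["mappable_bp"]
    df["decile"] = pd.qcut(per_bp.rank(method="first"), 10, labels=range(1, 11))

    counts = np.zeros(len(df), dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for c in deletions:
        by_chrom.setdefault(c.sequence_name, []).append(c.position)
    for chrom, poss in by_chrom.items():
        poss_arr = np.sort(np.array(poss))
        sel = df["chrom"] == chrom
        for i in df.index[sel]:
            s, e = df.at[i, "start"], df.at[i, "end"]
            counts[i] = np.searchsorted(poss_arr, e) - np.searchsorted(poss_arr, s)
    df["count"] = counts

    rng = np.random.default_rng(seed)
    dec_groups = {
        d: df[df["decile"] == d][["count", "mappable_bp"]].to_numpy()
        for d in range(1, 11)
    }

    def rate(arr: np.ndarray) -> float:
        bp = arr[:, 1].sum()
        return arr[:, 0].sum() / bp if bp else float("nan")

    base = rate(dec_groups[1])
    results = []
    for d in range(1, 11):
        arr = dec_groups[d]
        r = rate(arr)
        if not np.isfinite(r) or not np.isfinite(base) or base == 0:
            results.append(
                DecileRate(d, int(arr[:, 0].sum()), int(arr[:, 1].sum()),
                           float("nan"), float("nan"), float("nan"), undefined=True)
            )
            continue
        boot = np.empty(bootstrap_B)
        arr1 = dec_groups[1]
        for b in range(bootstrap_B):
            rb = rate(arr[rng.integers(0, len(arr), size=len(arr))])
            b1 = rate(arr1[rng.integers(0, len(arr1), size=len(arr1))]) if d != 1 else rb
            boot[b] = rb / b1 if b1 else np.nan
        results.append(
            DecileRate(
                d,
                int(arr[:, 0].sum()),
                int(arr[:, 1].sum()),
                r / base,
                float(np.nanquantile(boot, 0.025)),
                float(np.nanquantile(boot, 0.975)),
            )
        )
    return results


# --------------------------------------------------------------------------
# individual filtering


def filter_individuals(
    per_individual_counts: dict[str, int],
    low_pct: float = 10.0,
    high_pct: float = 90.0,
) -> set[str]:
    """Drop individuals with totals strictly below the ``low_pct`` or strictly
    above the ``high_pct`` percentile (linear-interpolation percentiles)."""
    if len(per_individual_counts) < 10:
        raise ValueError("need at least 10 individuals")
    values = np.array(list(per_individual_counts.values()), dtype=float)
    lo = np.percentile(values, low_pct)
    hi = np.percentile(values, high_pct)
    return {k for k, v in per_individual_counts.items() if lo <= v <= hi}
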