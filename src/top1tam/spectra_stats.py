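"""Spectrum comparison statistics and sequence-logo construction.

Cosine similarity between category-count vectors, an empirical significance
test against a Dirichlet-multinomial null (flat concentration, trial counts
matched to the observed vectors), complete-linkage hierarchical clustering of
cosine distances with bootstrap clade support, and two-bit sequence logos of
canonicalized deletion contexts.

Canonicalization of a 2 bp deletion window follows two rules: the window is
reverse-complemented when the deleted dinucleotide contains an A, except for
the self-complementary AT and TA classes; and within its repeat/MH ambiguity
range the deletion is right-aligned to the most 3' T where one exists,
otherwise to the limit of the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .indel_classify import ClassifiedDeletion, SpectrumVector
from .sequence import equivalent_deletion_range, revcomp


# --------------------------------------------------------------------------
# cosine similarity and its null


def _as_array(v) -> np.ndarray:
    if isinstance(v, SpectrumVector):
        return v.counts
    return np.asarray(v, dtype=float)


def cosine_similarity(a, b) -> float:
    """cos(theta) = sum(a_i b_i) / (||a|| ||b||); scale-invariant."""
    x, y = _as_array(a), _as_array(b)
    if x.shape != y.shape:
        raise ValueError("vectors must share a scheme")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(x @ y / (nx * ny))


@dataclass
class DmNullConfig:
    n_categories: int
    trials_a: int
    trials_b: int
    n_pairs: int = 10_000
    seed: int = 0
    concentration: np.ndarray | None = None  # defaults to a vector of ones

    def __post_init__(self) -> None:
        if self.trials_a < 1 or self.trials_b < 1:
            raise ValueError("trial counts must be >= 1")
        if self.concentration is None:
            self.concentration = np.ones(self.n_categories)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if (self.concentration <= 0).any():
            raise ValueError("concentration must be strictly positive")


def _dm_sample(
    rng: np.random.Generator, n_pairs: int, trials: int, concentration: np.ndarray
) -> np.ndarray:
    """Dirichlet-multinomial counts, one vector per row."""
    p = rng.dirichlet(concentration, size=n_pairs)
    return rng.multinomial(trials, p)


def dm_cosine_pvalue(a, b, config: DmNullConfig | None = None) -> tuple[float, float]:
    """(observed cosine, empirical p) under the Dirichlet-multinomial null.

    The null draws ``n_pairs`` vector pairs with flat Dirichlet concentration
    and trial counts m1 = sum(a), m2 = sum(b); p is the smoothed exceedance
    fraction (k+1)/(n_pairs+1), never exactly zero.
    """
    x, y = _as_array(a), _as_array(b)
    obs = cosine_similarity(x, y)
    if config is None:
        config = DmNullConfig(
            n_categories=len(x),
            trials_a=max(1, int(round(x.sum()))),
            trials_b=max(1, int(round(y.sum()))),
        )
    if config.n_categories != len(x):
        raise ValueError("config.n_categories must match the scheme length")
    rng = np.random.default_rng(config.seed)
    va = _dm_sample(rng, config.n_pairs, config.trials_a, config.concentration)
    vb = _dm_sample(rng, config.n_pairs, config.trials_b, config.concentration)
    dots = np.einsum("ij,ij->i", va, vb).astype(float)
    norms = np.linalg.norm(va, axis=1) * np.linalg.norm(vb, axis=1)
    null = np.where(norms > 0, dots / np.where(norms > 0, norms, 1.0), 1.0)
    k = int((null >= obs - 1e-12).sum())
    return obs, (k + 1) / (config.n_pairs + 1)


# --------------------------------------------------------------------------
# hierarchical clustering with bootstrap support


@dataclass
class ClusterResult:
    labels: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset, float]  # clade (leaf-label set) -> support %
    newick: str


def _clades(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for i, (a, b, _dist, _cnt) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        clades.append(merged)
    return clades


def _newick(
    Z: np.ndarray, labels: list[str], supports: dict[frozenset, float]
) -> str:
    n = len(labels)
    members = _clades(Z, labels)

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        a, b, dist, _ = Z[node - n]
        clade = members[node - n]
        sup = supports.get(clade)
        tag = f"{sup:.0f}" if sup is not None else ""
        return f"({render(int(a))},{render(int(b))}){tag}:{dist:.6g}"

    return render(n + len(Z) - 1) + ";"


def cluster_spectra(
    spectra: list[SpectrumVector],
    B: int = 1000,
    seed: int = 0,
    labels: list[str] | None = None,
) -> ClusterResult:
    """Complete-linkage clustering of pairwise cosine distances (1 - cosine)
    with bootstrap clade support.

    Replicates resample each spectrum's mutations with replacement (a
    multinomial redraw at the observed proportions), recluster, and a join is
    supported when its exact leaf set reappears as a clade in the replicate.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 spectra")
    scheme = spectra[0].labels
    for s in spectra:
        if s.labels != scheme:
            raise ValueError("spectra use different schemes")
    if labels is None:
        labels = [f"s{i}" for i in range(len(spectra))]
    X = np.array([s.counts for s in spectra], dtype=float)
    Z = linkage(pdist(X, metric="cosine"), method="complete")
    clades = _clades(Z, labels)

    rng = np.random.default_rng(seed)
    hits = dict.fromkeys(clades, 0)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every spectrum needs at least one mutation")
    probs = X / totals[:, None]
    for _ in range(B):
        Xb = np.array(
            [rng.multinomial(int(round(t)), p) for t, p in zip(totals, probs)],
            dtype=float,
        )
        Zb = linkage(pdist(Xb, metric="cosine"), method="complete")
        replicate = set(_clades(Zb, labels))
        for clade in hits:
            if clade in replicate:
                hits[clade] += 1
    supports = {clade: 100.0 * h / B for clade, h in hits.items()}
    return ClusterResult(
        labels=labels,
        linkage_matrix=Z,
        supports=supports,
        newick=_newick(Z, labels, supports),
    )


# --------------------------------------------------------------------------
# canonicalized context windows and logos


def canonicalize_context(
    sequences: dict[str, str],
    classified: ClassifiedDeletion,
    flank: int = 10,
) -> tuple[str, bool]:
    """Oriented, right-aligned window around a 2 bp deletion.

    Returns (window, padded) where the window spans ``flank`` bases either
    side of the deleted dinucleotide (window length = 2*flank + 2) and
    ``padded`` marks N-padding at a sequence end.  The strand rule inspects
    the deleted pair (register-independent: register shifts swap the two
    bases, preserving base content).
    """
    call = classified.call
    if call.length != 2:
        raise ValueError("canonicalization is defined for 2 bp deletions")
    seq = sequences[call.sequence_name]
    pos = call.position
    di = seq[pos : pos + 2]
    flip = "A" in di and di not in ("AT", "TA")
    if flip:
        work = revcomp(seq)
        pos = len(seq) - (pos + 2)
    else:
        work = seq
    left, right = equivalent_deletion_range(work, pos, 2)
    p = _logo_register(work, left, right)
    lo, hi = p - flank, p + 2 + flank
    window = work[max(0, lo) : min(len(work), hi)]
    pad_l, pad_r = max(0, -lo), max(0, hi - len(work))
    return "N" * pad_l + window + "N" * pad_r, bool(pad_l or pad_r)


def _logo_register(seq: str, left: int, right: int) -> int:
    for p in range(right, left - 1, -1):
        if seq[p + 1] == "T":
            return p
    for p in range(right, left - 1, -1):
        if seq[p] == "T":
            return p
    return right


@dataclass
class LogoMatrix:
    """Positions x {A,C,G,T} matrix of scaled information content (bits)."""

    matrix: pd.DataFrame
    n_sequences: int

    @property
    def column_bits(self) -> pd.Series:
        return self.matrix.sum(axis=1)


def build_logo(windows: list[str]) -> LogoMatrix:
    """Two-bit information-content matrix from equal-length windows.

    Per column, information = 2 + sum_b f_b log2 f_b over non-N bases; each
    cell is f_b x information.  No small-sample correction is applied.
    """
    if not windows:
        raise ValueError("no windows supplied")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must have equal length")
    rows = []
    for i in range(width):
        col = [w[i] for w in windows if w[i] in "ACGT"]
        freqs = np.array([col.count(b) for b in "ACGT"], dtype=float)
        total = freqs.sum()
        if total == 0:
            rows.append(np.zeros(4))
            continue
        f = freqs / total
        nz = f[f > 0]
        info = 2.0 + float((nz * np.log2(nz)).sum())
        rows.append(f * info)
    matrix = pd.DataFrame(rows, columns=list("ACGT"))
    return LogoMatrix(matrix=matrix, n_sequences=len(windows))
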