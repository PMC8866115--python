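"""Expression grouping, stratum rates, HETR calling and decile curves."""

import numpy as np
import pandas as pd
import pytest

from top1tam.indel_classify import IndelCall
from top1tam.synthetic_data import (
    generate_genome,
    plant_deletions,
    simulate_expression_dataset,
    simulate_signal_track,
)
from top1tam.transcription_strata import (
    TissueExpressionSummary,
    assign_expression_groups,
    filter_individuals,
    hetr_enrichment,
    hetr_genes,
    resolve_overlapping_genes,
    signal_decile_rates,
    stratum_rates,
)


def _tpm(rows: dict[str, list[float]], samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    return df


class TestExpressionGroups:
    def test_housekeeping_threshold_is_strict_tenfold(self):
        rows = {f"g{i}": [10.0, 10.0, 10.0] for i in range(12)}
        rows["hk"] = [10.0, 10.0, 89.0]  # max 8.9x median: housekeeping-like
        rows["spiky"] = [10.0, 10.0, 111.0]  # max 11.1x median: excluded
        groups = assign_expression_groups(_tpm(rows), "housekeeping-deciles")
        assert "hk" in groups and "spiky" not in groups

    def test_germline_collapse_membership(self):
        groups = assign_expression_groups(
            {f"g{i}": i for i in range(1, 10)}, "germline-4"
        )
        assert groups["g1"] == "unexpressed"
        assert {groups[f"g{i}"] for i in (2, 3, 4)} == {"low"}
        assert {groups[f"g{i}"] for i in (5, 6, 7)} == {"mid"}
        assert {groups[f"g{i}"] for i in (8, 9)} == {"high"}

    def test_overlap_resolution_keeps_highest_median_then_mean(self):
        tpm = _tpm(
            {"a": [5.0, 5.0], "b": [9.0, 9.0], "c": [9.0, 11.0], "d": [1.0, 1.0]}
        )
        spans = {"a": (0, 100), "b": (50, 150), "c": (120, 220), "d": (300, 400)}
        kept = resolve_overlapping_genes(tpm, spans)
        # c (median 9? -> median 10) beats b; b overlaps c and a
        med = tpm.median(axis=1)
        assert med["c"] > med["b"]
        assert set(kept) == {"c", "d", "a"}

    def test_decile_partition_near_equal(self):
        tpm = _tpm({f"g{i}": [float(i + 1)] for i in range(100)})
        groups = assign_expression_groups(tpm, "deciles")
        sizes = pd.Series(groups).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            assign_expression_groups(_tpm({f"g{i}": [0.0] for i in range(12)}), "deciles")


class TestStratumRates:
    def test_printed_formula_arithmetic(self):
        """c=10, g=1e6, n=5 gives rate 2e-6 per bp per genome."""
        spans = {"g0": (0, 1_000_000)}
        groups = {"g0": "high"}
        indels = [IndelCall("chr1", 1000 * i, "AC", "") for i in range(10)]
        rates = stratum_rates(indels, spans, groups, n_genomes=5, bootstrap_B=10)
        assert rates[0].rate == pytest.approx(10 / (1e6 * 5))

    def test_zero_indels_zero_ci(self):
        spans = {"g0": (0, 1000), "g1": (2000, 3000)}
        groups = {"g0": "x", "g1": "x"}
        (r,) = stratum_rates([], spans, groups, n_genomes=3)
        assert r.rate == 0.0 and (r.ci_low, r.ci_high) == (0.0, 0.0)

    def test_count_conservation_across_groups(self):
        spans = {f"g{i}": (i * 100, i * 100 + 100) for i in range(10)}
        groups = {f"g{i}": "lo" if i < 5 else "hi" for i in range(10)}
        indels = [IndelCall("chr1", p, "AC", "") for p in range(0, 1000, 37)]
        rates = stratum_rates(indels, spans, groups, n_genomes=1, bootstrap_B=5)
        in_span = sum(
            any(s <= c.position < e for s, e in spans.values()) for c in indels
        )
        assert sum(r.count for r in rates) == in_span

    def test_coupled_dataset_recovers_monotone_deciles(self):
        ds, planted = simulate_expression_dataset(
            n_genes=500, coupling=1.0, seed=31, deletions_per_gene_baseline=6.0
        )
        groups = assign_expression_groups(ds.tpm, "deciles", gene_spans=ds.gene_spans)
        rates = stratum_rates(
            planted.deletions, ds.gene_spans, groups, ds.n_individuals, seed=1
        )
        by_decile = {int(r.stratum): r for r in rates}
        vals = [by_decile[d].rate for d in range(1, 11)]
        rho = pd.Series(vals).corr(pd.Series(range(10)), method="spearman")
        assert rho > 0.9
        assert by_decile[10].ci_low > by_decile[1].rate


class TestHetr:
    def test_truth_recovery(self):
        ds, _ = simulate_expression_dataset(n_genes=200, hetr_fraction=0.1, seed=21)
        summary = TissueExpressionSummary.from_expression(ds.tpm, ds.tissue_labels)
        recovered = {
            (g, t) for t in summary.within_median.columns for g in hetr_genes(summary, t)
        }
        assert recovered == set(ds.truth_hetr.items())

    def test_ubiquitously_high_gene_excluded(self):
        samples = ["t1_a", "t1_b", "t2_a", "t2_b"]
        rows = {f"g{i}": [1.0] * 4 for i in range(20)}
        rows["ubiq"] = [500.0] * 4
        tpm = _tpm(rows, samples)
        labels = {s: s.split("_")[0] for s in samples}
        summary = TissueExpressionSummary.from_expression(tpm, labels)
        assert "ubiq" not in hetr_genes(summary, "t1")

    def test_empty_result_is_not_an_error(self):
        samples = ["t1_a", "t2_a"]
        tpm = _tpm({f"g{i}": [1.0, 1.0] for i in range(20)}, samples)
        labels = {"t1_a": "t1", "t2_a": "t2"}
        summary = TissueExpressionSummary.from_expression(tpm, labels)
        assert hetr_genes(summary, "t1") == set()

    def test_single_tissue_rejected(self):
        tpm = _tpm({"g0": [1.0, 2.0]}, ["a", "b"])
        with pytest.raises(ValueError, match="tissue"):
            TissueExpressionSummary.from_expression(tpm, {"a": "t1", "b": "t1"})


class TestHetrEnrichment:
    def _setup(self, rng):
        spans = {f"g{i}": (i * 1000, i * 1000 + 900) for i in range(40)}
        hetr_sets = {"liver": {f"g{i}" for i in range(8)}}

        def dels(weights):
            calls = []
            genes = list(spans)
            for _ in range(600):
                g = genes[rng.choice(len(genes), p=weights)]
                s, e = spans[g]
                calls.append(IndelCall("chr1", int(rng.integers(s, e)), "AC", ""))
            return calls

        return spans, hetr_sets, dels

    def test_planted_tissue_bias_detected(self, rng):
        spans, hetr_sets, dels = self._setup(rng)
        w_biased = np.array([5.0] * 8 + [1.0] * 32)
        w_flat = np.ones(40)
        by_cancer = {
            "HCC": dels(w_biased / w_biased.sum()),
            "other1": dels(w_flat / 40),
            "other2": dels(w_flat / 40),
        }
        results = hetr_enrichment(by_cancer, hetr_sets, spans)
        hcc = next(r for r in results if r.cancer == "HCC")
        assert hcc.odds_ratio > 1 and hcc.q_value < 0.01

    def test_exchangeable_cancers_near_unit_odds(self, rng):
        spans, hetr_sets, dels = self._setup(rng)
        w = np.ones(40) / 40
        by_cancer = {f"c{i}": dels(w) for i in range(3)}
        results = hetr_enrichment(by_cancer, hetr_sets, spans)
        assert all(r.q_value > 0.05 for r in results)

    def test_depletion_display_reciprocal(self, rng):
        spans, hetr_sets, dels = self._setup(rng)
        w_depleted = np.array([0.1] * 8 + [1.0] * 32)
        w_flat = np.ones(40)
        by_cancer = {
            "dep": dels(w_depleted / w_depleted.sum()),
            "o1": dels(w_flat / 40),
            "o2": dels(w_flat / 40),
        }
        results = hetr_enrichment(by_cancer, hetr_sets, spans)
        dep = next(r for r in results if r.cancer == "dep")
        assert dep.odds_ratio < 1
        assert dep.display_value == pytest.approx(1.0 / dep.odds_ratio)


class TestSignalDeciles:
    def test_first_decile_is_unity_and_flat_without_coupling(self):
        genome = generate_genome(60_000, seed=41)
        planted = plant_deletions(
            genome, 6000, tnt_bias=0.0, length_distribution={2: 1.0}, seed=42
        )
        track = simulate_signal_track(genome, planted, coupling=0.0, seed=43)
        rates = signal_decile_rates(track, planted.deletions, bootstrap_B=200, seed=44)
        assert rates[0].relative_rate == 1.0
        assert all(0.85 < r.relative_rate < 1.15 for r in rates)
        inside = [r for r in rates[1:] if r.ci_low <= 1.0 <= r.ci_high]
        assert len(inside) >= 7  # flat curve: CIs cover 1 nearly everywhere

    def test_strong_coupling_detected_in_top_decile(self):
        genome = generate_genome(60_000, seed=45)
        planted = plant_deletions(genome, 1500, tnt_bias=0.0, seed=46)
        track = simulate_signal_track(
            genome, planted, coupling=400.0, seed=47, noise_scale=0.5
        )
        rates = signal_decile_rates(track, planted.deletions, bootstrap_B=200, seed=48)
        assert rates[-1].relative_rate > 1.0
        assert rates[-1].ci_low > 1.0


class TestFilterIndividuals:
    def test_uniform_counts_all_retained(self):
        counts = {f"i{k}": 7 for k in range(20)}
        assert filter_individuals(counts) == set(counts)

    def test_matches_percentile_oracle(self):
        counts = {f"i{k}": k + 1 for k in range(100)}
        kept = filter_individuals(counts)
        vals = np.array(list(counts.values()), dtype=float)
        lo, hi = np.percentile(vals, [10, 90])
        expected = {k for k, v in counts.items() if lo <= v <= hi}
        assert kept == expected

    def test_stable_under_fixed_thresholds(self):
        """Re-applying the filter with the original percentile bounds keeps
        the retained set unchanged (thresholds recomputed on the filtered set
        would tighten, so stability holds per fixed bounds, not per call)."""
        counts = {
            f"i{k}": int(v)
            for k, v in enumerate(np.random.default_rng(1).integers(0, 50, 40))
        }
        vals = np.array(list(counts.values()), dtype=float)
        lo, hi = np.percentile(vals, [10, 90])
        once = filter_individuals(counts)
        assert once == {k for k, v in counts.items() if lo <= v <= hi}
        assert {k for k in once if lo <= counts[k] <= hi} == once
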