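"""Synthetic-data generator: determinism, placement, planted-effect recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from h3k4pipe.genome import GenomeLayout
from h3k4pipe.islands import bin_tags
from h3k4pipe.simulate import (
    SimulationTruth,
    make_truth,
    simulate_genome,
    simulate_qpcr,
    simulate_tags,
)


def _promoter_density(ts, gene):
    mids = ts.midpoints().get(gene.chrom, np.array([]))
    s, e = gene.promoter(1000)
    n = np.searchsorted(mids, e) - np.searchsorted(mids, s)
    return n / (e - s)


class TestSimulateGenome:
    def test_zero_genes_degenerate(self):
        layout, genes, seqs = simulate_genome(1, 1_000_000, 0, seed=7)
        assert layout.chrom_names == ("chr1",)
        assert layout.chrom_lengths == (1_000_000,)
        assert genes == []
        assert len(seqs["chr1"]) == 1_000_000

    def test_deterministic_given_seed(self):
        a = simulate_genome(2, 200_000, 40, seed=1)
        b = simulate_genome(2, 200_000, 40, seed=1)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]
        c = simulate_genome(2, 200_000, 40, seed=2)
        assert c[2] != a[2]

    def test_gene_spans_non_overlapping_brute_force(self):
        _, genes, _ = simulate_genome(1, 1_000_000, 50, seed=3)
        assert len(genes) == 50
        for i, g in enumerate(genes):
            for h in genes[i + 1 :]:
                if g.chrom != h.chrom:
                    continue
                assert g.span_end <= h.span_start or h.span_end <= g.span_start

    def test_exons_sorted_within_span(self):
        _, genes, _ = simulate_genome(1, 500_000, 30, seed=5)
        for g in genes:
            prev = g.span_start
            for a, b in g.exons:
                assert g.span_start <= a < b <= g.span_end
                assert a >= prev
                prev = b

    def test_placement_failure_raises(self):
        with pytest.raises(RuntimeError, match="could not place"):
            simulate_genome(1, 30_000, 50, seed=1, gene_length_range=(2000, 3000))


class TestSimulateTags:
    def test_conservation_and_bounds(self, small_layout):
        _, genes, _ = simulate_genome(1, 1_000_000, 20, seed=2)
        truth = make_truth(genes, seed=2, n_enriched=10, base_fold=8.0)
        samples = simulate_tags(small_layout, genes, truth, 2, depth=20_000)
        assert len(samples) == 4
        for ts in samples:
            cov = bin_tags(ts, small_layout)
            assert sum(int(c.sum()) for c in cov.counts.values()) == ts.total_count
            lens = (ts.fragments["end"] - ts.fragments["start"]).to_numpy()
            assert lens.min() >= 150 and lens.max() <= 250

    def test_deterministic_and_order_independent(self, small_layout):
        _, genes, _ = simulate_genome(1, 1_000_000, 10, seed=4)
        truth = make_truth(genes, seed=9, n_enriched=5)
        a = simulate_tags(small_layout, genes, truth, 2, depth=5_000)
        b = simulate_tags(small_layout, genes, truth, 2, depth=5_000)
        for x, y in zip(a, b):
            assert x.fragments.equals(y.fragments)

    def test_null_is_homogeneous_poisson(self, small_layout):
        """No planted enrichment: binned counts pass a chi-square GOF test."""
        truth = SimulationTruth({}, set(), [], 0.0, seed=11)
        (ts,) = simulate_tags(small_layout, [], truth, 1, depth=200_000,
                              groups=("A",))
        counts = bin_tags(ts, small_layout, bin_size=100).counts["chr1"]
        assert len(counts) == 10_000
        lam = counts.mean()
        # pool the Poisson tail bins so expected counts stay > 5
        kmax = int(stats.poisson.isf(5 / len(counts), lam))
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax + 1), lam) * len(counts)
        exp[-1] = stats.poisson.sf(kmax - 1, lam) * len(counts)
        keep = exp > 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 2)  # mean estimated from data
        assert p > 0.001

    def test_promoter_enrichment_factor_ten(self, small_layout):
        """Factor 10 in both groups: promoter density >= 5x background
        averaged over 20 replicate simulations."""
        _, genes, _ = simulate_genome(1, 1_000_000, 10, seed=6)
        gene = genes[0]
        ratios = []
        for seed in range(20):
            truth = SimulationTruth(
                {gene.gene_id: {"A": 10.0, "B": 10.0}}, set(), [], 0.0, seed
            )
            (ts,) = simulate_tags(small_layout, genes, truth, 1, depth=20_000,
                                  groups=("A",))
            bg = ts.total_count / small_layout.total_length
            ratios.append(_promoter_density(ts, gene) / bg)
        assert np.mean(ratios) >= 5.0

    def test_group_fold_ratio_envelope(self, small_layout):
        """A=5 vs B=1 at one gene: A/B promoter density ratio near 5."""
        _, genes, _ = simulate_genome(1, 1_000_000, 10, seed=8)
        gene = genes[0]
        ratios = []
        for seed in range(20):
            truth = SimulationTruth(
                {gene.gene_id: {"A": 5.0, "B": 1.0}}, set(), [], 0.0, seed
            )
            a, b = simulate_tags(small_layout, genes, truth, 1, depth=200_000)
            ratios.append(_promoter_density(a, gene) / _promoter_density(b, gene))
        assert 3.5 <= np.mean(ratios) <= 6.5

    def test_fold_validation(self, small_layout):
        _, genes, _ = simulate_genome(1, 1_000_000, 2, seed=1)
        truth = SimulationTruth(
            {genes[0].gene_id: {"A": 0.5, "B": 1.0}}, set(), [], 0.0, 1
        )
        with pytest.raises(ValueError, match=">= 1"):
            simulate_tags(small_layout, genes, truth, 1, depth=1000)


class TestMakeTruth:
    def test_differential_subset_and_folds(self):
        _, genes, _ = simulate_genome(1, 500_000, 40, seed=3)
        truth = make_truth(genes, 5, n_enriched=20, n_diff_up=4, n_diff_down=3,
                           diff_fold=3.0, spotlight_fold=2.3, n_weak=5)
        assert len(truth.enriched_genes) == 20
        assert len(truth.differential_genes) == 7
        assert truth.differential_genes <= set(truth.enriched_genes)
        ratios = sorted(
            round(f["B"] / f["A"], 6)
            for g, f in truth.enriched_genes.items()
            if g in truth.differential_genes
        )
        assert ratios == [round(1 / 3, 6)] * 3 + [3.0] * 4


class TestSimulateQpcr:
    def test_table_shape(self):
        df = simulate_qpcr(timepoints=(0, 6, 24, 48, 72, 96), replicates=3, seed=0)
        for (ab, tgt), sub in df.groupby(["antibody", "target"]):
            assert len(sub) == 18  # 3 replicates x 6 timepoints

    def test_no_decay_limit(self):
        hl = {"H3K4me3": math.inf}
        bf = {"H3K4me3": 100.0}
        df = simulate_qpcr(timepoints=(0, 96), replicates=6, seed=3,
                           halflife=hl, baseline_fold=bf)
        from h3k4pipe.qpcr import enrichment_table

        enr = enrichment_table(df)
        gapdh = enr[enr["target"] == "GAPDH"]
        m0 = gapdh[gapdh["timepoint_h"] == 0]["fold_over_negative"].mean()
        m96 = gapdh[gapdh["timepoint_h"] == 96]["fold_over_negative"].mean()
        assert abs(math.log2(m96 / m0)) < 0.5  # equal within Ct noise

    def test_halflife_closed_form(self):
        """24 h half-life: enrichment at 48 h is one quarter of 0 h."""
        hl = {"H3K4me3": 24.0}
        bf = {"H3K4me3": 200.0}
        folds = []
        for seed in range(10):
            df = simulate_qpcr(timepoints=(0, 48), replicates=3, seed=seed,
                               halflife=hl, baseline_fold=bf)
            from h3k4pipe.qpcr import enrichment_table

            enr = enrichment_table(df)
            g = enr[enr["target"] == "GAPDH"]
            folds.append(
                g[g["timepoint_h"] == 48]["fold_over_negative"].mean()
                / g[g["timepoint_h"] == 0]["fold_over_negative"].mean()
            )
        mean, se = np.mean(folds), np.std(folds, ddof=1) / math.sqrt(len(folds))
        assert abs(mean - 0.25) <= max(2 * se, 0.02)

    def test_replicate_validation(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_qpcr(replicates=1)
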