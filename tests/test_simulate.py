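"""Generator checks: EMS spectrum, Haldane meiosis, Mendelian segregation,
bulk selection, pooled read sampling, and whole-dataset determinism."""

import io

import numpy as np
import pytest
from scipy import stats

from mutmapkit.genome import (
    Chromosome,
    EmsSpectrum,
    GenomeModel,
    SimulationConfig,
    default_config,
    default_spectrum,
)
from mutmapkit.simulate import (
    MUT_SAMPLE,
    POOL_SAMPLE,
    WT_SAMPLE,
    draw_ems_variants,
    sample_pool_reads,
    select_mutant_bulk,
    simulate_dataset,
    simulate_f2_population,
    simulate_gamete,
)
from mutmapkit.variants import select_markers
from mutmapkit.vcfio import write_vcf


def haldane_r(d):
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def two_chrom_genome(len_bp=10**7, morgans=1.0):
    return GenomeModel(
        (Chromosome("c1", len_bp, morgans), Chromosome("c2", len_bp, morgans))
    )


class TestDrawEmsVariants:
    def test_single_variant_is_the_causal_locus(self, genome, rng):
        out = draw_ems_variants(genome, 1, default_spectrum(), ("chr4", 195_678_521), rng)
        assert len(out) == 1
        assert out[0].is_causal and (out[0].chrom, out[0].pos) == ("chr4", 195_678_521)

    def test_transition_fraction_matches_spectrum(self, genome, rng):
        n = 5654
        out = draw_ems_variants(genome, n, default_spectrum(), ("chr4", 195_678_521), rng)
        k = sum(1 for m in out if m.variant_class in ("G>A", "C>T"))
        p = (2730 + 2465) / 5654
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= k <= hi  # realized transitions ~91.9% of sites

    def test_positions_split_binomially_between_equal_chromosomes(self, rng):
        g = two_chrom_genome()
        out = draw_ems_variants(g, 1000, default_spectrum(), None, rng)
        n1 = sum(1 for m in out if m.chrom == "c1")
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= n1 <= hi

    def test_positions_unique_within_chromosome(self, genome, rng):
        out = draw_ems_variants(genome, 3000, default_spectrum(), None, rng)
        keys = [(m.chrom, m.pos) for m in out]
        assert len(set(keys)) == len(keys)
        assert all(1 <= m.pos for m in out)

    def test_causal_outside_genome_rejected(self, genome, rng):
        with pytest.raises(ValueError):
            draw_ems_variants(genome, 10, default_spectrum(), ("chrZ", 1), rng)

    def test_capacity_error(self, rng):
        tiny = GenomeModel((Chromosome("c1", 5, 0.0),))
        with pytest.raises(ValueError):
            draw_ems_variants(tiny, 6, default_spectrum(), None, rng)


class TestGameteModel:
    def test_zero_genetic_length_gives_single_block(self, rng):
        g = simulate_gamete(0.0, rng)
        assert g.crossovers.size == 0
        assert set(np.unique(g.origin_at([0.0, 0.0, 0.0]))) <= {0, 1}

    def test_negative_length_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_gamete(-0.1, rng)

    @pytest.mark.parametrize("d", [0.05, 0.2, 0.5])
    def test_recombination_fraction_matches_haldane_closed_form(self, d, rng):
        n = 100_000
        rec = 0
        for _ in range(n):
            g = simulate_gamete(d, rng)
            o = g.origin_at([0.0, d])
            rec += o[0] != o[1]
        assert rec / n == pytest.approx(haldane_r(d), abs=0.005)

    def test_distant_loci_recombine_freely(self, rng):
        n = 20_000
        rec = sum(
            np.diff(simulate_gamete(30.0, rng).origin_at([0.0, 30.0]))[0] != 0
            for _ in range(n)
        )
        assert rec / n == pytest.approx(0.5, abs=0.02)


class TestF2Population:
    def _markers(self, genome, positions):
        spec = EmsSpectrum({"G>A": 1.0})
        out = []
        for chrom, pos in positions:
            out.extend(
                m for m in draw_ems_variants(genome, 1, spec, (chrom, pos), 7)
            )
        return out

    def test_single_marker_segregates_1_2_1(self):
        g = GenomeModel((Chromosome("c1", 10**6, 0.5),))
        cfg = SimulationConfig(genome=g, n_variants=1, causal=("c1", 500_000),
                               n_f2=100_000, pool_size=10)
        markers = self._markers(g, [("c1", 500_000)])
        geno = simulate_f2_population(cfg, markers, np.random.default_rng(5))
        freq = np.bincount(geno[:, 0], minlength=3) / cfg.n_f2
        assert freq == pytest.approx([0.25, 0.5, 0.25], abs=0.01)
        chi2 = ((np.bincount(geno[:, 0]) - cfg.n_f2 * np.array([0.25, 0.5, 0.25])) ** 2
                / (cfg.n_f2 * np.array([0.25, 0.5, 0.25]))).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_zero_genetic_distance_is_complete_linkage(self):
        g = GenomeModel((Chromosome("c1", 10**6, 0.0),))
        cfg = SimulationConfig(genome=g, n_variants=2, causal=("c1", 100),
                               n_f2=5000, pool_size=10)
        markers = self._markers(g, [("c1", 100)]) + self._markers(g, [("c1", 900_000)])
        geno = simulate_f2_population(cfg, markers, np.random.default_rng(6))
        assert (geno[:, 0] == geno[:, 1]).all()

    def test_markers_on_different_chromosomes_are_independent(self):
        g = two_chrom_genome(morgans=1.0)
        cfg = SimulationConfig(genome=g, n_variants=2, causal=("c1", 5000),
                               n_f2=100_000, pool_size=10)
        markers = self._markers(g, [("c1", 5000)]) + self._markers(g, [("c2", 5000)])
        geno = simulate_f2_population(cfg, markers, np.random.default_rng(7))
        # F2 dosage correlation between loci equals 1 - 2r
        corr = np.corrcoef(geno[:, 0], geno[:, 1])[0, 1]
        r = (1 - corr) / 2
        assert r == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("d", [0.01, 0.1, 0.5, 1.0])
    def test_marker_pair_recombination_matches_haldane(self, d):
        """Haldane consistency of the population sampler at marker resolution."""
        g = GenomeModel((Chromosome("c1", 10**6, max(d, 1e-9)),))
        cfg = SimulationConfig(genome=g, n_variants=2, causal=("c1", 1),
                               n_f2=50_000, pool_size=10)
        markers = self._markers(g, [("c1", 1)]) + self._markers(g, [("c1", 10**6)])
        geno = simulate_f2_population(cfg, markers, np.random.default_rng(int(d * 100)))
        # F2 dosage correlation between loci equals 1 - 2r
        corr = np.corrcoef(geno[:, 0], geno[:, 1])[0, 1]
        r_emp = (1 - corr) / 2
        r_true = haldane_r(d)
        se_r = (1 - corr**2) / np.sqrt(cfg.n_f2) / 2  # delta method
        assert abs(r_emp - r_true) < 3 * max(se_r, 1e-3)


class TestBulkSelection:
    def _two_locus_setup(self, r, n=120_000, seed=8):
        d = -0.5 * np.log(1 - 2 * r) if r < 0.5 else 30.0
        g = GenomeModel((Chromosome("c1", 10**6, max(d, 1e-12)),))
        cfg = SimulationConfig(genome=g, n_variants=2, causal=("c1", 1),
                               n_f2=n, pool_size=n)
        spec = EmsSpectrum({"G>A": 1.0})
        markers = draw_ems_variants(g, 1, spec, ("c1", 1), 1) + draw_ems_variants(
            g, 1, spec, ("c1", 10**6), 2
        )
        geno = simulate_f2_population(cfg, markers, np.random.default_rng(seed))
        return geno

    @staticmethod
    def brute_force_linked_freq(r):
        """Expected mutant-allele frequency at a marker in aa-selected
        individuals, by enumerating the 4x4 two-locus gamete combinations."""
        # gamete haplotypes (causal, marker): probabilities under Haldane r
        haplos = {(1, 1): (1 - r) / 2, (1, 0): r / 2, (0, 1): r / 2, (0, 0): (1 - r) / 2}
        num = den = 0.0
        for (c1, m1), p1 in haplos.items():
            for (c2, m2), p2 in haplos.items():
                if c1 == 1 and c2 == 1:  # recessive (aa) at the causal locus
                    den += p1 * p2
                    num += p1 * p2 * (m1 + m2) / 2
        return num / den

    def test_brute_force_oracle_equals_one_minus_r(self):
        for r in (0.0, 0.1, 0.25, 0.5):
            assert self.brute_force_linked_freq(r) == pytest.approx(1 - r, abs=1e-12)

    def test_perfect_selection_fixes_causal_allele(self):
        geno = self._two_locus_setup(0.2)
        bulk = select_mutant_bulk(geno, 0, 200, 0.0, np.random.default_rng(0))
        assert (geno[bulk, 0] == 2).all()
        assert geno[bulk, 0].mean() / 2 == 1.0

    @pytest.mark.parametrize("r", [0.1, 0.3])
    def test_linked_marker_frequency_matches_enumeration(self, r):
        geno = self._two_locus_setup(r)
        bulk = select_mutant_bulk(geno, 0, geno.shape[0], 0.0, np.random.default_rng(1))
        f = geno[bulk, 1].mean() / 2
        expected = self.brute_force_linked_freq(r)
        se = np.sqrt(0.5 / (2 * bulk.size))  # conservative binomial-scale SE
        assert f == pytest.approx(expected, abs=4 * se)

    def test_unlinked_marker_frequency_is_half(self):
        geno = self._two_locus_setup(0.5)
        bulk = select_mutant_bulk(geno, 0, geno.shape[0], 0.0, np.random.default_rng(2))
        assert geno[bulk, 1].mean() / 2 == pytest.approx(0.5, abs=0.01)

    def test_phenotyping_errors_admit_non_mutants(self):
        geno = self._two_locus_setup(0.2, n=20_000)
        bulk = select_mutant_bulk(geno, 0, 2000, 0.3, np.random.default_rng(3))
        frac_err = (geno[bulk, 0] != 2).mean()
        assert frac_err == pytest.approx(0.3, abs=0.04)

    def test_empty_bulk_raises(self):
        geno = np.zeros((10, 1), dtype=np.int8)
        with pytest.raises(ValueError, match="recessive"):
            select_mutant_bulk(geno, 0, 5, 0.0, np.random.default_rng(0))

    def test_null_bulk_is_uniform_sample(self):
        geno = self._two_locus_setup(0.2, n=1000)
        bulk = select_mutant_bulk(geno, None, 200, 0.0, np.random.default_rng(4))
        assert bulk.size == 200 and len(set(bulk.tolist())) == 200


class TestPooledReads:
    def test_pure_alt_no_error_gives_all_alt_reads(self, rng):
        ref, alt = sample_pool_reads(np.ones(50), 60, 0.0, rng)
        assert (ref == 0).all()
        assert alt.mean() == pytest.approx(60, abs=5)

    def test_mean_index_at_half_frequency(self, rng):
        ref, alt = sample_pool_reads(np.full(10_000, 0.5), 60, 0.0, rng)
        keep = ref + alt > 0
        idx = alt[keep] / (ref + alt)[keep]
        assert idx.mean() == pytest.approx(0.5, abs=0.005)

    def test_sequencing_error_pulls_index_from_one(self, rng):
        ref, alt = sample_pool_reads(np.ones(10_000), 60, 0.01, rng)
        keep = ref + alt > 0
        idx = alt[keep] / (ref + alt)[keep]
        assert idx.mean() == pytest.approx(0.99, abs=0.005)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_pool_reads(np.array([1.5]), 60, 0.0, rng)
        with pytest.raises(ValueError):
            sample_pool_reads(np.array([0.5]), 0.0, 0.0, rng)


class TestWholeDataset:
    def test_identical_config_gives_byte_identical_vcf(self, small_config, tmp_path):
        paths = []
        for name in ("a.vcf", "b.vcf"):
            ds = simulate_dataset(small_config)
            p = tmp_path / name
            write_vcf(ds.records, [WT_SAMPLE, MUT_SAMPLE, POOL_SAMPLE], str(p),
                      genome=small_config.genome)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_marker_recovery_above_95_percent_without_sequencing_error(self):
        cfg = default_config(n_variants=2000, n_f2=400, pool_size=100,
                             sequencing_error_rate=0.0, seed=21)
        ds = simulate_dataset(cfg)
        markers = select_markers(ds.records, MUT_SAMPLE, WT_SAMPLE)
        # losses only from Poisson low-depth sites in a parent
        assert len(markers) / len(ds.records) >= 0.95

    def test_causal_can_be_dropped_from_marker_set(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, causal_in_markers=False)
        ds = simulate_dataset(cfg)
        assert ds.causal_record is None
        assert len(ds.records) == cfg.n_variants - 1

    def test_truth_table_carries_bulk_frequency_of_one_at_causal(self, small_dataset):
        causal = [t for t in small_dataset.truth if t["is_causal"]]
        assert len(causal) == 1
        assert causal[0]["true_bulk_allele_freq"] == 1.0
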