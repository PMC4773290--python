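"""Simulator: LD control, phenotype model, annotations, BAF generator, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regulocal as rl
from regulocal.io import read_bed, read_vcf
from regulocal.simulate import InvalidSpecError


def spec(**kw):
    defaults = dict(n_variants=12, block_lengths=(6, 6), n_founders=2,
                    recomb_prob=0.0, mutation_prob=0.0, seed=5)
    defaults.update(kw)
    return rl.LocusSpec(**defaults)


class TestHaplotypes:
    def test_single_founder_degenerate_copy(self):
        haps = rl.simulate_haplotypes(spec(n_founders=1), n_samples=20)
        assert np.all(haps == haps[0])

    def test_two_founders_perfect_within_block_ld(self):
        haps = rl.simulate_haplotypes(spec(), n_samples=200)
        g = haps[0::2] + haps[1::2]
        block = g[:, :6]
        seg = [j for j in range(6) if np.ptp(block[:, j]) > 0]
        for a in seg:
            for b in seg:
                assert rl.r2(block[:, a], block[:, b]) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        s = spec(mutation_prob=0.02, recomb_prob=0.3, seed=7)
        h1 = rl.simulate_haplotypes(s, n_samples=50)
        h2 = rl.simulate_haplotypes(s, n_samples=50)
        assert np.array_equal(h1, h2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            spec(n_founders=0)
        with pytest.raises(InvalidSpecError):
            spec(block_lengths=(6, 5))
        with pytest.raises(InvalidSpecError):
            spec(mutation_prob=1.5)

    def test_maf_matches_founder_pool_frequency(self):
        s = spec(n_founders=4, n_variants=20, block_lengths=(20,), seed=3)
        n = 4000
        rng = np.random.default_rng(s.seed)
        founders = rng.integers(0, 2, size=(4, 20))
        haps = rl.simulate_haplotypes(s, n_samples=n)
        f_pool = founders.mean(axis=0)
        f_hat = haps.mean(axis=0)
        # binomial sampling error over 2n haplotypes, 4 sigma
        tol = 4 * np.sqrt(np.maximum(f_pool * (1 - f_pool), 0.25 / (2 * n)) / (2 * n))
        assert np.all(np.abs(f_hat - f_pool) <= np.maximum(tol, 0.02))

    def test_mutation_degrades_within_block_ld_monotonically(self):
        mean_r2 = []
        for mu in (0.0, 0.05, 0.2):
            vals = []
            for seed in range(50):
                s = spec(seed=seed, mutation_prob=mu)
                g = rl.simulate_haplotypes(s, 300)
                g = g[0::2] + g[1::2]
                try:
                    vals.append(rl.r2(g[:, 0], g[:, 3]))
                except rl.UndefinedLdError:
                    continue
            mean_r2.append(np.mean(vals))
        assert mean_r2[0] > mean_r2[1] > mean_r2[2]


class TestTraits:
    def test_h0_phenotypes_uncorrelated_with_dosage(self):
        s = spec(n_founders=4, mutation_prob=0.01)
        cfg = rl.CausalConfig(scenario="H0", n_samples=500, seed=2)
        haps = rl.simulate_haplotypes(s, cfg.n_samples)
        b = rl.simulate_traits(haps, cfg, s)
        for j in range(s.n_variants):
            if np.ptp(b.genotypes[:, j]) == 0:
                continue
            r = np.corrcoef(b.genotypes[:, j], b.trait)[0, 1]
            assert abs(r) < 0.2

    def test_h4_zero_noise_rank_correlation(self):
        s = spec(n_founders=4, mutation_prob=0.01)
        cfg = rl.CausalConfig(scenario="H4", trait_causal=3, expr_causal=3,
                              beta_trait=0.5, beta_expr=0.5, noise_sd=0.0,
                              n_samples=100, seed=4)
        haps = rl.simulate_haplotypes(s, cfg.n_samples)
        b = rl.simulate_traits(haps, cfg, s)
        dosage = b.genotypes[:, 3]
        assert stats.spearmanr(b.trait, dosage).statistic == pytest.approx(1.0)
        assert stats.spearmanr(b.expression, dosage).statistic == pytest.approx(1.0)

    def test_h4_strong_effect_reaches_genome_wide_significance(self, h4_bundle):
        # non-centrality n*beta^2*2f(1-f)/var_y ~ 124 at n=2000, beta=0.4,
        # f~0.35 => p far below 5e-8 at the causal variant
        res = rl.marginal_regression(h4_bundle.genotypes[:, 30], h4_bundle.trait)
        assert res.p < 5e-8

    def test_scenario_config_invariants(self):
        with pytest.raises(InvalidSpecError):
            rl.CausalConfig(scenario="H4", trait_causal=1, expr_causal=2)
        with pytest.raises(InvalidSpecError):
            rl.CausalConfig(scenario="H3", trait_causal=1, expr_causal=1)
        with pytest.raises(InvalidSpecError):
            rl.CausalConfig(scenario="H0", trait_causal=1)
        with pytest.raises(InvalidSpecError):
            rl.CausalConfig(scenario="H1", trait_causal=None)


class TestAnnotations:
    positions = tuple(range(5000, 5000 + 40 * 3000, 3000))

    def test_saturation_all_within(self):
        intervals, truth = rl.simulate_annotations(self.positions, 1.0, 0.0, seed=1)
        assert set(truth.values()) == {"within"}
        assert len(intervals) == len(self.positions)

    def test_empty_tracks(self):
        intervals, truth = rl.simulate_annotations(self.positions, 0.0, 0.0, seed=1)
        assert intervals == []
        assert set(truth.values()) == {"none"}

    def test_reference_grid_shaped_fractions(self):
        pos = tuple(range(5000, 5000 + 46 * 4000, 4000))
        _, truth = rl.simulate_annotations(pos, 33 / 46, 13 / 46, seed=9)
        counts = pd.Series(list(truth.values())).value_counts()
        assert counts["within"] == 33
        assert counts["near"] == 13

    def test_truth_labels_verified_by_annotator(self):
        intervals, truth = rl.simulate_annotations(self.positions, 0.3, 0.3, seed=2)
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end", "track"])
        variants = pd.DataFrame({
            "variant": list(truth), "chrom": "1", "pos": self.positions,
        })
        matrix = rl.build_annotation_matrix(variants, df, near_bp=500)
        assert matrix.summary_status().to_dict() == truth


class TestFaireBaf:
    def _bundle(self, n=10, seed=8):
        s = spec(n_founders=2, seed=seed)
        cfg = rl.CausalConfig(scenario="H0", n_samples=n, seed=seed)
        haps = rl.simulate_haplotypes(s, n)
        return rl.simulate_traits(haps, cfg, s)

    def test_noiseless_null_gives_identical_channels(self):
        b = self._bundle()
        vid = b.variant_ids[0]
        baf = rl.simulate_faire_baf(b, {vid: 0.0}, baf_noise_sd=0.0, seed=1)
        wide = baf.pivot_table(index="sample", columns="treatment", values="baf")
        assert np.allclose(wide["control"], wide["faire"])

    def test_injected_shift_recovered_in_mean(self):
        b = self._bundle(n=400, seed=12)
        j = next(j for j in range(b.spec.n_variants) if (b.genotypes[:, j] == 1).sum() >= 20)
        vid = b.variant_ids[j]
        baf = rl.simulate_faire_baf(b, {vid: 0.102}, baf_noise_sd=0.02, seed=3)
        hets = b.genotypes[:, j] == 1
        het_samples = [s for s, h in zip(b.sample_ids, hets) if h]
        sub = baf[(baf["sample"].isin(het_samples)) & (baf["treatment"] == "faire")]
        assert sub["baf"].mean() == pytest.approx(0.602, abs=0.01)

    def test_invalid_shift_rejected(self):
        b = self._bundle()
        with pytest.raises(InvalidSpecError):
            rl.simulate_faire_baf(b, {b.variant_ids[0]: 0.6})


class TestFixtureRoundTrip:
    def test_vcf_round_trip_and_sorted(self, tmp_path, h4_bundle):
        paths = rl.write_fixture_bundle(h4_bundle, tmp_path)
        variants, dosages, samples = read_vcf(paths["vcf"])
        assert samples == h4_bundle.sample_ids
        assert variants["pos"].is_monotonic_increasing
        assert np.array_equal(dosages, h4_bundle.genotypes)
        assert list(variants["variant"]) == h4_bundle.variant_ids

    def test_bed_consistent_with_truth(self, tmp_path, h4_bundle):
        paths = rl.write_fixture_bundle(h4_bundle, tmp_path)
        bed = read_bed(paths["bed"])
        variants = pd.DataFrame({
            "variant": h4_bundle.variant_ids,
            "chrom": h4_bundle.spec.chrom,
            "pos": h4_bundle.spec.positions,
        })
        matrix = rl.build_annotation_matrix(variants, bed, near_bp=500)
        assert matrix.summary_status().to_dict() == h4_bundle.annotation_truth
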