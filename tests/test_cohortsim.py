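"""Cohort simulator: Hardy-Weinberg draws, depth model, fact stream."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from variantdwh import (
    AFHyperparams,
    EthnicGroup,
    Genotype,
    assign_samples,
    generate_world,
    genotype_probabilities,
    simulate_cohort,
    simulate_depth,
    simulate_genotype,
)
from variantdwh.refgen import generate_diseases, generate_geography
from variantdwh.types import GeographyEntry


class TestGenotypeProbabilities:
    @pytest.mark.parametrize("af,expected", [
        (0.0, (1.0, 0.0, 0.0)),
        (0.5, (0.25, 0.5, 0.25)),
        (1.0, (0.0, 0.0, 1.0)),
        (0.1, (0.81, 0.18, 0.01)),
    ])
    def test_known_values(self, af, expected):
        assert genotype_probabilities(af) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_valid_distribution_for_any_af(self, af):
        p = genotype_probabilities(af)
        assert all(0.0 <= x <= 1.0 for x in p)
        assert sum(p) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("af", [-0.1, 1.1])
    def test_out_of_range_rejected(self, af):
        with pytest.raises(ValueError):
            genotype_probabilities(af)


class TestSimulateGenotype:
    def test_monomorphic_boundaries(self):
        rng = np.random.default_rng(0)
        assert all(simulate_genotype(0.0, rng) is Genotype.HOM_REF for _ in range(50))
        assert all(simulate_genotype(1.0, rng) is Genotype.HOM_ALT for _ in range(50))

    def test_homalt_rate_matches_af_squared(self):
        rng = np.random.default_rng(1)
        n, af = 100_000, 0.1
        hits = sum(simulate_genotype(af, rng) is Genotype.HOM_ALT for _ in range(n))
        p = af * af
        assert abs(hits - n * p) <= 4 * np.sqrt(n * p * (1 - p))


class TestSimulateDepth:
    def test_alt_never_exceeds_total(self):
        rng = np.random.default_rng(2)
        for _ in range(50_000):
            gt = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_ALT
            dp, ad = simulate_depth(20.0, gt, rng)
            assert 0 <= ad <= dp

    def test_het_alt_fraction_is_half(self):
        rng = np.random.default_rng(3)
        draws = [simulate_depth(60.0, Genotype.HET, rng) for _ in range(10_000)]
        total = sum(d for d, _ in draws)
        alt = sum(a for _, a in draws)
        assert abs(alt / total - 0.5) <= 4 * np.sqrt(0.25 / total)

    def test_error_free_homalt_uses_all_reads(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            dp, ad = simulate_depth(30.0, Genotype.HOM_ALT, rng, error_rate=0.0)
            assert ad == dp

    def test_invalid_inputs(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            simulate_depth(0.0, Genotype.HET, rng)
        with pytest.raises(ValueError):
            simulate_depth(10.0, Genotype.HOM_REF, rng)


class TestAssignSamples:
    def test_country_matches_ethnicity(self):
        geography = generate_geography(4, seed=1)
        samples = assign_samples(4, {g: 0.25 for g in EthnicGroup}, geography,
                                 [], 0.0, seed=2)
        geo = {g.geo_id: g for g in geography}
        assert all(geo[s.geo_fk].ethnic_group == s.ethnic_group for s in samples)

    def test_population_weighted_country_choice(self):
        """A country 10x more populous draws ~10x the samples (binomial noise)."""
        big = GeographyEntry(1, "EU-001", "Europe-S1", "Europe", 10_000_000, EthnicGroup.EUR)
        small = GeographyEntry(2, "EU-002", "Europe-S1", "Europe", 1_000_000, EthnicGroup.EUR)
        others = [GeographyEntry(3, "AM-001", "Americas-S1", "Americas", 1, EthnicGroup.AMR),
                  GeographyEntry(4, "AS-001", "Asia-S1", "Asia", 1, EthnicGroup.EAS),
                  GeographyEntry(5, "AF-001", "Africa-S1", "Africa", 1, EthnicGroup.AFR)]
        samples = assign_samples(10_000, {EthnicGroup.EUR: 1.0}, [big, small] + others,
                                 [], 0.0, seed=3)
        n_big = sum(1 for s in samples if s.geo_fk == 1)
        p = 10 / 11
        assert abs(n_big - 10_000 * p) <= 4 * np.sqrt(10_000 * p * (1 - p))

    def test_disease_prevalence_extremes(self):
        geography = generate_geography(8, seed=1)
        diseases = generate_diseases(10, seed=1)
        none = assign_samples(100, {g: 0.25 for g in EthnicGroup}, geography,
                              diseases, 0.0, seed=4)
        all_ = assign_samples(100, {g: 0.25 for g in EthnicGroup}, geography,
                              diseases, 1.0, seed=4)
        assert all(s.disease_fk is None for s in none)
        assert all(s.disease_fk is not None for s in all_)

    def test_bad_proportions_and_empty_group(self):
        geography = generate_geography(4, seed=1)
        with pytest.raises(ValueError):
            assign_samples(10, {EthnicGroup.EUR: 0.5}, geography, [], 0.0, seed=1)
        europe_only = [g for g in geography if g.ethnic_group == EthnicGroup.EUR]
        with pytest.raises(ValueError):
            assign_samples(10, {g: 0.25 for g in EthnicGroup}, europe_only, [], 0.0, seed=1)


class TestSimulateCohort:
    def _tiny_world(self, fixed_af, n_samples=20, n_variants=30, seed=5):
        return generate_world(n_samples=n_samples, n_variants=n_variants, seed=seed,
                              n_countries=8, n_diseases=5, n_genes=5,
                              af_hyperparams=AFHyperparams(fixed_af=fixed_af))

    def test_monomorphic_reference_yields_empty_stream(self):
        w = self._tiny_world(fixed_af=0.0)
        assert w.facts == []

    def test_saturated_catalog_yields_all_homalt(self):
        w = self._tiny_world(fixed_af=1.0)
        assert len(w.facts) == 20 * 30
        assert all(f.genotype is Genotype.HOM_ALT for f in w.facts)

    def test_stream_ordering_and_fk_consistency(self, small_world):
        from variantdwh.types import CHROM_RANK
        keys = [(f.sample_id, CHROM_RANK[f.chrom], f.pos) for f in small_world.facts]
        assert keys == sorted(keys)
        geo = {g.geo_id: g for g in small_world.geography}
        sample = {s.sample_id: s for s in small_world.samples}
        for f in small_world.facts[:500]:
            assert geo[f.geo_fk].ethnic_group == sample[f.sample_id].ethnic_group
            assert f.disease_fk == sample[f.sample_id].disease_fk

    def test_row_count_matches_analytic_expectation(self, small_world):
        """E[rows] = sum over samples and variants of 1 - P(0/0; af)."""
        groups = {s.sample_id: s.ethnic_group for s in small_world.samples}
        mean = var = 0.0
        for s in small_world.samples:
            for v in small_world.catalog:
                af = v.af[groups[s.sample_id]]
                p = 2 * af * (1 - af) + af * af
                mean += p
                var += p * (1 - p)
        assert abs(len(small_world.facts) - mean) <= 4 * np.sqrt(var)

    def test_end_to_end_determinism(self, small_world):
        replay = generate_world(n_samples=50, n_variants=500, seed=7,
                                n_countries=12, n_diseases=50, n_genes=20,
                                exons_per_gene_mean=5.0)
        assert replay.facts == small_world.facts
        assert replay.samples == small_world.samples

    def test_containment_violation_rejected(self, small_world):
        bad_models = {"ensembl": small_world.gene_model_ens[:2]}
        with pytest.raises(ValueError):
            list(simulate_cohort(small_world.catalog, small_world.samples,
                                 bad_models, seed=1))


def test_af_parameter_recovery_slope(small_world):
    """Empirical per-group AFs regress on catalog AFs with slope ~ 1."""
    groups = list(EthnicGroup)
    n_group = {g: sum(1 for s in small_world.samples if s.ethnic_group == g)
               for g in groups}
    sample_group = {s.sample_id: s.ethnic_group for s in small_world.samples}
    counts = {}
    for f in small_world.facts:
        key = ((f.chrom, f.pos), sample_group[f.sample_id])
        counts[key] = counts.get(key, 0) + (1 if f.genotype is Genotype.HET else 2)
    x, y = [], []
    for v in small_world.catalog:
        for g in groups:
            if n_group[g] == 0:
                continue
            x.append(v.af[g])
            y.append(counts.get(((v.chrom, v.pos), g), 0) / (2 * n_group[g]))
    slope = np.polyfit(x, y, 1)[0]
    assert abs(slope - 1.0) < 0.05
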