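"""Query suite: rendering, oracle semantics, engine equivalence."""

import numpy as np
import pandas as pd
import pytest

from variantdwh import AFHyperparams, SQLiteAdapter, build_all, generate_world
from variantdwh.queries import (
    QUERY_IDS,
    UnsupportedQueryError,
    compare_results,
    descriptor,
    execute,
    oracle,
    render,
)

from conftest import default_params


class TestRender:
    def test_range_predicate_and_literal_binding(self):
        sql = render("Q5", "raw", {"sample_id": 7, "chrom": "1", "start": 10, "end": 99})
        assert "BETWEEN 10 AND 99" in sql
        assert "sample_id = 7" in sql
        assert ":" not in sql  # fully substituted

    def test_string_parameters_are_escaped(self):
        sql = render("Q3A", "raw", {"omim_id": "1'; DROP TABLE fact; --"})
        assert "'1''; DROP TABLE fact; --'" in sql  # quote doubled, one literal

    def test_unsupported_level_pair(self):
        with pytest.raises(UnsupportedQueryError):
            render("Q5", "aggr", {"sample_id": 1, "chrom": "1", "start": 1, "end": 2})

    def test_missing_required_parameter(self):
        with pytest.raises(UnsupportedQueryError, match="omim_id"):
            render("Q3A", "raw", {})

    def test_unknown_query_and_dialect(self):
        with pytest.raises(UnsupportedQueryError):
            render("Q99", "raw", {})
        with pytest.raises(UnsupportedQueryError):
            render("Q7", "raw", {}, dialect="hiveql")

    def test_levels_differ_only_in_count_source(self):
        """The AF query reads counts from different tables per level but
        shares the denominator logic."""
        raw = render("Q1A", "raw")
        aggr = render("Q1A", "aggr")
        denorm = render("Q1A", "aggr_denorm")
        for sql in (raw, aggr, denorm):
            assert "FROM sample_counts_geo" in sql
        assert "FROM fact f" in raw and "fact_agg_counts a" in aggr
        assert "fact_agg_counts_dims a" in denorm

    def test_invalid_render_option_rejected(self):
        with pytest.raises(UnsupportedQueryError):
            render("Q2A", "raw", {"source": "dbsnp"})


class TestOracleSemantics:
    def test_af_continent_equals_weighted_country_counts(self, small_world):
        """Integer identity: region numerator = sum of country numerators."""
        q1a = oracle("Q1A", {}, small_world)
        q1b = oracle("Q1B", {}, small_world)
        geo = {g.country: g.region for g in small_world.geography}
        sizes_region = {}
        sizes_country = {}
        geo_by_id = {g.geo_id: g for g in small_world.geography}
        for s in small_world.samples:
            g = geo_by_id[s.geo_fk]
            sizes_region[g.region] = sizes_region.get(g.region, 0) + 1
            sizes_country[g.country] = sizes_country.get(g.country, 0) + 1
        q1b = q1b.assign(region=q1b.country.map(geo),
                         ac=[round(af * 2 * sizes_country[c])
                             for af, c in zip(q1b.af, q1b.country)])
        by_region = q1b.groupby(["chrom", "pos", "ref", "alt", "region"]).ac.sum()
        for row in q1a.itertuples():
            ac_region = round(row.af * 2 * sizes_region[row.region])
            assert ac_region == by_region.get(
                (row.chrom, row.pos, row.ref, row.alt, row.region), 0)

    def test_af_values_within_unit_interval(self, small_world):
        for qid in ("Q1A", "Q1B"):
            af = oracle(qid, {}, small_world).af
            assert (af >= 0).all() and (af <= 1).all()

    def test_rare_query_without_filters_counts_all_variants(self, small_world):
        """With cutoff 1.0 and the damaging filter off, the per-exon query
        degenerates to distinct observed-variant counts per merged exon."""
        q2b = oracle("Q2B", {"af_cutoff": 1.0, "damaging_only": "no"}, small_world)
        exons = [e for e in small_world.gene_model_ens if e.is_merged]
        observed = {(f.chrom, f.pos, f.ref, f.alt) for f in small_world.facts}
        brute = {}
        for e in exons:
            n = sum(1 for (c, p, _, _) in observed if c == e.chrom and e.start <= p <= e.end)
            if n:
                brute[(e.gene_symbol, e.transcript_id, e.exon_number)] = n
        got = {(r.gene_symbol, r.transcript_id, r.exon_number): r.n_variants
               for r in q2b.itertuples()}
        assert got == brute

    def test_het_hom_ratio_fixture(self):
        """Hand-built sample with 4 het and 2 hom calls on X gives ratio 2."""
        from variantdwh.types import FactRecord, Genotype, World, SampleRecord, EthnicGroup

        facts = []
        for i in range(6):
            facts.append(FactRecord(
                sample_id=1, chrom="X", pos=1000 + i, ref="A", alt="G",
                genotype=Genotype.HET if i < 4 else Genotype.HOM_ALT,
                dp=30, ad_alt=15, geo_fk=1, region_fk_ens=1, region_fk_rs=1,
                disease_fk=None, prediction_fk=i + 1))
        world = World(facts=facts,
                      samples=[SampleRecord(1, EthnicGroup.EUR, 1, None)])
        result = oracle("Q9", {"sample_id": 1}, world)
        assert float(result.het_hom_ratio[0]) == 2.0
        absent = oracle("Q9", {"sample_id": 2}, world)
        assert pd.isna(absent.het_hom_ratio[0])

    def test_substitution_collapse_modes(self, small_world):
        plain = oracle("Q6", {"collapse": "no"}, small_world)
        collapsed = oracle("Q6", {"collapse": "strand"}, small_world)
        assert plain.n.sum() == collapsed.n.sum() == len(small_world.facts)
        assert set(collapsed.substitution) <= {
            "C>A", "C>G", "C>T", "T>A", "T>C", "T>G"}

    def test_distinct_variant_totals_consistent(self, small_world):
        q7 = oracle("Q7", {}, small_world)
        observed = {(f.chrom, f.pos, f.ref, f.alt) for f in small_world.facts}
        assert int(q7.n_variants.sum()) == len(observed)


class TestEngineEquivalence:
    def test_all_queries_match_oracle_on_small_world(self, small_world, small_adapter):
        params = default_params(small_world)
        for qid in QUERY_IDS:
            p = params.get(qid, {})
            expected = oracle(qid, p, small_world)
            for level in descriptor(qid)["levels"]:
                got = execute(small_adapter, qid, level, p)
                compare_results(qid, got, expected)

    def test_refseq_source_matches_oracle(self, small_world, small_adapter):
        for qid in ("Q2B", "Q4A", "Q11"):
            p = {"source": "refseq"}
            expected = oracle(qid, p, small_world)
            got = execute(small_adapter, qid, "raw", p)
            compare_results(qid, got, expected)

    def test_saturation_fixture(self, tmp_path):
        """All AFs = 1: every sample carries every variant as hom-alt, so the
        substitution counts are n_samples per variant and the distinct-variant
        totals equal the catalog size."""
        w = generate_world(n_samples=10, n_variants=40, seed=13, n_countries=8,
                           n_diseases=5, n_genes=5,
                           af_hyperparams=AFHyperparams(fixed_af=1.0))
        wh = build_all(tmp_path / "wh", w)
        with SQLiteAdapter(wh) as adapter:
            q6 = execute(adapter, "Q6", "raw")
            assert int(q6.n.sum()) == 10 * 40
            per_type = {(v.ref, v.alt) for v in w.catalog}
            counts = {}
            for v in w.catalog:
                counts[f"{v.ref}>{v.alt}"] = counts.get(f"{v.ref}>{v.alt}", 0) + 10
            assert dict(zip(q6.substitution, q6.n)) == counts
            assert len(per_type) == len(q6)
            q7 = execute(adapter, "Q7", "raw")
            assert int(q7.n_variants.sum()) == 40
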