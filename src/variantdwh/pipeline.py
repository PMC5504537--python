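"""End-to-end convenience: build a whole synthetic world in one call.

Defaults follow the reference study conditions: four ethnic groups with
uniform cohort proportions, 181 countries, 7569 OMIM-like diseases, a
right-skewed allele-frequency law with mean 0.05, a 60x mean site depth
and two gene-model sources.  Cohort size and catalog size are the knobs
that set problem scale.
"""

from __future__ import annotations

from . import cohortsim, refgen
from .refgen import AFHyperparams
from .types import EthnicGroup, World

__all__ = ["generate_world", "DEFAULTS"]

DEFAULTS = dict(
    n_countries=181,
    n_diseases=7569,
    n_genes=100,
    exons_per_gene_mean=8.0,
    damaging_fraction=0.2,
    disease_prevalence=0.2,
)


def generate_world(
    n_samples: int,
    n_variants: int,
    seed: int,
    n_countries: int = DEFAULTS["n_countries"],
    n_diseases: int = DEFAULTS["n_diseases"],
    n_genes: int = DEFAULTS["n_genes"],
    exons_per_gene_mean: float = DEFAULTS["exons_per_gene_mean"],
    af_hyperparams: AFHyperparams = AFHyperparams(),
    damaging_fraction: float = DEFAULTS["damaging_fraction"],
    disease_prevalence: float = DEFAULTS["disease_prevalence"],
    ethnic_proportions: dict | None = None,
) -> World:
    """Generate reference tables, a cohort and its fact records."""
    proportions = ethnic_proportions or {g: 0.25 for g in EthnicGroup}
    geography = refgen.generate_geography(n_countries, seed)
    gene_models = {
        "ensembl": refgen.generate_gene_model(n_genes, exons_per_gene_mean, seed, "ensembl"),
        "refseq": refgen.generate_gene_model(n_genes, exons_per_gene_mean, seed, "refseq"),
    }
    catalog, predictions = refgen.generate_catalog(
        gene_models, n_variants, af_hyperparams, damaging_fraction, seed)
    diseases = refgen.generate_diseases(n_diseases, seed)
    samples = cohortsim.assign_samples(
        n_samples, proportions, geography, diseases, disease_prevalence, seed)
    facts = list(cohortsim.simulate_cohort(catalog, samples, gene_models, seed))
    return World(
        geography=geography,
        gene_model_ens=gene_models["ensembl"],
        gene_model_rs=gene_models["refseq"],
        diseases=diseases,
        catalog=catalog,
        predictions=predictions,
        samples=samples,
        facts=facts,
    )
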