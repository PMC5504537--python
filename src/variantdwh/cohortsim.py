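"""Cohort simulation: samples, genotypes, read depths, fact records.

The simulator follows a three-step procedure.  First every sample is
assigned an ethnic group and, within the group, a country chosen with
probability proportional to country population.  Second, for every
(sample, catalog variant) pair a diploid genotype is drawn under
Hardy-Weinberg equilibrium from the allele frequency ``af`` of the
sample's ethnic group:

    P(0/0) = 1 - 2*af + af**2
    P(0/1) = 2*af*(1 - af)
    P(1/1) = af**2

Third, total and allelic read depths are simulated for every
non-reference genotype: total depth is Poisson with the site mean depth,
and the alt-supporting read count is Binomial(dp, 1/2) for heterozygotes
while homozygous-alt sites lose reads to a small allelic error rate.

Only non-reference calls become fact records; a cohort of N samples
therefore yields about ``sum_v (1 - P(0/0; af_v))`` rows per sample, and
allele-frequency denominators must come from the sample registry rather
than the fact table.
"""

from __future__ import annotations

from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .refgen import _child_rng, merged_exons
from .types import (
    CHROM_RANK,
    DiseaseEntry,
    EthnicGroup,
    FactRecord,
    Genotype,
    GenomicRegionEntry,
    GeographyEntry,
    SampleRecord,
    VariantCatalogEntry,
)

__all__ = [
    "genotype_probabilities",
    "simulate_genotype",
    "simulate_depth",
    "assign_samples",
    "simulate_cohort",
]

#: Allelic error rate at homozygous-alt sites (fraction of reads
#: supporting the reference allele despite a 1/1 genotype).
HOM_ALT_ERROR_RATE = 0.01


def genotype_probabilities(af: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities (P(0/0), P(0/1), P(1/1)).

    Evaluates ``(1 - 2*af + af**2, 2*af*(1 - af), af**2)`` exactly as
    written; the three terms sum to one for any allele frequency.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return (1.0 - 2.0 * af + af * af, 2.0 * af * (1.0 - af), af * af)


def simulate_genotype(af: float, rng: np.random.Generator) -> Genotype:
    """Draw one genotype under Hardy-Weinberg equilibrium at frequency ``af``."""
    p = genotype_probabilities(af)
    u = rng.random()
    if u < p[0]:
        return Genotype.HOM_REF
    if u < p[0] + p[1]:
        return Genotype.HET
    return Genotype.HOM_ALT


def simulate_depth(
    mean_dp: float,
    genotype: Genotype,
    rng: np.random.Generator,
    error_rate: float = HOM_ALT_ERROR_RATE,
) -> tuple[int, int]:
    """Simulate (total depth, alt-supporting depth) for one call.

    dp ~ Poisson(mean_dp); given dp, ad_alt is Binomial(dp, 1/2) for a
    heterozygote and dp - Binomial(dp, error_rate) for a homozygote.
    """
    if mean_dp <= 0:
        raise ValueError("mean_dp must be positive")
    dp = int(rng.poisson(mean_dp))
    if dp == 0:
        return 0, 0
    if genotype is Genotype.HET:
        ad = int(rng.binomial(dp, 0.5))
    elif genotype is Genotype.HOM_ALT:
        ad = dp - int(rng.binomial(dp, error_rate))
    else:
        raise ValueError("depth is only simulated for non-reference genotypes")
    return dp, ad


def assign_samples(
    n_samples: int,
    ethnic_proportions: Mapping[EthnicGroup, float],
    geography: Sequence[GeographyEntry],
    diseases: Sequence[DiseaseEntry],
    disease_prevalence: float,
    seed: int,
) -> list[SampleRecord]:
    """Assign each sample an ethnic group, a country and possibly a disease.

    Group membership is multinomial with ``ethnic_proportions``; within a
    group the country is multinomial with weights proportional to country
    population.  Each sample carries a disease with probability
    ``disease_prevalence``, uniformly over the disease list.
    """
    props = {g: float(p) for g, p in ethnic_proportions.items()}
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"ethnic proportions sum to {total}, expected 1")
    rng = _child_rng(seed, "samples")
    groups = list(EthnicGroup)
    p_groups = np.array([props.get(g, 0.0) for g in groups])
    by_group: dict[EthnicGroup, list[GeographyEntry]] = {g: [] for g in groups}
    for geo in geography:
        by_group[geo.ethnic_group].append(geo)
    weights: dict[EthnicGroup, np.ndarray] = {}
    for g in groups:
        if p_groups[groups.index(g)] > 0 and not by_group[g]:
            raise ValueError(f"no countries available for group {g}")
        if by_group[g]:
            w = np.array([c.population for c in by_group[g]], dtype=float)
            weights[g] = w / w.sum()

    group_idx = rng.choice(len(groups), size=n_samples, p=p_groups)
    has_disease = rng.random(n_samples) < disease_prevalence
    disease_idx = (rng.integers(0, len(diseases), size=n_samples)
                   if diseases else np.zeros(n_samples, dtype=int))
    samples: list[SampleRecord] = []
    for i in range(n_samples):
        g = groups[int(group_idx[i])]
        geo = by_group[g][int(rng.choice(len(by_group[g]), p=weights[g]))]
        disease_fk = None
        if diseases and has_disease[i]:
            disease_fk = diseases[int(disease_idx[i])].disease_id
        samples.append(SampleRecord(sample_id=i + 1, ethnic_group=g,
                                    geo_fk=geo.geo_id, disease_fk=disease_fk))
    return samples


def _check_containment(
    catalog: Sequence[VariantCatalogEntry],
    gene_models: Mapping[str, Sequence[GenomicRegionEntry]],
) -> None:
    for src, gm in gene_models.items():
        exons = merged_exons(gm)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for e in exons:
            by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
        for v in catalog:
            if not any(s <= v.pos <= e for s, e in by_chrom.get(v.chrom, [])):
                raise ValueError(
                    f"variant {v.chrom}:{v.pos} not contained in any {src} merged exon")


def simulate_cohort(
    catalog: Sequence[VariantCatalogEntry],
    samples: Sequence[SampleRecord],
    gene_models: Optional[Mapping[str, Sequence[GenomicRegionEntry]]] = None,
    seed: int = 0,
    error_rate: float = HOM_ALT_ERROR_RATE,
) -> Iterator[FactRecord]:
    """Stream fact records for a whole cohort, (sample_id, chrom, pos)-ordered.

    For every (sample, variant) pair an independent Hardy-Weinberg draw is
    made with the sample's group allele frequency; only non-reference
    genotypes are emitted.  Genotype and depth draws are vectorized per
    sample; the stream is deterministic for a fixed seed.
    """
    if gene_models:
        _check_containment(catalog, gene_models)
    rng = _child_rng(seed, "cohort")
    groups = list(EthnicGroup)
    order = sorted(range(len(catalog)),
                   key=lambda i: (CHROM_RANK[catalog[i].chrom], catalog[i].pos,
                                  catalog[i].ref, catalog[i].alt))
    cat = [catalog[i] for i in order]
    af_matrix = np.array([[v.af[g] for g in groups] for v in cat])  # (V, G)
    mean_dp = np.array([v.mean_dp for v in cat])
    n_v = len(cat)
    for s in sorted(samples, key=lambda r: r.sample_id):
        af = af_matrix[:, groups.index(s.ethnic_group)]
        u = rng.random(n_v)
        p_homref = 1.0 - 2.0 * af + af * af
        p_het = 2.0 * af * (1.0 - af)
        gt = np.where(u < p_homref, 0, np.where(u < p_homref + p_het, 1, 2))
        nz = np.nonzero(gt)[0]
        if nz.size == 0:
            continue
        dp = rng.poisson(mean_dp[nz])
        het = gt[nz] == 1
        ad = np.where(het, rng.binomial(dp, 0.5),
                      dp - rng.binomial(dp, error_rate))
        for j, idx in enumerate(nz):
            v = cat[int(idx)]
            yield FactRecord(
                sample_id=s.sample_id, chrom=v.chrom, pos=v.pos,
                ref=v.ref, alt=v.alt,
                genotype=Genotype.HET if het[j] else Genotype.HOM_ALT,
                dp=int(dp[j]), ad_alt=int(ad[j]),
                geo_fk=s.geo_fk, region_fk_ens=v.region_fk_ens,
                region_fk_rs=v.region_fk_rs, disease_fk=s.disease_fk,
                prediction_fk=v.prediction_fk)
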