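"""Synthetic reference world: variant catalog and dimension tables.

This module emulates the public resources a variant warehouse is loaded
from: an ExAC/dbNSFP-like SNV catalog with per-ethnic-group allele
frequencies, a deleteriousness call and a site mean depth; a world
geography hierarchy (region -> subregion -> country) with population
sizes; Ensembl- and RefSeq-like exon tables; and an OMIM-like disease
list.  Everything is generated deterministically from an integer seed.

Allele-frequency model
----------------------
No public catalog documents a generative AF model (real resources simply
report observed frequencies), so the generator uses a right-skewed
Beta(a, b) law for a per-variant base frequency and adds independent
Gaussian jitter on the logit scale per ethnic group.  The shared base
induces the positive cross-group AF correlation seen in real cohorts;
the jitter magnitude controls how population-specific a variant can be.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import (
    CHROMOSOMES,
    CHROM_LENGTHS,
    CHROM_RANK,
    REGION_TO_GROUP,
    DiseaseEntry,
    EthnicGroup,
    GenomicRegionEntry,
    GeographyEntry,
    PredictionRecord,
    VariantCatalogEntry,
)

__all__ = [
    "AFHyperparams",
    "generate_geography",
    "generate_gene_model",
    "generate_catalog",
    "generate_diseases",
    "merged_exons",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AFHyperparams:
    """Hyperparameters of the allele-frequency model.

    beta_a, beta_b
        Shape parameters of the base-AF Beta law.  The default
        Beta(0.25, 4.75) has mean 0.05 and is strongly right-skewed:
        most variants are rare, a thin tail is common.
    group_logit_sd
        Standard deviation of the per-group jitter on the logit scale.
    fixed_af
        If set, every variant gets exactly this AF in every group
        (degenerate distribution, useful for saturation fixtures).
    """

    beta_a: float = 0.25
    beta_b: float = 4.75
    group_logit_sd: float = 0.5
    fixed_af: Optional[float] = None


def _child_rng(seed: int, *tags: object) -> np.random.Generator:
    """Independent, reproducible stream for one generator component."""
    ints = [seed] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# Geography

def generate_geography(n_countries: int, seed: int) -> list[GeographyEntry]:
    """Generate the geography dimension.

    Each of the four world regions (Europe, Americas, Asia, Africa) maps
    1:1 to an ethnic group; countries are split into a few subregions per
    region and get heavy-tailed (log-normal) population sizes so that
    population-weighted country assignment is nontrivial.
    """
    if n_countries < 4:
        raise ValueError("n_countries must be >= 4 to cover the four ethnic groups")
    rng = _child_rng(seed, "geography")
    regions = list(REGION_TO_GROUP)
    # every region gets at least one country; the rest are assigned at random
    assignment = regions + [regions[i] for i in rng.integers(0, 4, size=n_countries - 4)]
    assignment.sort(key=regions.index)
    entries: list[GeographyEntry] = []
    per_region_counter: dict[str, int] = {r: 0 for r in regions}
    populations = np.rint(rng.lognormal(mean=16.0, sigma=1.3, size=n_countries)).astype(np.int64)
    populations = np.maximum(populations, 10_000)
    for geo_id, region in enumerate(assignment, start=1):
        per_region_counter[region] += 1
        idx = per_region_counter[region]
        subregion = f"{region}-S{(idx - 1) // 6 + 1}"
        entries.append(
            GeographyEntry(
                geo_id=geo_id,
                country=f"{region[:2].upper()}-{idx:03d}",
                subregion=subregion,
                region=region,
                population=int(populations[geo_id - 1]),
                ethnic_group=REGION_TO_GROUP[region],
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Gene models

def _gene_skeletons(n_genes: int, exons_per_gene_mean: float, seed: int):
    """Shared gene loci and exon unions, identical across annotation sources.

    Genes are laid out cyclically over the chromosomes with random
    intergenic gaps; each gene's exon union is a chain of non-overlapping
    exons separated by introns.  Both annotation sources derive their
    transcripts from this skeleton so that the merged-transcript
    footprints of a gene coincide across sources.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _child_rng(seed, "gene-skeleton")
    cursors = {c: 1 for c in CHROMOSOMES}
    skeletons = []  # (gene_symbol, chrom, [(start, end), ...])
    chrom_cycle = 0
    for g in range(1, n_genes + 1):
        k = 1 + rng.poisson(max(exons_per_gene_mean - 1.0, 0.0))
        exon_lens = rng.integers(80, 400, size=k)
        intron_lens = rng.integers(200, 3000, size=max(k - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        placed = False
        for _ in range(len(CHROMOSOMES)):
            chrom = CHROMOSOMES[chrom_cycle % len(CHROMOSOMES)]
            chrom_cycle += 1
            gap = int(rng.integers(5_000, 50_000))
            start = cursors[chrom] + gap
            if start + span <= CHROM_LENGTHS[chrom]:
                exons = []
                pos = start
                for i in range(k):
                    exons.append((pos, pos + int(exon_lens[i]) - 1))
                    pos += int(exon_lens[i])
                    if i < k - 1:
                        pos += int(intron_lens[i])
                cursors[chrom] = exons[-1][1] + 1
                skeletons.append((f"GENE{g:04d}", chrom, exons))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"requested {n_genes} genes exceed the available coordinate space"
            )
    return skeletons


def generate_gene_model(
    n_genes: int,
    exons_per_gene_mean: float,
    seed: int,
    source: str = "ensembl",
) -> list[GenomicRegionEntry]:
    """Generate one annotation source's exon table.

    Every gene receives a canonical transcript spanning all of its exons,
    zero or more alternative transcripts over contiguous exon subsets,
    and exactly one merged transcript whose exons are the union of the
    gene's exons.  Calling with the same seed but a different ``source``
    yields the same gene loci with independently drawn transcript
    structures (Ensembl vs RefSeq annotate the same genes differently).
    """
    if source not in ("ensembl", "refseq"):
        raise ValueError(f"unknown source {source!r}")
    skeletons = _gene_skeletons(n_genes, exons_per_gene_mean, seed)
    rng = _child_rng(seed, "transcripts", source)
    prefix = "ENST" if source == "ensembl" else "NM_"
    entries: list[GenomicRegionEntry] = []
    region_id = 0
    for gi, (gene, chrom, exons) in enumerate(skeletons, start=1):
        k = len(exons)
        n_alt = int(rng.integers(0, 3)) if k > 1 else 0
        transcripts: list[tuple[str, list[int], bool]] = [
            (f"{prefix}{gi:05d}01", list(range(k)), True)  # canonical: all exons
        ]
        for t in range(n_alt):
            i = int(rng.integers(0, k))
            j = int(rng.integers(i, k))
            transcripts.append((f"{prefix}{gi:05d}{t + 2:02d}", list(range(i, j + 1)), False))
        for tx_id, exon_idx, canonical in transcripts:
            for num, ei in enumerate(exon_idx, start=1):
                region_id += 1
                entries.append(GenomicRegionEntry(
                    region_id=region_id, source=source, gene_symbol=gene,
                    transcript_id=tx_id, exon_number=num, chrom=chrom,
                    start=exons[ei][0], end=exons[ei][1],
                    is_canonical=canonical, is_merged=False))
        # merged transcript: union of all the gene's exons
        for num, (s, e) in enumerate(exons, start=1):
            region_id += 1
            entries.append(GenomicRegionEntry(
                region_id=region_id, source=source, gene_symbol=gene,
                transcript_id=f"{prefix}M{gi:05d}", exon_number=num, chrom=chrom,
                start=s, end=e, is_canonical=False, is_merged=True))
    return entries


def merged_exons(gene_model: Sequence[GenomicRegionEntry]) -> list[GenomicRegionEntry]:
    """The merged-transcript exons of a gene model, in genomic order."""
    ex = [e for e in gene_model if e.is_merged]
    ex.sort(key=lambda e: (CHROM_RANK[e.chrom], e.start))
    return ex


# ---------------------------------------------------------------------------
# Variant catalog

def _resolve_region_fk(exons: Sequence[GenomicRegionEntry], chrom: str, pos: int) -> int:
    """region_id of the merged-transcript exon containing (chrom, pos)."""
    for e in exons:
        if e.chrom == chrom and e.start <= pos <= e.end:
            return e.region_id
    raise ValueError(f"position {chrom}:{pos} not contained in any merged exon")


def generate_catalog(
    gene_models: Mapping[str, Sequence[GenomicRegionEntry]],
    n_variants: int,
    af_hyperparams: AFHyperparams = AFHyperparams(),
    damaging_fraction: float = 0.2,
    seed: int = 0,
    depth_gamma: tuple[float, float] = (10.0, 6.0),
) -> tuple[list[VariantCatalogEntry], list[PredictionRecord]]:
    """Generate the SNV catalog and its prediction dimension.

    Variant positions are drawn uniformly (without replacement) over the
    base pairs of the merged-transcript exons, so every variant is exonic
    by construction.  ``depth_gamma = (shape, scale)`` parameterizes the
    Gamma law of the site mean depth; the default has mean 60x, typical
    of exome capture.
    """
    if not gene_models or "ensembl" not in gene_models or not gene_models["ensembl"]:
        raise ValueError("gene_models must contain a non-empty 'ensembl' model")
    if n_variants == 0:
        return [], []
    rng = _child_rng(seed, "catalog")
    exons_by_source = {src: merged_exons(gm) for src, gm in gene_models.items()}
    ens = exons_by_source["ensembl"]

    lengths = np.array([e.end - e.start + 1 for e in ens], dtype=np.int64)
    total_bp = int(lengths.sum())
    if n_variants > total_bp:
        raise ValueError(f"cannot place {n_variants} unique variants in {total_bp} exonic bp")
    offsets = np.sort(rng.choice(total_bp, size=n_variants, replace=False))
    cum = np.cumsum(lengths)
    exon_idx = np.searchsorted(cum, offsets, side="right")
    within = offsets - (cum[exon_idx] - lengths[exon_idx])

    # allele frequencies
    hp = af_hyperparams
    groups = list(EthnicGroup)
    if hp.fixed_af is not None:
        af_matrix = np.full((n_variants, len(groups)), float(hp.fixed_af))
    else:
        base = rng.beta(hp.beta_a, hp.beta_b, size=n_variants)
        base = np.clip(base, 1e-4, 1 - 1e-4)
        logit = np.log(base / (1 - base))
        jitter = rng.normal(0.0, hp.group_logit_sd, size=(n_variants, len(groups)))
        af_matrix = 1.0 / (1.0 + np.exp(-(logit[:, None] + jitter)))

    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_shift = rng.integers(1, 4, size=n_variants)
    alt_idx = (ref_idx + alt_shift) % 4
    damaging = rng.random(n_variants) < damaging_fraction
    mean_dp = rng.gamma(depth_gamma[0], depth_gamma[1], size=n_variants)
    mean_dp = np.maximum(mean_dp, 1.0)
    fathmm_score = np.where(damaging, 0.5 + 0.5 * rng.random(n_variants),
                            0.5 * rng.random(n_variants))
    sift_score = rng.random(n_variants)

    catalog: list[VariantCatalogEntry] = []
    predictions: list[PredictionRecord] = []
    for i in range(n_variants):
        e = ens[int(exon_idx[i])]
        chrom, pos = e.chrom, e.start + int(within[i])
        fk_rs = -1
        if "refseq" in exons_by_source:
            fk_rs = _resolve_region_fk(exons_by_source["refseq"], chrom, pos)
        vid = i + 1
        predictions.append(PredictionRecord(
            prediction_fk=vid, fathmm_damaging=bool(damaging[i]),
            fathmm_score=round(float(fathmm_score[i]), 6),
            sift_score=round(float(sift_score[i]), 6),
            mean_dp=round(float(mean_dp[i]), 3)))
        catalog.append(VariantCatalogEntry(
            variant_id=vid, chrom=chrom, pos=pos,
            ref=str(_BASES[ref_idx[i]]), alt=str(_BASES[alt_idx[i]]),
            af={g: float(af_matrix[i, j]) for j, g in enumerate(groups)},
            fathmm_damaging=bool(damaging[i]),
            mean_dp=round(float(mean_dp[i]), 3),
            prediction_fk=vid, gene_symbol=e.gene_symbol,
            region_fk_ens=e.region_id, region_fk_rs=fk_rs))
    catalog.sort(key=lambda v: (CHROM_RANK[v.chrom], v.pos))
    return catalog, predictions


# ---------------------------------------------------------------------------
# Catalog (de)serialization — the catalog is generator state, not a warehouse
# table; it round-trips through a flat frame so the CLI can split generation
# of the reference world from cohort simulation.

def catalog_to_frame(catalog: Sequence[VariantCatalogEntry]):
    import pandas as pd

    rows = []
    for v in catalog:
        row = {"variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
               "ref": v.ref, "alt": v.alt, "fathmm_damaging": v.fathmm_damaging,
               "mean_dp": v.mean_dp, "prediction_fk": v.prediction_fk,
               "gene_symbol": v.gene_symbol, "region_fk_ens": v.region_fk_ens,
               "region_fk_rs": v.region_fk_rs}
        for g in EthnicGroup:
            row[f"af_{g.value}"] = v.af[g]
        rows.append(row)
    cols = ["variant_id", "chrom", "pos", "ref", "alt",
            *[f"af_{g.value}" for g in EthnicGroup], "fathmm_damaging",
            "mean_dp", "prediction_fk", "gene_symbol", "region_fk_ens", "region_fk_rs"]
    return pd.DataFrame(rows, columns=cols)


def catalog_from_frame(df) -> list[VariantCatalogEntry]:
    return [
        VariantCatalogEntry(
            variant_id=int(r.variant_id), chrom=str(r.chrom), pos=int(r.pos),
            ref=str(r.ref), alt=str(r.alt),
            af={g: float(getattr(r, f"af_{g.value}")) for g in EthnicGroup},
            fathmm_damaging=bool(r.fathmm_damaging), mean_dp=float(r.mean_dp),
            prediction_fk=int(r.prediction_fk), gene_symbol=str(r.gene_symbol),
            region_fk_ens=int(r.region_fk_ens), region_fk_rs=int(r.region_fk_rs))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Diseases

def generate_diseases(n_diseases: int, seed: int) -> list[DiseaseEntry]:
    """OMIM-like disease list with unique synthetic six-digit identifiers."""
    if n_diseases < 0:
        raise ValueError("n_diseases must be >= 0")
    if n_diseases == 0:
        return []
    rng = _child_rng(seed, "diseases")
    omim = rng.choice(np.arange(100_000, 1_000_000), size=n_diseases, replace=False)
    return [
        DiseaseEntry(disease_id=i + 1, omim_id=str(int(omim[i])),
                     name=f"Synthetic disorder {int(omim[i])}")
        for i in range(n_diseases)
    ]
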