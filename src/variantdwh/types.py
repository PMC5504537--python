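"""Core domain types shared across the warehouse modules.

The object model mirrors a star schema for genomic variant calls: a fact
record per non-reference genotype call, and dimensions for geography,
gene models (two annotation sources), diseases and variant-level
predictions.  Types are plain dataclasses; bulk operations convert them
to pandas DataFrames via the ``*_to_frame`` helpers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import pandas as pd

#: Chromosome labels in canonical sort order (autosomes, then X, Y).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Canonical rank used wherever records are sorted by chromosome.
CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Synthetic chromosome lengths (bp).  Desk-scale stand-ins roughly
#: proportional to the human karyotype; only relative sizes matter.
CHROM_LENGTHS: dict[str, int] = {
    **{str(i): 25_000_000 - (i - 1) * 900_000 for i in range(1, 23)},
    "X": 16_000_000,
    "Y": 6_000_000,
}


class EthnicGroup(str, enum.Enum):
    """The four ethnic groups of the cohort (continental ancestry)."""

    EUR = "EUR"
    AMR = "AMR"
    EAS = "EAS"
    AFR = "AFR"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.value


#: 1:1 mapping of world region to ethnic group.
REGION_TO_GROUP: dict[str, EthnicGroup] = {
    "Europe": EthnicGroup.EUR,
    "Americas": EthnicGroup.AMR,
    "Asia": EthnicGroup.EAS,
    "Africa": EthnicGroup.AFR,
}

GROUP_TO_REGION: dict[EthnicGroup, str] = {g: r for r, g in REGION_TO_GROUP.items()}


class Genotype(str, enum.Enum):
    """Diploid genotype call; the fact table stores only non-reference calls."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"

    @property
    def vcf_code(self) -> str:
        return {"HOM_REF": "0/0", "HET": "0/1", "HOM_ALT": "1/1"}[self.value]


class StorageLevel(str, enum.Enum):
    """Physical storage levels of the warehouse.

    ``raw``          - fact table at genotype-call granularity.
    ``aggr``         - genotype counts per (variant, geography, disease),
                       dimension FKs retained.
    ``aggr_denorm``  - the aggregated table with dimensions pre-joined.
    ``cube``         - materialized group-by results along declared
                       hierarchies (answers only its precomputed patterns).
    """

    RAW = "raw"
    AGGR = "aggr"
    AGGR_DENORM = "aggr_denorm"
    CUBE = "cube"


@dataclass(frozen=True)
class GeographyEntry:
    geo_id: int
    country: str
    subregion: str
    region: str
    population: int
    ethnic_group: EthnicGroup


@dataclass(frozen=True)
class GenomicRegionEntry:
    """One exon of one transcript of one gene, for one annotation source."""

    region_id: int
    source: str  # "ensembl" | "refseq"
    gene_symbol: str
    transcript_id: str
    exon_number: int
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    is_canonical: bool
    is_merged: bool


@dataclass(frozen=True)
class DiseaseEntry:
    disease_id: int
    omim_id: str  # synthetic six-digit label
    name: str


@dataclass(frozen=True)
class PredictionRecord:
    """Variant-level annotation row (dbNSFP-like): deleteriousness call,
    placeholder predictor scores and the site mean depth of coverage."""

    prediction_fk: int
    fathmm_damaging: bool
    fathmm_score: float
    sift_score: float
    mean_dp: float


@dataclass(frozen=True)
class VariantCatalogEntry:
    """One candidate SNV with per-group allele frequencies."""

    variant_id: int
    chrom: str
    pos: int
    ref: str
    alt: str
    af: dict[EthnicGroup, float]
    fathmm_damaging: bool
    mean_dp: float
    prediction_fk: int
    gene_symbol: str = ""
    region_fk_ens: int = -1
    region_fk_rs: int = -1


@dataclass(frozen=True)
class SampleRecord:
    sample_id: int
    ethnic_group: EthnicGroup
    geo_fk: int
    disease_fk: Optional[int] = None


@dataclass(frozen=True)
class FactRecord:
    """One non-reference genotype call (the fact-table row)."""

    sample_id: int
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype
    dp: int
    ad_alt: int
    geo_fk: int
    region_fk_ens: int
    region_fk_rs: int
    disease_fk: Optional[int]
    prediction_fk: int
    gl: Optional[float] = None  # genotype likelihood placeholder, never simulated


@dataclass
class World:
    """An in-memory instance of the whole synthetic reference world plus,
    optionally, a simulated cohort.  The query oracles run against this."""

    geography: list[GeographyEntry] = field(default_factory=list)
    gene_model_ens: list[GenomicRegionEntry] = field(default_factory=list)
    gene_model_rs: list[GenomicRegionEntry] = field(default_factory=list)
    diseases: list[DiseaseEntry] = field(default_factory=list)
    catalog: list[VariantCatalogEntry] = field(default_factory=list)
    predictions: list[PredictionRecord] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)
    facts: list[FactRecord] = field(default_factory=list)


def _records_to_frame(records: Iterable, enum_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    rows = [vars(r) if not hasattr(r, "__dataclass_fields__") else
            {f.name: getattr(r, f.name) for f in fields(r)} for r in records]
    df = pd.DataFrame(rows)
    for col in enum_cols:
        if col in df.columns:
            df[col] = df[col].map(lambda v: v.value if isinstance(v, enum.Enum) else v)
    return df


def geography_to_frame(entries: Iterable[GeographyEntry]) -> pd.DataFrame:
    df = _records_to_frame(entries, ("ethnic_group",))
    if df.empty:
        df = pd.DataFrame(columns=["geo_id", "country", "subregion", "region",
                                   "population", "ethnic_group"])
    return df


def gene_model_to_frame(entries: Iterable[GenomicRegionEntry]) -> pd.DataFrame:
    df = _records_to_frame(entries)
    if df.empty:
        df = pd.DataFrame(columns=["region_id", "source", "gene_symbol", "transcript_id",
                                   "exon_number", "chrom", "start", "end",
                                   "is_canonical", "is_merged"])
    return df


def diseases_to_frame(entries: Iterable[DiseaseEntry]) -> pd.DataFrame:
    df = _records_to_frame(entries)
    if df.empty:
        df = pd.DataFrame(columns=["disease_id", "omim_id", "name"])
    return df


def predictions_to_frame(entries: Iterable[PredictionRecord]) -> pd.DataFrame:
    df = _records_to_frame(entries)
    if df.empty:
        df = pd.DataFrame(columns=["prediction_fk", "fathmm_damaging", "fathmm_score",
                                   "sift_score", "mean_dp"])
    return df


def samples_to_frame(entries: Iterable[SampleRecord]) -> pd.DataFrame:
    df = _records_to_frame(entries, ("ethnic_group",))
    if df.empty:
        df = pd.DataFrame(columns=["sample_id", "ethnic_group", "geo_fk", "disease_fk"])
    return df


FACT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "genotype", "dp",
                "ad_alt", "geo_fk", "region_fk_ens", "region_fk_rs",
                "disease_fk", "prediction_fk", "gl"]


def facts_to_frame(records: Iterable[FactRecord]) -> pd.DataFrame:
    df = _records_to_frame(records, ("genotype",))
    if df.empty:
        df = pd.DataFrame(columns=FACT_COLUMNS)
    return df[FACT_COLUMNS]
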