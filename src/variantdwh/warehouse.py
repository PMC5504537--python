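"""Star-schema materialization at the physical storage levels.

A warehouse instance is a directory of columnar tables (Parquet by
default, ORC optional; codec configurable) plus a ``catalog.json``
registry mapping table names to files — a desk-scale stand-in for a
Hive metastore.  Storage levels:

``raw``
    ``fact`` — one row per non-reference genotype call, partitioned by
    chromosome and sorted by (chrom, ref, alt, sample_id) within
    partitions to aid compression of low-cardinality columns.
``aggr``
    ``fact_agg_counts`` — het/hom-alt counts per (variant, country,
    disease), dimension FKs retained, plus an artificial surrogate key.
``aggr_denorm``
    ``fact_agg_counts_dims`` — the aggregated table with every FK
    replaced by the dimension attributes (pre-joined wide table).

The sample registry (``dim_sample``) and a small per-country sample
count table (``sample_counts_geo``) are stored alongside: the fact table
holds only variant sites, so allele-frequency denominators must come
from the registry, not from fact rows.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.orc
import pyarrow.parquet as pq

from .types import (
    CHROM_RANK,
    FACT_COLUMNS,
    FactRecord,
    GeographyEntry,
    SampleRecord,
    World,
    diseases_to_frame,
    facts_to_frame,
    gene_model_to_frame,
    geography_to_frame,
    predictions_to_frame,
    samples_to_frame,
)

logger = logging.getLogger(__name__)

_PARQUET_CODECS = {"none": "NONE", "snappy": "SNAPPY", "gzip": "GZIP"}
_ORC_CODECS = {"none": "UNCOMPRESSED", "snappy": "SNAPPY", "gzip": "ZLIB"}

DIMENSION_TABLES = {
    "dim_geography", "dim_genomic_position_ensembl", "dim_genomic_position_refseq",
    "dim_disease", "dim_variant_predictions",
}


class Warehouse:
    """A directory of registered columnar tables with a JSON catalog."""

    def __init__(self, root: str | Path, fmt: str = "parquet", codec: str = "snappy"):
        if fmt not in ("parquet", "orc"):
            raise ValueError(f"unsupported format {fmt!r}")
        if codec not in _PARQUET_CODECS:
            raise ValueError(f"unsupported codec {codec!r}")
        self.root = Path(root)
        self.fmt = fmt
        self.codec = codec
        self.root.mkdir(parents=True, exist_ok=True)
        self._catalog_path = self.root / "catalog.json"
        if self._catalog_path.exists():
            meta = json.loads(self._catalog_path.read_text())
            self.fmt = meta.get("format", fmt)
            self.codec = meta.get("codec", codec)
            self._tables: dict[str, dict] = meta.get("tables", {})
        else:
            self._tables = {}
            self._flush()

    # -- catalog ----------------------------------------------------------
    def _flush(self) -> None:
        meta = {"format": self.fmt, "codec": self.codec, "tables": self._tables}
        self._catalog_path.write_text(json.dumps(meta, indent=2, sort_keys=True))

    @property
    def table_names(self) -> list[str]:
        return sorted(self._tables)

    def has_table(self, name: str) -> bool:
        return name in self._tables

    # -- IO ---------------------------------------------------------------
    def _write_file(self, df: pd.DataFrame, path: Path) -> None:
        table = pa.Table.from_pandas(df, preserve_index=False)
        if self.fmt == "parquet":
            pq.write_table(table, path, compression=_PARQUET_CODECS[self.codec])
        else:
            pa.orc.write_table(table, path, compression=_ORC_CODECS[self.codec])

    def _read_file(self, path: Path) -> pd.DataFrame:
        if self.fmt == "parquet":
            return pq.read_table(path).to_pandas()
        return pa.orc.read_table(str(path)).to_pandas()

    def write_table(self, name: str, df: pd.DataFrame,
                    partition_by: Optional[str] = None) -> None:
        """Write and register one table, optionally one file per partition value."""
        ext = "parquet" if self.fmt == "parquet" else "orc"
        schema_cols = list(df.columns)
        if partition_by is None:
            rel = f"{name}.{ext}"
            self._write_file(df, self.root / rel)
            files = [rel]
        else:
            tdir = self.root / name
            tdir.mkdir(exist_ok=True)
            files = []
            keys = sorted(df[partition_by].unique(),
                          key=lambda c: CHROM_RANK.get(str(c), 99))
            for key in keys:
                rel = f"{name}/{partition_by}={key}.{ext}"
                self._write_file(df[df[partition_by] == key], self.root / rel)
                files.append(rel)
        self._tables[name] = {"files": files, "columns": schema_cols,
                              "partition_by": partition_by}
        self._flush()

    def read_table(self, name: str) -> pd.DataFrame:
        if name not in self._tables:
            raise KeyError(f"table {name!r} not registered in {self._catalog_path}")
        entry = self._tables[name]
        parts = [self._read_file(self.root / rel) for rel in entry["files"]]
        if not parts:
            return pd.DataFrame(columns=entry["columns"])
        return pd.concat(parts, ignore_index=True)[entry["columns"]]


# ---------------------------------------------------------------------------
# builders

def build_reference(wh: Warehouse, world: World) -> None:
    """Write all dimension tables of the synthetic reference world."""
    wh.write_table("dim_geography", geography_to_frame(world.geography))
    wh.write_table("dim_genomic_position_ensembl", gene_model_to_frame(world.gene_model_ens))
    wh.write_table("dim_genomic_position_refseq", gene_model_to_frame(world.gene_model_rs))
    wh.write_table("dim_disease", diseases_to_frame(world.diseases))
    wh.write_table("dim_variant_predictions", predictions_to_frame(world.predictions))


def build_sample_registry(wh: Warehouse, samples: Sequence[SampleRecord],
                          geography: Sequence[GeographyEntry]) -> None:
    """Write the sample registry and the per-country sample-count helper."""
    sdf = samples_to_frame(samples)
    sdf["disease_fk"] = sdf["disease_fk"].astype("Int64")
    wh.write_table("dim_sample", sdf)
    counts = sdf.groupby("geo_fk").size().rename("n_samples").reset_index()
    gdf = geography_to_frame(geography)
    merged = counts.merge(gdf, left_on="geo_fk", right_on="geo_id", validate="1:1")
    wh.write_table("sample_counts_geo",
                   merged[["geo_fk", "country", "subregion", "region",
                           "ethnic_group", "n_samples"]])


def _fact_frame(stream: Iterable[FactRecord]) -> pd.DataFrame:
    df = facts_to_frame(stream)
    df["disease_fk"] = df["disease_fk"].astype("Int64")
    df["gl"] = df["gl"].astype("float64")
    return df


def build_fact(wh: Warehouse, fact_stream: Iterable[FactRecord]) -> tuple[int, int]:
    """Materialize the raw fact table; returns (written, rejected) row counts.

    Records whose FKs do not resolve against the registered dimensions are
    rejected (logged and counted) rather than failing the whole load.
    """
    df = _fact_frame(fact_stream)
    rejected = 0
    if not df.empty:
        checks = [
            ("geo_fk", "dim_geography", "geo_id"),
            ("region_fk_ens", "dim_genomic_position_ensembl", "region_id"),
            ("region_fk_rs", "dim_genomic_position_refseq", "region_id"),
            ("prediction_fk", "dim_variant_predictions", "prediction_fk"),
            ("disease_fk", "dim_disease", "disease_id"),
        ]
        ok = pd.Series(True, index=df.index)
        for col, table, key in checks:
            if not wh.has_table(table):
                continue
            valid = set(wh.read_table(table)[key])
            col_ok = df[col].isna() | df[col].isin(valid)
            bad = int((~col_ok).sum())
            if bad:
                logger.warning("rejecting %d fact records with unresolvable %s", bad, col)
            ok &= col_ok
        rejected = int((~ok).sum())
        df = df[ok]
        df = df.sort_values(["chrom", "ref", "alt", "sample_id", "pos"],
                            key=lambda s: s.map(CHROM_RANK) if s.name == "chrom" else s,
                            kind="mergesort").reset_index(drop=True)
    wh.write_table("fact", df, partition_by="chrom" if not df.empty else None)
    return len(df), rejected


def build_agg_counts(wh: Warehouse) -> int:
    """Level-2 table: genotype counts per (variant, country, disease)."""
    raw = wh.read_table("fact")
    keys = ["chrom", "pos", "ref", "alt", "geo_fk", "disease_fk",
            "region_fk_ens", "region_fk_rs", "prediction_fk"]
    if raw.empty:
        agg = pd.DataFrame(columns=["agg_id"] + keys + ["n_het", "n_homalt"])
    else:
        tmp = raw.assign(n_het=(raw["genotype"] == "HET").astype("int64"),
                         n_homalt=(raw["genotype"] == "HOM_ALT").astype("int64"))
        agg = tmp.groupby(keys, dropna=False)[["n_het", "n_homalt"]].sum().reset_index()
        agg = agg.sort_values(keys, key=lambda s: s.map(CHROM_RANK) if s.name == "chrom" else s,
                              kind="mergesort").reset_index(drop=True)
        agg.insert(0, "agg_id", np.arange(1, len(agg) + 1))  # artificial surrogate key
    wh.write_table("fact_agg_counts", agg)
    return len(agg)


def build_agg_denorm(wh: Warehouse) -> int:
    """Level-3 table: level 2 with every FK replaced by dimension attributes."""
    agg = wh.read_table("fact_agg_counts")
    geo = wh.read_table("dim_geography")
    dis = wh.read_table("dim_disease")
    pred = wh.read_table("dim_variant_predictions")
    gens = wh.read_table("dim_genomic_position_ensembl")
    genr = wh.read_table("dim_genomic_position_refseq")

    def _join(df, dim, left, right, cols, suffix, required=True):
        dim = dim[[right] + cols].rename(columns={c: f"{c}{suffix}" for c in cols})
        out = df.merge(dim, how="left", left_on=left, right_on=right)
        if required and not df.empty:
            missing = out[f"{cols[0]}{suffix}"].isna() & df[left].notna()
            if missing.any():
                raise ValueError(f"dangling {left} in level-2 table")
        if right != left:
            out = out.drop(columns=[right])
        return out

    out = agg.copy()
    out = _join(out, geo, "geo_fk", "geo_id",
                ["country", "subregion", "region", "ethnic_group"], "")
    out = _join(out, dis.rename(columns={"omim_id": "disease_omim", "name": "disease_name"}),
                "disease_fk", "disease_id", ["disease_omim", "disease_name"], "",
                required=False)
    out = _join(out, pred, "prediction_fk", "prediction_fk",
                ["fathmm_damaging", "fathmm_score", "sift_score", "mean_dp"], "")
    gcols = ["gene_symbol", "transcript_id", "exon_number", "start", "end",
             "is_canonical", "is_merged"]
    out = _join(out, gens.rename(columns={"region_id": "_rid_ens"}),
                "region_fk_ens", "_rid_ens", gcols, "_ens")
    out = _join(out, genr.rename(columns={"region_id": "_rid_rs"}),
                "region_fk_rs", "_rid_rs", gcols, "_rs")
    out = out.drop(columns=["geo_fk", "disease_fk", "prediction_fk",
                            "region_fk_ens", "region_fk_rs"])
    wh.write_table("fact_agg_counts_dims", out)
    return len(out)


def build_all(root: str | Path, world: World, fmt: str = "parquet",
              codec: str = "snappy") -> Warehouse:
    """Build every storage level of a warehouse from an in-memory world."""
    wh = Warehouse(root, fmt=fmt, codec=codec)
    build_reference(wh, world)
    build_sample_registry(wh, world.samples, world.geography)
    build_fact(wh, world.facts)
    build_agg_counts(wh)
    build_agg_denorm(wh)
    return wh


def allele_count_by_level(wh: Warehouse) -> dict[str, int]:
    """Total alt-allele count (n_het + 2*n_homalt) at every stored level."""
    out = {}
    fact = wh.read_table("fact")
    out["raw"] = int((fact["genotype"] == "HET").sum() + 2 * (fact["genotype"] == "HOM_ALT").sum())
    for name, level in (("fact_agg_counts", "aggr"), ("fact_agg_counts_dims", "aggr_denorm")):
        if wh.has_table(name):
            t = wh.read_table(name)
            out[level] = int(t["n_het"].sum() + 2 * t["n_homalt"].sum())
    return out
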