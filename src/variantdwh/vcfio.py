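"""Per-sample VCF 4.2 export and re-import (GT:DP:AD), via pysam."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .types import CHROMOSOMES, CHROM_LENGTHS, CHROM_RANK, Genotype

__all__ = ["export_vcf", "import_vcf"]

_GT_TUPLES = {Genotype.HET: (0, 1), Genotype.HOM_ALT: (1, 1)}


def _build_header(sample_name: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in CHROMOSOMES:
        header.contigs.add(chrom, length=CHROM_LENGTHS[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample_name)
    return header


def export_vcf(fact: pd.DataFrame, sample_id: int, path: str | Path,
               known_samples: Sequence[int] | None = None) -> int:
    """Write one sample's fact records as an uncompressed VCF 4.2 file.

    Returns the number of data lines written.  ``known_samples`` is the
    sample registry; a registered sample with zero fact records yields a
    header-only VCF, while an unregistered sample is an error.
    """
    sub = fact[fact["sample_id"] == sample_id]
    if sub.empty:
        registry = set(known_samples) if known_samples is not None else set(fact["sample_id"])
        if sample_id not in registry:
            raise KeyError(f"unknown sample {sample_id}")
    sub = sub.sort_values(["chrom", "pos"],
                          key=lambda s: s.map(CHROM_RANK) if s.name == "chrom" else s,
                          kind="mergesort")
    header = _build_header(f"S{sample_id}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in sub.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom, start=int(row.pos) - 1, stop=int(row.pos),
                alleles=(row.ref, row.alt))
            gt = Genotype(row.genotype)
            rec.samples[0]["GT"] = _GT_TUPLES[gt]
            rec.samples[0]["DP"] = int(row.dp)
            rec.samples[0]["AD"] = (int(row.dp) - int(row.ad_alt), int(row.ad_alt))
            vcf.write(rec)
    return len(sub)


def import_vcf(path: str | Path) -> pd.DataFrame:
    """Read a single-sample VCF back into (chrom, pos, ref, alt, genotype, dp, ad_alt)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        (sample_name,) = vcf.header.samples
        for rec in vcf:
            call = rec.samples[sample_name]
            gt = call["GT"]
            genotype = Genotype.HET if tuple(gt) == (0, 1) else Genotype.HOM_ALT
            ad = call["AD"]
            rows.append({
                "chrom": rec.contig, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alts[0], "genotype": genotype.value,
                "dp": int(call["DP"]) if call["DP"] is not None else 0,
                "ad_alt": int(ad[1]) if ad is not None and ad[1] is not None else 0,
            })
    cols = ["chrom", "pos", "ref", "alt", "genotype", "dp", "ad_alt"]
    return pd.DataFrame(rows, columns=cols)
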