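"""Brute-force reference implementations of the query suite.

Each oracle computes the query definition directly over the in-memory
:class:`~variantdwh.types.World` with loops and dictionaries — no SQL,
no warehouse tables — and returns a DataFrame with the same columns and
canonical ordering as the engine path.  These are the correctness
references the benchmark harness verifies engines against.

Conventions shared with the SQL path (fixed, not tuned per engine):

* AF denominator is 2 x the number of registry samples in the group;
  fact rows are variant sites only, absent rows count as 0/0.
* A variant "absent from a group" still yields a row with AF 0.
* Region membership is point containment pos in [start, end]; the
  A-subqueries use canonical transcripts, the B-subqueries use the exons
  of merged transcripts.
* Depth quantiles use linear interpolation between closest ranks over
  the site mean depth of every contributing genotype call.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ..types import CHROM_RANK, World
from .runner import canonicalize

__all__ = ["oracle"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _geo(world: World) -> dict:
    return {g.geo_id: g for g in world.geography}


def _group_of_sample(world: World, attr: str) -> dict[int, str]:
    geo = _geo(world)
    return {s.sample_id: getattr(geo[s.geo_fk], attr) for s in world.samples}


def _observed_variants(world: World) -> list[tuple]:
    seen = {(f.chrom, f.pos, f.ref, f.alt) for f in world.facts}
    return sorted(seen, key=lambda v: (CHROM_RANK[v[0]], v[1], v[2], v[3]))


def _containing_regions(world: World, source: str, detail: str) -> dict:
    """(chrom, pos) -> list of group keys for every observed variant position.

    detail='transcript': canonical transcripts, key (gene, transcript).
    detail='exon': merged-transcript exons, key (gene, transcript, exon_number).
    """
    model = world.gene_model_ens if source == "ensembl" else world.gene_model_rs
    want_canonical = detail == "transcript"
    entries = [e for e in model if (e.is_canonical if want_canonical else e.is_merged)]
    positions = {(f.chrom, f.pos) for f in world.facts}
    out: dict[tuple, list[tuple]] = {}
    for chrom, pos in positions:
        keys = []
        for e in entries:
            if e.chrom == chrom and e.start <= pos <= e.end:
                if want_canonical:
                    keys.append((e.gene_symbol, e.transcript_id))
                else:
                    keys.append((e.gene_symbol, e.transcript_id, e.exon_number))
        out[(chrom, pos)] = keys
    return out


def _q1(world: World, geo_attr: str) -> pd.DataFrame:
    sample_group = _group_of_sample(world, geo_attr)
    denom = Counter(sample_group.values())
    counts: dict[tuple, list[int]] = defaultdict(lambda: [0, 0])
    for f in world.facts:
        c = counts[(f.chrom, f.pos, f.ref, f.alt, sample_group[f.sample_id])]
        if f.genotype.value == "HET":
            c[0] += 1
        else:
            c[1] += 1
    rows = []
    for var in _observed_variants(world):
        for grp in sorted(denom):
            h, hom = counts.get(var + (grp,), (0, 0))
            rows.append({"chrom": var[0], "pos": var[1], "ref": var[2], "alt": var[3],
                         geo_attr: grp, "af": (h + 2 * hom) / (2.0 * denom[grp])})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", geo_attr, "af"])


def _variant_allele_counts(world: World) -> dict[tuple, int]:
    ac: dict[tuple, int] = defaultdict(int)
    for f in world.facts:
        ac[(f.chrom, f.pos, f.ref, f.alt)] += 1 if f.genotype.value == "HET" else 2
    return ac


def _q2(world: World, af_cutoff: float, source: str, detail: str,
        damaging_only: bool = True) -> pd.DataFrame:
    n_total = len(world.samples)
    pred = {p.prediction_fk: p for p in world.predictions}
    var_pred = {(f.chrom, f.pos, f.ref, f.alt): f.prediction_fk for f in world.facts}
    regions = _containing_regions(world, source, detail)
    agg: dict[tuple, list] = defaultdict(lambda: [0, 0.0])
    for var, ac in _variant_allele_counts(world).items():
        af = ac / (2.0 * n_total)
        if af >= af_cutoff:
            continue
        if damaging_only and not pred[var_pred[var]].fathmm_damaging:
            continue
        for key in regions[(var[0], var[1])]:
            agg[key][0] += 1
            agg[key][1] += af
    cols = (["gene_symbol", "transcript_id"] if detail == "transcript"
            else ["gene_symbol", "transcript_id", "exon_number"])
    rows = [dict(zip(cols, k), n_variants=v[0], cum_af=v[1]) for k, v in agg.items()]
    return pd.DataFrame(rows, columns=cols + ["n_variants", "cum_af"])


def _q3(world: World, omim_id: str, source: str, detail: str) -> pd.DataFrame:
    disease_ids = {d.omim_id: d.disease_id for d in world.diseases}
    target = disease_ids.get(str(omim_id))
    regions = _containing_regions(world, source, detail)
    agg: Counter = Counter()
    for f in world.facts:
        if f.disease_fk != target or target is None:
            continue
        for key in regions[(f.chrom, f.pos)]:
            agg[key] += 1
    cols = (["gene_symbol", "transcript_id"] if detail == "transcript"
            else ["gene_symbol", "transcript_id", "exon_number"])
    rows = [dict(zip(cols, k), n_records=n) for k, n in agg.items()]
    return pd.DataFrame(rows, columns=cols + ["n_records"])


def _q4(world: World, source: str, detail: str) -> pd.DataFrame:
    pred_dp = {p.prediction_fk: p.mean_dp for p in world.predictions}
    regions = _containing_regions(world, source, detail)
    values: dict[tuple, list[float]] = defaultdict(list)
    for f in world.facts:
        dp = pred_dp[f.prediction_fk]
        for key in regions[(f.chrom, f.pos)]:
            values[key].append(dp)
    cols = (["gene_symbol", "transcript_id"] if detail == "transcript"
            else ["gene_symbol", "transcript_id", "exon_number"])
    out_cols = ["dp_min", "dp_q25", "dp_median", "dp_q75", "dp_max"]
    rows = []
    for key, vals in values.items():
        qs = np.quantile(np.array(vals, dtype=float),
                         [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
        rows.append(dict(zip(cols, key), **dict(zip(out_cols, map(float, qs)))))
    return pd.DataFrame(rows, columns=cols + out_cols)


def _q5(world: World, sample_id: int, chrom: str, start: int, end: int) -> pd.DataFrame:
    rows = [{"chrom": f.chrom, "pos": f.pos, "ref": f.ref, "alt": f.alt,
             "genotype": f.genotype.value, "dp": f.dp, "ad_alt": f.ad_alt}
            for f in world.facts
            if f.sample_id == sample_id and f.chrom == chrom and start <= f.pos <= end]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "genotype", "dp", "ad_alt"])


def _q6(world: World, collapse: str) -> pd.DataFrame:
    c: Counter = Counter()
    for f in world.facts:
        ref, alt = f.ref, f.alt
        if collapse == "strand" and ref in ("A", "G"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        c[f"{ref}>{alt}"] += 1
    rows = [{"substitution": k, "n": n} for k, n in c.items()]
    return pd.DataFrame(rows, columns=["substitution", "n"])


def _q7(world: World) -> pd.DataFrame:
    per_chrom: dict[str, set] = defaultdict(set)
    for f in world.facts:
        per_chrom[f.chrom].add((f.pos, f.ref, f.alt))
    rows = [{"chrom": c, "n_variants": len(s)} for c, s in per_chrom.items()]
    return pd.DataFrame(rows, columns=["chrom", "n_variants"])


def _q8(world: World, sample_id: int, ratio_cutoff: float) -> pd.DataFrame:
    n = sum(1 for f in world.facts
            if f.sample_id == sample_id and f.dp > 0 and f.ad_alt / f.dp > ratio_cutoff)
    return pd.DataFrame([{"n": n}], columns=["n"])


def _q9(world: World, sample_id: int) -> pd.DataFrame:
    n_het = sum(1 for f in world.facts
                if f.sample_id == sample_id and f.chrom == "X" and f.genotype.value == "HET")
    n_hom = sum(1 for f in world.facts
                if f.sample_id == sample_id and f.chrom == "X" and f.genotype.value == "HOM_ALT")
    ratio = n_het / n_hom if n_hom > 0 else None
    return pd.DataFrame([{"n_het": n_het, "n_homalt": n_hom, "het_hom_ratio": ratio}],
                        columns=["n_het", "n_homalt", "het_hom_ratio"])


def _q10(world: World, chrom: str) -> pd.DataFrame:
    c = Counter(f.sample_id for f in world.facts if f.chrom == chrom)
    return pd.DataFrame([{"sample_id": s, "n": n} for s, n in c.items()],
                        columns=["sample_id", "n"])


def _q11(world: World, source: str) -> pd.DataFrame:
    regions = _containing_regions(world, source, "exon")
    genes: dict[int, set] = defaultdict(set)
    for f in world.facts:
        for key in regions[(f.chrom, f.pos)]:
            genes[f.sample_id].add(key[0])
    return pd.DataFrame([{"sample_id": s, "n_genes": len(g)} for s, g in genes.items()],
                        columns=["sample_id", "n_genes"])


def _q12(world: World, sample_id: int) -> pd.DataFrame:
    c = Counter(f.chrom for f in world.facts if f.sample_id == sample_id)
    return pd.DataFrame([{"chrom": ch, "n": n} for ch, n in c.items()],
                        columns=["chrom", "n"])


def oracle(query_id: str, params: Optional[Mapping[str, object]] = None,
           world: World = None) -> pd.DataFrame:
    """Compute one query's reference answer directly from the world."""
    p = dict(params or {})
    source = str(p.get("source", "ensembl"))
    if query_id == "Q1A":
        df = _q1(world, "region")
    elif query_id == "Q1B":
        df = _q1(world, "country")
    elif query_id in ("Q2A", "Q2B"):
        df = _q2(world, float(p.get("af_cutoff", 0.01)), source,
                 "transcript" if query_id == "Q2A" else "exon",
                 damaging_only=str(p.get("damaging_only", "yes")) == "yes")
    elif query_id in ("Q3A", "Q3B"):
        df = _q3(world, str(p["omim_id"]), source,
                 "transcript" if query_id == "Q3A" else "exon")
    elif query_id in ("Q4A", "Q4B"):
        df = _q4(world, source, "transcript" if query_id == "Q4A" else "exon")
    elif query_id == "Q5":
        df = _q5(world, int(p["sample_id"]), str(p["chrom"]), int(p["start"]), int(p["end"]))
    elif query_id == "Q6":
        df = _q6(world, str(p.get("collapse", "no")))
    elif query_id == "Q7":
        df = _q7(world)
    elif query_id == "Q8":
        df = _q8(world, int(p["sample_id"]), float(p.get("ratio_cutoff", 0.9)))
    elif query_id == "Q9":
        df = _q9(world, int(p["sample_id"]))
    elif query_id == "Q10":
        df = _q10(world, str(p["chrom"]))
    elif query_id == "Q11":
        df = _q11(world, source)
    elif query_id == "Q12":
        df = _q12(world, int(p["sample_id"]))
    else:
        raise ValueError(f"unknown query id {query_id!r}")
    return canonicalize(query_id, df)
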