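"""Query registry, SQL rendering and engine execution.

Each query ships as a YAML descriptor (id, applicable storage levels,
parameters, render options, canonical sort order) plus one SQL template
file per level.  Templates use two substitution mechanisms:

* ``{placeholder}`` — render options resolved against a whitelist of
  choices (e.g. which gene-model dimension table to interval-join);
* ``:name`` — value parameters, bound as safely escaped SQL literals.

Engine results are canonicalized (sorted by the descriptor's key
columns) so they can be compared against the pure in-memory oracle.
"""

from __future__ import annotations

import importlib.resources as resources
import re
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from ..engine import EngineAdapter

__all__ = ["QUERY_IDS", "descriptor", "render", "execute", "canonicalize",
           "compare_results", "weighted_quantiles", "UnsupportedQueryError"]

QUERY_IDS = ("Q1A", "Q1B", "Q2A", "Q2B", "Q3A", "Q3B", "Q4A", "Q4B",
             "Q5", "Q6", "Q7", "Q8", "Q9", "Q10", "Q11", "Q12")

DIALECTS = ("sqlite",)

_PARAM_RE = re.compile(r"(?<!:):([a-zA-Z_]\w*)")


class UnsupportedQueryError(ValueError):
    """Raised for an unknown query id or an unsupported (query, level) pair."""


@lru_cache(maxsize=None)
def descriptor(query_id: str) -> dict:
    if query_id not in QUERY_IDS:
        raise UnsupportedQueryError(f"unknown query id {query_id!r}")
    ref = resources.files("variantdwh.queries") / "descriptors" / f"{query_id}.yaml"
    return yaml.safe_load(ref.read_text())


@lru_cache(maxsize=None)
def _template(query_id: str, level: str) -> str:
    ref = resources.files("variantdwh.queries") / "sql" / f"{query_id}.{level}.sql"
    return ref.read_text()


def _sql_literal(value: object) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, str):
        return "'" + value.replace("'", "''") + "'"
    raise TypeError(f"unsupported parameter type {type(value).__name__}")


def render(query_id: str, level: str, params: Optional[Mapping[str, object]] = None,
           dialect: str = "sqlite") -> str:
    """Render one query to fully parameter-substituted SQL text."""
    if dialect not in DIALECTS:
        raise UnsupportedQueryError(f"unknown dialect {dialect!r}")
    desc = descriptor(query_id)
    if level not in desc["levels"]:
        raise UnsupportedQueryError(
            f"query {query_id} is not defined at storage level {level!r} "
            f"(levels: {desc['levels']})")
    params = dict(params or {})
    sql = _template(query_id, level)

    # identifier-level options, validated against the descriptor whitelist
    for opt in desc.get("render_options", []):
        choice = str(params.pop(opt["name"], opt["default"]))
        if choice not in opt["choices"]:
            raise UnsupportedQueryError(
                f"{opt['name']}={choice!r} not in {sorted(opt['choices'])}")
        sql = sql.replace("{%s}" % opt["placeholder"], opt["choices"][choice])

    # value parameters, bound as escaped literals
    values: dict[str, object] = {}
    for p in desc.get("params", []):
        if p["name"] in params:
            values[p["name"]] = params.pop(p["name"])
        elif "default" in p:
            values[p["name"]] = p["default"]
        else:
            raise UnsupportedQueryError(
                f"query {query_id} missing required parameter {p['name']!r}")
    if params:
        raise UnsupportedQueryError(f"unexpected parameters {sorted(params)}")

    def _bind(match: re.Match) -> str:
        name = match.group(1)
        if name not in values:
            raise UnsupportedQueryError(f"template references unknown parameter :{name}")
        return _sql_literal(values[name])

    return _PARAM_RE.sub(_bind, sql)


def weighted_quantiles(values: np.ndarray, weights: np.ndarray) -> tuple[float, ...]:
    """min/q25/median/q75/max of ``values`` with integer multiplicities,
    using linear interpolation between closest ranks."""
    expanded = np.repeat(np.asarray(values, dtype=float),
                         np.asarray(weights, dtype=int))
    qs = np.quantile(expanded, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return tuple(float(q) for q in qs)


def _postprocess(desc: dict, df: pd.DataFrame) -> pd.DataFrame:
    post = desc.get("postprocess")
    if not post:
        return df
    if post["kind"] != "weighted_quantiles":  # pragma: no cover - single kind shipped
        raise ValueError(f"unknown postprocess {post['kind']!r}")
    group_by, vcol, wcol = post["group_by"], post["value_col"], post["weight_col"]
    out_cols = ["dp_min", "dp_q25", "dp_median", "dp_q75", "dp_max"]
    rows = []
    for key, grp in df.groupby(group_by, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_by, key),
                         **dict(zip(out_cols, weighted_quantiles(grp[vcol], grp[wcol])))))
    return pd.DataFrame(rows, columns=group_by + out_cols)


def canonicalize(query_id: str, df: pd.DataFrame) -> pd.DataFrame:
    """Sort a result by the query's canonical key columns."""
    sort_by = descriptor(query_id).get("sort_by") or []
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    return df.reset_index(drop=True)


def execute(adapter: EngineAdapter, query_id: str, level: str,
            params: Optional[Mapping[str, object]] = None,
            dialect: str = "sqlite") -> pd.DataFrame:
    """Render, execute on the adapter, post-process and canonicalize."""
    sql = render(query_id, level, params, dialect=dialect)
    columns, rows = adapter.execute_sql(sql)
    df = pd.DataFrame(rows, columns=columns)
    df = _postprocess(descriptor(query_id), df)
    return canonicalize(query_id, df)


def compare_results(query_id: str, a: pd.DataFrame, b: pd.DataFrame,
                    rtol: float = 1e-9, atol: float = 1e-12) -> None:
    """Assert two canonicalized results are equal: exact on keys and counts,
    within relative tolerance on real-valued measures."""
    desc = descriptor(query_id)
    float_cols = set(desc.get("float_cols") or [])
    if list(a.columns) != list(b.columns):
        raise AssertionError(f"{query_id}: column mismatch {list(a.columns)} vs {list(b.columns)}")
    if len(a) != len(b):
        raise AssertionError(f"{query_id}: row count {len(a)} vs {len(b)}")
    for col in a.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if col in float_cols:
            xf = pd.to_numeric(a[col]).astype(float).to_numpy()
            yf = pd.to_numeric(b[col]).astype(float).to_numpy()
            both_nan = np.isnan(xf) & np.isnan(yf)
            ok = both_nan | np.isclose(xf, yf, rtol=rtol, atol=atol)
            if not ok.all():
                i = int(np.nonzero(~ok)[0][0])
                raise AssertionError(
                    f"{query_id}: column {col} differs at row {i}: {xf[i]} vs {yf[i]}")
        else:
            if not all(_eq(u, v) for u, v in zip(x, y)):
                bad = next((u, v) for u, v in zip(x, y) if not _eq(u, v))
                raise AssertionError(f"{query_id}: column {col} differs: {bad[0]} vs {bad[1]}")


def _eq(u: object, v: object) -> bool:
    if pd.isna(u) and pd.isna(v):
        return True
    try:
        return bool(u == v) or float(u) == float(v)
    except (TypeError, ValueError):
        return bool(u == v)
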