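"""Benchmark harness: timed query runs over engine/format/level combinations.

The harness reads a YAML configuration describing which queries to run,
against which warehouses (format x codec), at which storage levels, with
how many repetitions; executes every combination; and records one timing
row per run.  Engine failures are recorded as ``failed`` rows and the
run continues (real benchmarks contain failed cells).  With verification
enabled, each run's result cardinality is checked against the pure
oracle, and a diverging engine is flagged — correctness dominates timing.

The harness is strictly read-only over the warehouse.  Timings are
labelled ``warm``; an optional OS cache-purge hook can be installed for
cold-cache measurements but is off by default and platform-specific.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd
import yaml

from .engine import SQLiteAdapter
from .queries import execute, oracle
from .types import World
from .warehouse import Warehouse

__all__ = ["BenchConfig", "QueryJob", "TimingRecord", "load_config", "run",
           "summarize", "plot", "CSV_COLUMNS"]

CSV_COLUMNS = ["query_id", "engine", "format", "codec", "level", "rep",
               "wall_seconds", "row_count", "status"]

_ENGINES: dict[str, Callable[[Warehouse], object]] = {"sqlite": SQLiteAdapter}


@dataclass(frozen=True)
class QueryJob:
    query_id: str
    levels: tuple[str, ...]
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WarehouseRef:
    path: str
    format: str
    codec: str


@dataclass
class BenchConfig:
    warehouses: list[WarehouseRef]
    queries: list[QueryJob]
    engines: list[str] = field(default_factory=lambda: ["sqlite"])
    repetitions: int = 5  # benchmark convention: each query timed several times
    verify: bool = False
    cache_purge_hook: Optional[Callable[[], None]] = None
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for e in self.engines:
            if e not in _ENGINES:
                raise ValueError(f"unknown engine {e!r} (available: {sorted(_ENGINES)})")


@dataclass(frozen=True)
class TimingRecord:
    query_id: str
    engine: str
    format: str
    codec: str
    level: str
    rep: int
    wall_seconds: Optional[float]  # None for failed runs
    row_count: Optional[int]
    status: str  # "ok" | "failed" | "diverged"


def load_config(path: str | Path) -> BenchConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return BenchConfig(
        warehouses=[WarehouseRef(**w) for w in raw["warehouses"]],
        queries=[QueryJob(q["id"], tuple(q.get("levels", ["raw"])),
                          dict(q.get("params", {}))) for q in raw["queries"]],
        engines=list(raw.get("engines", ["sqlite"])),
        repetitions=int(raw.get("repetitions", 5)),
        verify=bool(raw.get("verify", False)),
        out=raw.get("out"),
    )


def run(config: BenchConfig, world: Optional[World] = None) -> list[TimingRecord]:
    """Execute every (query, engine, warehouse, level) combination
    ``repetitions`` times; write a CSV if ``config.out`` is set."""
    if config.verify and world is None:
        raise ValueError("verification requires the in-memory world for the oracle")
    records: list[TimingRecord] = []
    for whref in config.warehouses:
        wh = Warehouse(whref.path, fmt=whref.format, codec=whref.codec)
        for engine_name in config.engines:
            adapter = _ENGINES[engine_name](wh)
            adapter.open()
            try:
                for job in config.queries:
                    for level in job.levels:
                        expected = None
                        if config.verify:
                            expected = len(oracle(job.query_id, job.params, world))
                        for rep in range(1, config.repetitions + 1):
                            if config.cache_purge_hook is not None:
                                config.cache_purge_hook()
                            t0 = time.perf_counter()
                            try:
                                result = execute(adapter, job.query_id, level, job.params)
                            except Exception:
                                records.append(TimingRecord(
                                    job.query_id, engine_name, whref.format,
                                    whref.codec, level, rep, None, None, "failed"))
                                continue
                            elapsed = time.perf_counter() - t0
                            status = "ok"
                            if expected is not None and len(result) != expected:
                                status = "diverged"
                            records.append(TimingRecord(
                                job.query_id, engine_name, whref.format,
                                whref.codec, level, rep, elapsed, len(result), status))
            finally:
                adapter.close()
    if config.out:
        out = Path(config.out)
        out.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out / "timings.csv", index=False)
    return records


def records_to_frame(records: Sequence[TimingRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=CSV_COLUMNS)
    return df


def summarize(records: Sequence[TimingRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max wall time per (query, engine, format, codec, level).

    All-failed combinations are flagged and excluded from the means;
    partially failed combinations report statistics over successful runs.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["query_id", "engine", "format", "codec", "level",
                                     "n_runs", "n_failed", "mean_seconds",
                                     "min_seconds", "max_seconds", "all_failed"])
    keys = ["query_id", "engine", "format", "codec", "level"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        ok = grp[grp["status"] == "ok"]["wall_seconds"].astype(float)
        rows.append(dict(
            zip(keys, key),
            n_runs=len(grp),
            n_failed=int((grp["status"] != "ok").sum()),
            mean_seconds=float(ok.mean()) if len(ok) else float("nan"),
            min_seconds=float(ok.min()) if len(ok) else float("nan"),
            max_seconds=float(ok.max()) if len(ok) else float("nan"),
            all_failed=bool(len(ok) == 0),
        ))
    return pd.DataFrame(rows)


def _family(query_id: str) -> str:
    return query_id.rstrip("AB") if query_id[1] in "1234" and len(query_id) <= 3 else "Q5-Q12"


def build_figure(summary: pd.DataFrame, title: str):
    """Grouped bar chart of mean times with min/max error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[~summary["all_failed"]].reset_index(drop=True)
    labels = [f"{r.query_id}\n{r.level}\n{r.format}/{r.codec}" for r in sub.itertuples()]
    means = sub["mean_seconds"].to_numpy()
    yerr = [means - sub["min_seconds"].to_numpy(),
            sub["max_seconds"].to_numpy() - means]
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(sub)), 4))
    ax.bar(range(len(sub)), means, yerr=yerr, capsize=3, color="#4878a8")
    ax.set_xticks(range(len(sub)))
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("wall time [s]")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot(summary: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """One figure per query family; error bars show recorded min/max."""
    if summary.empty:
        return {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for family, grp in summary.groupby(summary["query_id"].map(_family)):
        fig = build_figure(grp, f"Query family {family}")
        path = out_dir / f"bench_{family.replace('-', '_')}.png"
        fig.savefig(path, dpi=120)
        paths[family] = path
    return paths
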