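"""Engine adapters: a minimal connection contract over SQL engines.

An adapter exposes ``open() / execute_sql(text) / close()`` — submit SQL
text, receive column names and typed rows — so additional engines (e.g.
remote JDBC-style endpoints) can be plugged into the query runner and
the benchmark harness.  The default adapter is the embedded analytical
engine: an in-memory SQLite database loaded from the warehouse's
columnar files at ``open()`` time.
"""

from __future__ import annotations

import sqlite3
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .warehouse import Warehouse

__all__ = ["EngineAdapter", "SQLiteAdapter", "EngineError"]


class EngineError(RuntimeError):
    """Engine-side failure; carries the SQL that was being executed."""

    def __init__(self, message: str, sql: str):
        super().__init__(f"{message}\n--- rendered SQL ---\n{sql}")
        self.sql = sql


class EngineAdapter(Protocol):  # pragma: no cover - structural contract
    name: str

    def open(self) -> None: ...

    def execute_sql(self, sql: str) -> tuple[list[str], list[tuple]]: ...

    def close(self) -> None: ...


_INDEXES = [
    ("fact", ["sample_id"]),
    ("fact", ["chrom", "pos", "ref", "alt"]),
    ("fact_agg_counts", ["chrom", "pos", "ref", "alt"]),
    ("dim_geography", ["geo_id"]),
    ("dim_disease", ["disease_id"]),
    ("dim_variant_predictions", ["prediction_fk"]),
    ("dim_genomic_position_ensembl", ["chrom", "start", "end"]),
    ("dim_genomic_position_refseq", ["chrom", "start", "end"]),
]


class SQLiteAdapter:
    """Embedded analytical SQL engine over the warehouse's columnar tables."""

    name = "sqlite"

    def __init__(self, warehouse: Warehouse):
        self.warehouse = warehouse
        self._conn: sqlite3.Connection | None = None

    def open(self) -> None:
        if self._conn is not None:
            return
        conn = sqlite3.connect(":memory:")
        for name in self.warehouse.table_names:
            df = self.warehouse.read_table(name).copy()
            for col in df.columns:
                if df[col].dtype == bool:
                    df[col] = df[col].astype(int)
                elif isinstance(df[col].dtype, pd.BooleanDtype):
                    df[col] = df[col].astype("Int64")
            df.to_sql(name, conn, index=False)
        for table, cols in _INDEXES:
            if self.warehouse.has_table(table):
                conn.execute(
                    f"CREATE INDEX IF NOT EXISTS ix_{table}_{'_'.join(cols)} "
                    f"ON {table} ({', '.join(cols)})")
        conn.commit()
        self._conn = conn

    def execute_sql(self, sql: str) -> tuple[list[str], list[tuple]]:
        if self._conn is None:
            self.open()
        try:
            cur = self._conn.execute(sql)
            rows = cur.fetchall()
        except sqlite3.Error as exc:
            raise EngineError(str(exc), sql) from exc
        columns = [d[0] for d in cur.description] if cur.description else []
        return columns, rows

    def close(self) -> None:
        if self._conn is not None:
            self._conn.close()
            self._conn = None

    def __enter__(self) -> "SQLiteAdapter":
        self.open()
        return self

    def __exit__(self, *exc) -> None:
        self.close()
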