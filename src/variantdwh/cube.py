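"""Materialized-aggregate store (OLAP-cube emulation).

The cube precomputes group-by results of the level-3 (aggregated,
denormalized) table along declared dimension hierarchies, e.g.
``region -> subregion -> country`` and ``gene -> transcript -> exon``.
A cuboid exists for every prefix of every declared hierarchy, plus the
apex (grand total).  Lookups whose grouping set is not a declared prefix
raise :class:`CubeReroute`, signalling the caller to fall back to the
level-3 table — mirroring how a distributed cube reroutes unanswerable
queries to the runtime engine.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = ["Cube", "CubeReroute", "DEFAULT_HIERARCHIES", "DEFAULT_MEASURES"]

#: Hierarchies over level-3 columns: geography, and the merged-transcript
#: gene model of the Ensembl source.
DEFAULT_HIERARCHIES: tuple[tuple[str, ...], ...] = (
    ("region", "subregion", "country"),
    ("gene_symbol_ens", "transcript_id_ens", "exon_number_ens"),
)

#: Measure name -> expression over the per-row count columns.
DEFAULT_MEASURES: dict[str, str] = {
    "n_het": "n_het",
    "n_homalt": "n_homalt",
    "n_records": "n_het + n_homalt",
    "allele_count": "n_het + 2*n_homalt",
}


class CubeReroute(Exception):
    """The requested grouping is not a declared cuboid; reroute to level 3."""


class Cube:
    def __init__(
        self,
        level3: pd.DataFrame,
        hierarchies: Sequence[Sequence[str]] = DEFAULT_HIERARCHIES,
        measures: Mapping[str, str] = DEFAULT_MEASURES,
    ):
        self.hierarchies = tuple(tuple(h) for h in hierarchies)
        self.measures = dict(measures)
        self._cuboids: dict[tuple[str, ...], pd.DataFrame] = {}
        values = pd.DataFrame(
            {name: level3.eval(expr) for name, expr in self.measures.items()}
        )
        patterns: set[tuple[str, ...]] = {()}
        for h in self.hierarchies:
            for k in range(1, len(h) + 1):
                patterns.add(tuple(h[:k]))
        for pattern in patterns:
            if pattern == ():
                cub = values.sum().to_frame().T
            else:
                cub = values.groupby([level3[c] for c in pattern]).sum().reset_index()
            self._cuboids[pattern] = cub

    @property
    def declared_patterns(self) -> list[tuple[str, ...]]:
        return sorted(self._cuboids)

    def lookup(
        self,
        group_by: Sequence[str],
        filters: Optional[Mapping[str, object]] = None,
    ) -> pd.DataFrame:
        """Answer a group-by query from the precomputed cuboids.

        ``group_by`` must be a declared hierarchy prefix (or empty for the
        grand total); ``filters`` are equality predicates on the grouping
        columns.  Never touches the underlying tables.
        """
        pattern = tuple(group_by)
        if pattern not in self._cuboids:
            raise CubeReroute(
                f"grouping {pattern!r} not declared; reroute to the level-3 table")
        out = self._cuboids[pattern]
        for col, value in (filters or {}).items():
            if col not in pattern:
                raise CubeReroute(
                    f"filter column {col!r} outside grouping {pattern!r}")
            out = out[out[col] == value]
        return out.reset_index(drop=True)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Persist every cuboid as a Parquet file plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"hierarchies": [list(h) for h in self.hierarchies],
                    "measures": self.measures, "cuboids": {}}
        for pattern, cub in self._cuboids.items():
            name = "apex" if pattern == () else "__".join(pattern)
            cub.to_parquet(directory / f"{name}.parquet", index=False)
            manifest["cuboids"][name] = list(pattern)
        (directory / "cube.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Cube":
        directory = Path(directory)
        manifest = json.loads((directory / "cube.json").read_text())
        cube = cls.__new__(cls)
        cube.hierarchies = tuple(tuple(h) for h in manifest["hierarchies"])
        cube.measures = dict(manifest["measures"])
        cube._cuboids = {
            tuple(pattern): pd.read_parquet(directory / f"{name}.parquet")
            for name, pattern in manifest["cuboids"].items()
        }
        return cube
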