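"""Answer aggregate queries from the materialized cube in O(lookup).

The cube precomputes group-bys along declared hierarchies
(region -> subregion -> country; gene -> transcript -> exon).  Declared
patterns answer instantly without touching the tables; anything else
raises a reroute signal so the caller can fall back to the level-3
table.
"""

import tempfile
from pathlib import Path

from variantdwh import build_all, generate_world
from variantdwh.cube import Cube, CubeReroute

world = generate_world(n_samples=100, n_variants=2000, seed=5)
with tempfile.TemporaryDirectory() as tmp:
    wh = build_all(Path(tmp) / "wh", world)
    cube = Cube(wh.read_table("fact_agg_counts_dims"))
    print("declared cuboids:", cube.declared_patterns)

    by_region = cube.lookup(("region",))
    print("\ngenotype calls per region:")
    print(by_region[["region", "n_records", "allele_count"]].to_string(index=False))

    europe = cube.lookup(("region",), {"region": "Europe"})
    print(f"\nEurope only: {int(europe.n_records[0])} calls")

    try:
        cube.lookup(("country",))  # country without its hierarchy prefix
    except CubeReroute as exc:
        print(f"\nundeclared grouping -> reroute: {exc}")
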