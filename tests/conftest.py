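"""Shared fixtures: seeded synthetic worlds and built warehouses.

Two problem sizes are used throughout: a small world for fast unit
tests, and a cohort-scale fixture (200 samples x 5000 catalog variants,
full-size geography and disease dimensions) for the end-to-end
equivalence and recovery checks.
"""

from __future__ import annotations

import pytest

from variantdwh import SQLiteAdapter, build_all, generate_world


@pytest.fixture(scope="session")
def small_world():
    return generate_world(n_samples=50, n_variants=500, seed=7,
                          n_countries=12, n_diseases=50, n_genes=20,
                          exons_per_gene_mean=5.0)


@pytest.fixture(scope="session")
def cohort_world():
    """200 samples x 5000 variants under the default study conditions."""
    return generate_world(n_samples=200, n_variants=5000, seed=11)


@pytest.fixture(scope="session")
def small_warehouse(small_world, tmp_path_factory):
    return build_all(tmp_path_factory.mktemp("wh_small"), small_world)


@pytest.fixture(scope="session")
def cohort_warehouse(cohort_world, tmp_path_factory):
    return build_all(tmp_path_factory.mktemp("wh_cohort"), cohort_world)


@pytest.fixture(scope="session")
def small_adapter(small_warehouse):
    with SQLiteAdapter(small_warehouse) as adapter:
        yield adapter


@pytest.fixture(scope="session")
def cohort_adapter(cohort_warehouse):
    with SQLiteAdapter(cohort_warehouse) as adapter:
        yield adapter


def common_disease_omim(world):
    """OMIM id of the disease carried by the most samples (non-trivial Q3)."""
    from collections import Counter

    counts = Counter(s.disease_fk for s in world.samples if s.disease_fk is not None)
    disease_fk = counts.most_common(1)[0][0]
    return next(d.omim_id for d in world.diseases if d.disease_id == disease_fk)


def default_params(world):
    """Valid parameter sets for every query against a given world."""
    omim = common_disease_omim(world)
    return {
        "Q3A": {"omim_id": omim}, "Q3B": {"omim_id": omim},
        "Q5": {"sample_id": 1, "chrom": "1", "start": 1, "end": 20_000_000},
        "Q8": {"sample_id": 1}, "Q9": {"sample_id": 1},
        "Q10": {"chrom": "1"}, "Q12": {"sample_id": 1},
    }
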