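"""Shared fixtures: small designed libraries and simulated datasets.

Heavy simulations are session-scoped so several test modules can share one
dataset; everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from regfoot import (DesignConfig, PromoterRegion, assign_barcodes,
                     draw_barcode_counts, mutate_variants)
from regfoot.barcode_pipeline import aggregate_variant_counts
from regfoot.library_design import ints_to_seq
from regfoot.synthetic_data import (barcode_map_frame, default_architecture,
                                    null_architecture, simulate_counts)


def random_region(seed: int, promoter_id: str = "p1") -> PromoterRegion:
    rng = np.random.default_rng(seed)
    return PromoterRegion(promoter_id=promoter_id, gene="gene", tss=115,
                          strand="+", sequence=ints_to_seq(rng.integers(0, 4, 160)))


def make_dataset(seed: int, *, architecture="default", conditions=("A", "B"),
                 active=("A",), depth=10 ** 6, n_variants=1500,
                 barcodes_median=3, n_replicates=1, include_repressor=True):
    """Library + barcode map + planted architecture + aggregated counts."""
    rng = np.random.default_rng(seed)
    region = random_region(seed)
    cfg = DesignConfig(n_variants=n_variants, rng_seed=seed)
    lib = mutate_variants(region, cfg, rng=rng)
    bmap = barcode_map_frame(assign_barcodes(
        lib, draw_barcode_counts(len(lib), barcodes_median, rng), cfg, rng=rng))
    if architecture == "null":
        arch = null_architecture(lib)
    else:
        inactive = [c for c in conditions if c not in active]
        arch = default_architecture(lib, rng, list(active), inactive,
                                    include_repressor=include_repressor)
    counts = simulate_counts(lib, bmap, arch, list(conditions), depth, depth,
                             seed=seed + 10_000, n_replicates=n_replicates)
    vc = aggregate_variant_counts(counts, bmap)
    return {"region": region, "library": lib, "barcode_map": bmap,
            "architecture": arch, "counts": counts, "variant_counts": vc}


@pytest.fixture(scope="session")
def small_library():
    """A 300-variant library for fast unit tests."""
    rng = np.random.default_rng(7)
    region = random_region(7, "small")
    cfg = DesignConfig(n_variants=300, rng_seed=7)
    lib = mutate_variants(region, cfg, rng=rng)
    bmap = barcode_map_frame(assign_barcodes(
        lib, draw_barcode_counts(len(lib), 3, rng), cfg, rng=rng))
    return region, lib, bmap


@pytest.fixture(scope="session")
def sim_dataset():
    """Planted RNAP + activator + repressor dataset at depth 1e6."""
    return make_dataset(42)


@pytest.fixture(scope="session")
def null_dataset():
    """Flat-expression dataset (no sequence dependence) at depth 1e5."""
    return make_dataset(43, architecture="null", conditions=("A",), depth=10 ** 5)
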