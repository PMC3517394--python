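import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blockscape as bs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return bs.default_registry()


@pytest.fixture(scope="session")
def small_city():
    """A 5x5-block city with its full pipeline products, built once."""
    return build_city_products(
        bs.SyntheticConfig(grid_nx=5, grid_ny=5, parcels_per_block=10, seed=7)
    )


def build_city_products(cfg: bs.SyntheticConfig, registry=None) -> dict:
    """Run the whole pipeline on one generated city; shared test helper."""
    registry = registry or bs.default_registry()
    city = bs.generate_city(cfg, registry)
    graph = bs.build_adjacency(city.blocks)
    parcels, unassigned = bs.assign_parcels_to_blocks(
        city.parcels.drop(columns=["true_block_id"]), city.blocks
    )
    nuisances, _ = bs.assign_parcels_to_blocks(city.nuisances, city.blocks)
    calls, tenure_errors = bs.classify_tenure(parcels)
    crime_counts, crime_unassigned = bs.aggregate_crime(city.crimes, city.blocks)
    block_indices = bs.build_block_indices(
        parcels, nuisances, registry, list(city.blocks),
        crime_counts=crime_counts, tenure_calls=calls,
    )
    table = bs.build_index_table(block_indices, graph)
    return {
        "city": city,
        "graph": graph,
        "parcels": parcels,
        "parcels_unassigned": unassigned,
        "nuisances": nuisances,
        "tenure_calls": calls,
        "tenure_errors": tenure_errors,
        "crime_counts": crime_counts,
        "crime_unassigned": crime_unassigned,
        "block_indices": block_indices,
        "index_table": table,
        "registry": registry,
    }


def random_rectangle_layout(seed: int, n: int = 60) -> dict:
    """Random axis-aligned rectangles snapped to a coarse lattice so that
    shared edges and corner contacts actually occur."""
    rng = np.random.default_rng(seed)
    from shapely.geometry import box

    blocks = {}
    for i in range(n):
        x0 = int(rng.integers(0, 20))
        y0 = int(rng.integers(0, 20))
        w = int(rng.integers(1, 4))
        h = int(rng.integers(1, 4))
        blocks[f"R{i:03d}"] = box(x0, y0, x0 + w, y0 + h)
    return blocks
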