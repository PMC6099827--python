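import numpy as np
import pytest

from lgflow import (
    SyntheticConfig,
    build_graph,
    effective_resistance_pairwise,
    generate_landscape,
    generate_lek_clusters,
    null_distance_matrix,
    simulate_genotypes,
    threshold_surface,
)
from lgflow.genetics import MISSING, GenotypeTable


def make_table(genotypes, ids=None, x=None, y=None, zone=None, cluster=None):
    """Build a GenotypeTable from a list of per-individual locus tuples,
    e.g. [[(1, 1), (2, 3)], [(1, 2), (MISSING, MISSING)]]."""
    n = len(genotypes)
    return GenotypeTable(
        ids=np.array(ids or [f"ind{i}" for i in range(n)], dtype=object),
        x=np.asarray(x if x is not None else np.zeros(n), dtype=float),
        y=np.asarray(y if y is not None else np.zeros(n), dtype=float),
        zone=np.array(zone or ["Z"] * n, dtype=object),
        alleles=np.array(genotypes, dtype=int),
        cluster_id=None if cluster is None else np.array(cluster, dtype=object),
    )


@pytest.fixture(scope="session")
def demo_landscape():
    cfg = SyntheticConfig(seed=11, grid_rows=50, grid_cols=50, n_clusters=8,
                          inds_per_cluster=30, n_loci=30, drift_scale=0.12,
                          mlpe_sigma_u=0.01, mlpe_sigma_e=0.005)
    raster = generate_landscape(cfg)
    node_sets = generate_lek_clusters(raster, cfg, min_separation_cells=12)
    return cfg, raster, node_sets


@pytest.fixture(scope="session")
def demo_dataset(demo_landscape):
    """A full synthetic dataset: landscape, clusters, resistances, genotypes."""
    cfg, raster, node_sets = demo_landscape
    surf = threshold_surface(
        raster, cfg.true_threshold, "positive", cfg.true_resistance,
        variable="habitat",
    )
    graph = build_graph(surf)
    r_true = effective_resistance_pairwise(graph, node_sets)
    null = null_distance_matrix(raster, node_sets)
    table = simulate_genotypes(node_sets, r_true, cfg, raster=raster)
    return {
        "config": cfg,
        "raster": raster,
        "node_sets": node_sets,
        "surface": surf,
        "r_true": r_true,
        "null": null,
        "table": table,
    }
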