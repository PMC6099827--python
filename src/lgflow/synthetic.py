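"""Synthetic landscapes, lek clusters and genotypes for the full pipeline.

The generator emulates the statistical structure the analysis assumes, at
desk scale: a spatially autocorrelated habitat index in [0, 1] with a known
habitat threshold; clusters of lek points placed in good habitat with
enforced spacing; and multilocus diploid genotypes whose pairwise
differentiation tracks effective resistance through an MLPE-structured
target,

    target G'_ST(i, j) = clamp(drift_scale * R_ij + u_i + u_j + eps_ij, 0, 0.95)

with cluster effects ``u ~ N(0, mlpe_sigma_u^2)`` and pair noise
``eps ~ N(0, mlpe_sigma_e^2)``.

Targets are realized via a double-centering construction: the target matrix
(converted from the G'_ST to the G_ST scale) is treated as a squared-distance
matrix between cluster allele-frequency vectors, Gower-centered into a
cross-cluster covariance (PSD up to eigenvalue clipping, since effective
resistance is a negative-type metric), and per-locus cluster frequencies are
drawn as correlated Gaussian perturbations of a base frequency vector with
allele-wise scale sqrt(p0 (1 - p0)).  Individuals are then Hardy-Weinberg
draws from their cluster's frequencies.  The mapping is approximate — the
simplex projection shrinks extreme targets — but it is monotone, which is
what the downstream rank-based checks require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .genetics import GenotypeTable
from .matrices import PairwiseMatrix
from .raster import Raster


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-condition defaults, scaled to desk size.

    The genotype dimensions mirror the field study (15 microsatellite loci;
    cluster counts on the order of the smallest management zone; 20
    individuals per cluster, within the observed 18.8-25.9 mean range); cell
    size is the 1.2-km analysis resolution.
    """

    grid_rows: int = 90
    grid_cols: int = 90
    cell_size: float = 1.2  # km, the analysis resolution
    autocorr_range: float = 8.0  # cells
    true_threshold: float = 0.5
    true_resistance: float = 20.0  # nonhabitat resistance of the true surface
    n_clusters: int = 10
    inds_per_cluster: int = 20
    n_loci: int = 15
    alleles_per_locus: int = 6
    drift_scale: float = 0.05  # G'_ST per unit effective resistance
    mlpe_sigma_u: float = 0.02
    mlpe_sigma_e: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.grid_rows,
            self.grid_cols,
            self.n_loci,
            self.alleles_per_locus,
            self.inds_per_cluster,
        )
        if any(c < 1 for c in counts):
            raise SyntheticError("counts must be >= 1")
        if self.n_clusters < 0:
            raise SyntheticError("n_clusters must be >= 0")
        if not 0 < self.true_threshold < 1:
            raise SyntheticError("true_threshold must be in (0, 1)")
        if self.true_resistance <= 1:
            raise SyntheticError("true_resistance must exceed 1")
        if self.drift_scale < 0:
            raise SyntheticError("drift_scale must be >= 0")


def generate_landscape(config: SyntheticConfig) -> Raster:
    """Spatially autocorrelated habitat index in [0, 1].

    White Gaussian noise is smoothed with a Gaussian kernel whose scale is
    set by ``autocorr_range`` (range 1 means no smoothing), then
    rank-transformed to a uniform [0, 1] field, so ``true_threshold`` is
    simultaneously a habitat-index value and an areal quantile.
    """
    rng = np.random.default_rng(config.seed)
    field = rng.standard_normal((config.grid_rows, config.grid_cols))
    sigma = max(config.autocorr_range - 1.0, 0.0) / 2.0
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    flat = field.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    uniform = (ranks + 0.5) / flat.size
    return Raster(
        uniform.reshape(field.shape),
        cell_size=config.cell_size,
        meta={"variable": "habitat_index", "autocorr_range": config.autocorr_range},
    )


def generate_lek_clusters(
    raster: Raster,
    config: SyntheticConfig,
    min_separation_cells: float | None = None,
    max_leks_per_cluster: int = 5,
    max_tries: int = 2000,
) -> dict:
    """Place ``n_clusters`` groups of lek points on above-median habitat.

    Returns cluster_id -> list of (row, col) cell indices.  Cluster centroids
    are kept pairwise farther apart than ``min_separation_cells`` (default:
    one quarter of the smaller grid dimension), mirroring the downstream
    clustering cut; lek points sit on cells with habitat value above the
    median, as real leks occur in high-index habitat.
    """
    if config.n_clusters == 0:
        return {}
    rng = np.random.default_rng(config.seed + 1)
    if min_separation_cells is None:
        min_separation_cells = min(raster.shape) / 4.0
    vals = raster.grid
    median = np.nanmedian(vals)
    good = np.argwhere((vals > median) & ~raster.mask)
    if len(good) < config.n_clusters:
        raise SyntheticError("not enough habitat cells to place clusters")
    # feasible-set sampling with restarts: draw each center uniformly from
    # the cells still far enough from every placed center; a draw sequence
    # that blocks itself is restarted rather than retried blindly
    centers: list[np.ndarray] = []
    n_restarts = max(max_tries // max(config.n_clusters, 1), 1)
    for _restart in range(n_restarts):
        centers = []
        feasible = np.ones(len(good), dtype=bool)
        while len(centers) < config.n_clusters and feasible.any():
            idx = rng.choice(np.flatnonzero(feasible))
            cand = good[idx]
            centers.append(cand)
            d = np.hypot(good[:, 0] - cand[0], good[:, 1] - cand[1])
            feasible &= d > min_separation_cells
        if len(centers) == config.n_clusters:
            break
    else:
        raise SyntheticError(
            f"could not place {config.n_clusters} clusters with separation "
            f"{min_separation_cells:g} cells after {n_restarts} restarts"
        )
    node_sets: dict = {}
    used: set = set()
    for k, center in enumerate(centers):
        n_leks = int(rng.integers(1, max_leks_per_cluster + 1))
        # compact neighborhood: nearest above-median cells to the centroid
        d = np.hypot(good[:, 0] - center[0], good[:, 1] - center[1])
        order = np.argsort(d, kind="stable")
        cells = []
        for i in order:
            cell = tuple(map(int, good[i]))
            if cell in used:
                continue
            cells.append(cell)
            used.add(cell)
            if len(cells) == n_leks:
                break
        node_sets[f"C{k + 1:03d}"] = cells
    return node_sets


def _target_matrix(
    resistance: PairwiseMatrix, config: SyntheticConfig, rng
) -> np.ndarray:
    r = resistance.values
    if not np.isfinite(r).all():
        raise SyntheticError("effective resistance must be finite")
    if not np.allclose(r, r.T, atol=1e-9):
        raise SyntheticError("effective resistance must be symmetric")
    k = r.shape[0]
    u = rng.normal(0.0, config.mlpe_sigma_u, size=k)
    eps = rng.normal(0.0, config.mlpe_sigma_e, size=(k, k))
    eps = (eps + eps.T) / 2.0
    target = config.drift_scale * r + u[:, None] + u[None, :] + eps
    np.fill_diagonal(target, 0.0)
    return np.clip(target, 0.0, 0.95)


def _gower_factor(sqdist: np.ndarray) -> np.ndarray:
    """Factor A with A A' = -0.5 J D J (eigenvalues clipped to >= 0)."""
    k = sqdist.shape[0]
    j = np.eye(k) - np.ones((k, k)) / k
    sigma = -0.5 * j @ sqdist @ j
    lam, q = np.linalg.eigh(sigma)
    lam = np.clip(lam, 0.0, None)
    return q * np.sqrt(lam)


def simulate_genotypes(
    node_sets: dict,
    effective_resistance: PairwiseMatrix,
    config: SyntheticConfig,
    raster: Raster | None = None,
    zone: str = "MZ-S",
) -> GenotypeTable:
    """Simulate diploid genotypes whose pairwise differentiation tracks
    effective resistance through the MLPE-structured target (module
    docstring).  Individuals are placed at their cluster's lek cells."""
    labels = sorted(node_sets)
    if effective_resistance.labels != labels:
        effective_resistance = effective_resistance.reorder(labels)
    k = len(labels)
    rng = np.random.default_rng(config.seed + 2)
    target_gstp = _target_matrix(effective_resistance, config, rng)

    # draw base frequencies first so the G'_ST -> G_ST conversion can use
    # the panel's expected heterozygosity
    base = rng.dirichlet(
        np.full(config.alleles_per_locus, 5.0), size=config.n_loci
    )
    h0 = float(np.mean(1.0 - np.sum(base**2, axis=1)))
    # pairwise, k=2: G'_ST = G_ST (1 + H_S) / (1 - H_S)  =>  invert at H_S ~ h0
    target_gst = target_gstp * (1.0 - h0) / (1.0 + h0)
    # E[(p_i - p_j)^2] summed over alleles = H0 * t_ij with t = 4 G_ST
    factor = _gower_factor(4.0 * target_gst)

    freqs = np.empty((k, config.n_loci, config.alleles_per_locus))
    for l in range(config.n_loci):
        p0 = base[l]
        scale = np.sqrt(p0 * (1.0 - p0))
        z = rng.standard_normal((factor.shape[1], config.alleles_per_locus))
        eta = factor @ z  # (k, alleles), cross-cluster covariance = Sigma
        p = p0[None, :] + eta * scale[None, :]
        p = np.clip(p, 1e-4, None)
        freqs[:, l, :] = p / p.sum(axis=1, keepdims=True)

    allele_sizes = 100 + 2 * np.arange(config.alleles_per_locus)
    n_total = k * config.inds_per_cluster
    alleles = np.empty((n_total, config.n_loci, 2), dtype=int)
    ids, xs, ys, zones, cluster_ids = [], [], [], [], []
    row = 0
    for ci, cid in enumerate(labels):
        cells = node_sets[cid]
        for ind in range(config.inds_per_cluster):
            ids.append(f"{cid}_I{ind + 1:03d}")
            cell = cells[ind % len(cells)]
            if raster is not None:
                x, y = raster.cell_center(*cell)
            else:
                x, y = (
                    (cell[1] + 0.5) * config.cell_size,
                    (cell[0] + 0.5) * config.cell_size,
                )
            xs.append(x)
            ys.append(y)
            zones.append(zone)
            cluster_ids.append(cid)
            for l in range(config.n_loci):
                draws = rng.choice(
                    config.alleles_per_locus, size=2, p=freqs[ci, l]
                )
                alleles[row, l] = allele_sizes[draws]
            row += 1
    return GenotypeTable(
        ids=np.array(ids, dtype=object),
        x=np.array(xs),
        y=np.array(ys),
        zone=np.array(zones, dtype=object),
        alleles=alleles,
        cluster_id=np.array(cluster_ids, dtype=object),
    )
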