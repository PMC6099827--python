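"""Sparse circuit-theory engine on raster resistance surfaces.

A resistance surface becomes a weighted graph: every non-NoData cell is a
node, neighboring cells are joined by a resistor whose conductance is the
mean of the two cell conductances (1/r), with diagonal neighbors down-
weighted by 1/sqrt(2) for the longer path.  Lek clusters enter as
*supernodes*: all of a cluster's cells are contracted into one node (zero
internal resistance), matching the use of lek clusters as circuit nodes.

Effective resistance between supernodes s and t is the voltage developed
between them when one unit of current is injected at s and removed at t,
computed from the reduced graph Laplacian (ground one node, factorize once
per component, reuse the factorization across all sources).  The "all-to-one"
current map grounds each focal cluster in turn, injects one unit at every
other cluster, and averages the resulting per-cell current magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .matrices import PairwiseMatrix
from .raster import Raster

log = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))


class CircuitError(ValueError):
    pass


@dataclass
class ResistanceGraph:
    """Conductance-weighted grid graph with optional supernode contraction."""

    shape: tuple[int, int]
    node_of_cell: np.ndarray  # (rows, cols) int; -1 where masked
    cells: np.ndarray  # (n_nodes, 2) row/col per node
    edges_i: np.ndarray
    edges_j: np.ndarray
    conductance: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    components: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def adjacency(self) -> sparse.csr_matrix:
        a = sparse.coo_matrix(
            (
                np.concatenate([self.conductance, self.conductance]),
                (
                    np.concatenate([self.edges_i, self.edges_j]),
                    np.concatenate([self.edges_j, self.edges_i]),
                ),
            ),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()


def build_graph(surface, neighborhood: int = 8) -> ResistanceGraph:
    """Build the conductance graph of a resistance surface.

    ``surface`` is a :class:`~lgflow.raster.Raster` (or anything with
    ``grid``/``mask``/``cell_size``/``origin``) whose non-masked cells hold
    per-cell resistances >= some positive value.
    """
    if neighborhood not in (4, 8):
        raise CircuitError("neighborhood must be 4 or 8")
    grid = np.asarray(surface.grid, dtype=float)
    mask = surface.mask
    if mask.all():
        raise CircuitError("surface has no unmasked cells")
    if np.any(grid[~mask] <= 0):
        raise CircuitError("resistances must be positive")

    nrows, ncols = grid.shape
    node_of_cell = -np.ones((nrows, ncols), dtype=np.int64)
    rr, cc = np.nonzero(~mask)
    node_of_cell[rr, cc] = np.arange(len(rr))
    cells = np.column_stack([rr, cc])

    cond = 1.0 / grid  # NaN where masked; never indexed there
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        offsets += [(1, 1, 1.0 / _SQRT2), (1, -1, 1.0 / _SQRT2)]

    ei, ej, ec = [], [], []
    for dr, dc, w in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a = node_of_cell[r0, c0]
        b = node_of_cell[r1, c1]
        ok = (a >= 0) & (b >= 0)
        g = 0.5 * (cond[r0, c0] + cond[r1, c1]) * w
        ei.append(a[ok])
        ej.append(b[ok])
        ec.append(g[ok])
    edges_i = np.concatenate(ei) if ei else np.empty(0, dtype=np.int64)
    edges_j = np.concatenate(ej) if ej else np.empty(0, dtype=np.int64)
    conductance = np.concatenate(ec) if ec else np.empty(0)

    graph = ResistanceGraph(
        shape=(nrows, ncols),
        node_of_cell=node_of_cell,
        cells=cells,
        edges_i=edges_i,
        edges_j=edges_j,
        conductance=conductance,
        cell_size=getattr(surface, "cell_size", 1.0),
        origin=getattr(surface, "origin", (0.0, 0.0)),
    )
    _n, labels = connected_components(graph.adjacency(), directed=False)
    graph.components = labels
    return graph


def _node_sets_to_nodes(graph: ResistanceGraph, node_sets: dict) -> dict:
    """cluster_id -> array of graph node indices, validating cell membership."""
    out = {}
    for cid, cells in node_sets.items():
        nodes = []
        for r, c in cells:
            nd = graph.node_of_cell[int(r), int(c)]
            if nd < 0:
                raise CircuitError(f"cluster {cid!r} cell ({r}, {c}) is masked")
            nodes.append(int(nd))
        if not nodes:
            raise CircuitError(f"cluster {cid!r} has no cells")
        out[str(cid)] = np.array(sorted(set(nodes)), dtype=np.int64)
    return out


def _contract(graph: ResistanceGraph, super_nodes: dict):
    """Merge each cluster's nodes into one. Returns (remap, n_new, super_ids)
    where ``remap[node] -> contracted index`` and ``super_ids[cid]`` is the
    contracted index of that cluster's supernode."""
    labels = sorted(super_nodes)
    remap = -np.ones(graph.n_nodes, dtype=np.int64)
    for k, cid in enumerate(labels):
        remap[super_nodes[cid]] = k
    free = np.flatnonzero(remap < 0)
    remap[free] = len(labels) + np.arange(len(free))
    return remap, len(labels) + len(free), {cid: k for k, cid in enumerate(labels)}


def _laplacian(remap, n_new, graph) -> sparse.csc_matrix:
    i = remap[graph.edges_i]
    j = remap[graph.edges_j]
    keep = i != j  # drop edges internal to a supernode
    i, j, c = i[keep], j[keep], graph.conductance[keep]
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-c, -c, c, c])
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n_new, n_new)).tocsc()


def effective_resistance_pairwise(
    graph: ResistanceGraph, node_sets: dict, statistic: str = "resistance"
) -> PairwiseMatrix:
    """Pairwise effective resistance between cluster supernodes.

    Pairs of clusters lying in different connected components get ``inf``
    and are flagged in ``meta['disconnected_pairs']``.
    """
    super_nodes = _node_sets_to_nodes(graph, node_sets)
    labels = sorted(super_nodes)
    if len(labels) < 2:
        raise CircuitError("need at least two node sets")
    for cid, nodes in super_nodes.items():
        comps = set(graph.components[nodes])
        if len(comps) > 1:
            raise CircuitError(f"cluster {cid!r} spans disconnected components")

    remap, n_new, super_ids = _contract(graph, super_nodes)
    lap = _laplacian(remap, n_new, graph)
    # contracted component labels
    adj = sparse.coo_matrix(
        (
            np.ones(len(graph.edges_i)),
            (remap[graph.edges_i], remap[graph.edges_j]),
        ),
        shape=(n_new, n_new),
    )
    _nc, comp = connected_components(adj + adj.T, directed=False)

    k = len(labels)
    out = np.full((k, k), np.inf)
    np.fill_diagonal(out, 0.0)
    for comp_id in np.unique(comp[[super_ids[c] for c in labels]]):
        members = [c for c in labels if comp[super_ids[c]] == comp_id]
        if len(members) < 2:
            continue
        comp_nodes = np.flatnonzero(comp == comp_id)
        local = -np.ones(n_new, dtype=np.int64)
        local[comp_nodes] = np.arange(len(comp_nodes))
        ground = super_ids[members[0]]
        keep = comp_nodes[comp_nodes != ground]
        lidx = -np.ones(n_new, dtype=np.int64)
        lidx[keep] = np.arange(len(keep))
        sub = lap[keep][:, keep].tocsc()
        lu = splu(sub)
        sols = {}
        for cid in members[1:]:
            e = np.zeros(len(keep))
            e[lidx[super_ids[cid]]] = 1.0
            sols[cid] = lu.solve(e)
        g0 = members[0]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ca, cb = members[a], members[b]
                ia, ib = labels.index(ca), labels.index(cb)
                if ca == g0:
                    r = sols[cb][lidx[super_ids[cb]]]
                elif cb == g0:
                    r = sols[ca][lidx[super_ids[ca]]]
                else:
                    xa, xb = sols[ca], sols[cb]
                    pa, pb = lidx[super_ids[ca]], lidx[super_ids[cb]]
                    r = xa[pa] - xa[pb] - xb[pa] + xb[pb]
                out[ia, ib] = out[ib, ia] = r
    m = PairwiseMatrix(labels, out, statistic)
    n_disc = int(np.sum(~np.isfinite(m.condensed())))
    if n_disc:
        m.meta["disconnected_pairs"] = n_disc
        log.warning("%d cluster pairs are in disconnected components", n_disc)
    return m


def null_distance_matrix(
    template: Raster, node_sets: dict, neighborhood: int = 8
) -> PairwiseMatrix:
    """Effective resistance over an undifferentiated landscape (all cells
    resistance 1, same NoData mask) — the geographic-distance null."""
    ones = template.copy_with(np.where(template.mask, np.nan, 1.0))
    graph = build_graph(ones, neighborhood=neighborhood)
    return effective_resistance_pairwise(graph, node_sets, statistic="geo_null")


@dataclass
class FlowMap:
    """Averaged per-cell current density from all-to-one circuit solves."""

    raster: Raster
    normalization: str = "mean_over_focal"

    def percentile_bins(self, n_bins: int = 10) -> np.ndarray:
        vals = self.raster.grid[~self.raster.mask]
        return np.nanpercentile(vals, np.linspace(0, 100, n_bins + 1))


def all_to_one_flow(graph: ResistanceGraph, node_sets: dict) -> FlowMap:
    """Average current map over all-to-one solves.

    For each focal cluster f: ground f, inject one unit of current at every
    other cluster in f's component, solve for node potentials, and accumulate
    per-cell current as half the sum of absolute currents on incident edges.
    The final map is the mean over focal clusters.
    """
    super_nodes = _node_sets_to_nodes(graph, node_sets)
    labels = sorted(super_nodes)
    if len(labels) < 2:
        raise CircuitError("need at least two node sets")
    remap, n_new, super_ids = _contract(graph, super_nodes)
    lap = _laplacian(remap, n_new, graph)
    adj = sparse.coo_matrix(
        (
            np.ones(len(graph.edges_i)),
            (remap[graph.edges_i], remap[graph.edges_j]),
        ),
        shape=(n_new, n_new),
    )
    _nc, comp = connected_components(adj + adj.T, directed=False)

    accum = np.zeros(graph.n_nodes)
    n_solves = 0
    for focal in labels:
        comp_id = comp[super_ids[focal]]
        others = [
            c for c in labels if c != focal and comp[super_ids[c]] == comp_id
        ]
        if not others:
            continue
        comp_nodes = np.flatnonzero(comp == comp_id)
        ground = super_ids[focal]
        keep = comp_nodes[comp_nodes != ground]
        lidx = -np.ones(n_new, dtype=np.int64)
        lidx[keep] = np.arange(len(keep))
        rhs = np.zeros(len(keep))
        for c in others:
            rhs[lidx[super_ids[c]]] += 1.0
        v_red = splu(lap[keep][:, keep].tocsc()).solve(rhs)
        v = np.zeros(n_new)
        v[keep] = v_red
        # per-cell current: half the absolute edge currents at each endpoint
        dv = np.abs(v[remap[graph.edges_i]] - v[remap[graph.edges_j]])
        edge_cur = graph.conductance * dv
        np.add.at(accum, graph.edges_i, 0.5 * edge_cur)
        np.add.at(accum, graph.edges_j, 0.5 * edge_cur)
        n_solves += 1
    if n_solves == 0:
        raise CircuitError("no focal cluster has a partner in its component")
    accum /= n_solves
    grid = np.full(graph.shape, np.nan)
    grid[graph.cells[:, 0], graph.cells[:, 1]] = accum
    return FlowMap(
        Raster(
            grid,
            cell_size=graph.cell_size,
            origin=graph.origin,
            meta={"normalization": "mean_over_focal", "n_focal": n_solves},
        )
    )
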