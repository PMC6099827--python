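"""End-to-end pipeline: genotypes + rasters -> model tables + flow map.

Stage order mirrors the analysis: cluster sampling locations (25-km
complete-linkage cut, minimum 8 individuals) -> pairwise G'_ST -> threshold
candidate resistance surfaces -> decorrelation search for nonhabitat
resistance values -> circuit-theory pairwise resistances -> within-variable
MLPE selection with the two-model significance rule -> between-variable AICc
comparison (including the additive combined landscape surface) -> Monte
Carlo cross-validation of the top surface -> all-to-one current-flow map.

Every artifact is written as plain text (CSV / ASCII grid / JSON) with a
provenance sidecar carrying the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit, clustering, genetics, io, surfaces, synthetic, validation
from .config import PipelineConfig
from .matrices import PairwiseMatrix
from .mlpe import between_variable_selection, within_variable_selection
from .raster import Raster, read_ascii_grid, write_ascii_grid

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def zone_summary(
    table: genetics.GenotypeTable, differentiation: str = "gst_prime"
) -> pd.DataFrame:
    """Per-zone cluster counts and mean/max pairwise differentiation —
    the standard summary of within-zone genetic structure."""
    rows = []
    for zone in pd.unique(table.zone):
        sub = table.subset(table.zone == zone)
        cids = pd.unique(sub.cluster_id) if sub.cluster_id is not None else []
        if len(cids) >= 2:
            freqs = genetics.allele_frequencies(sub, group_by="cluster")
            mat = genetics.pairwise_differentiation(freqs, differentiation)
            vals = mat.condensed()
            mean_d, max_d = float(np.mean(vals)), float(np.max(vals))
        else:
            mean_d = max_d = float("nan")
        counts = (
            pd.Series(sub.cluster_id).value_counts() if len(cids) else pd.Series()
        )
        rows.append(
            {
                "zone": zone,
                "n_individuals": sub.n_individuals,
                "n_clusters": len(cids),
                "mean_inds_per_cluster": (
                    float(counts.mean()) if len(counts) else float("nan")
                ),
                f"mean_{differentiation}": mean_d,
                f"max_{differentiation}": max_d,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    config: PipelineConfig
    clusters: clustering.ClusterSet
    node_sets: dict
    gst: PairwiseMatrix
    geo_null: PairwiseMatrix
    selected_resistances: dict  # variable -> (r_low, r_high)
    within: dict  # variable -> WithinVariableResult
    between: pd.DataFrame
    top_surface_label: str
    top_matrix: PairwiseMatrix
    cv: validation.CVResult
    flow: circuit.FlowMap
    summary: pd.DataFrame
    rasters: dict = field(default_factory=dict)
    audits: dict = field(default_factory=dict)


def _synthetic_variable_rasters(cfg: PipelineConfig) -> dict:
    """Generate one raster per configured variable.

    The first variable reuses the habitat landscape (the surface genotypes
    truly respond to); additional variables are independent autocorrelated
    fields, so they act as decoys the selection stages must reject."""
    out = {}
    base_seed = cfg.synthetic.seed
    for k, var in enumerate(cfg.variables):
        sub = synthetic.SyntheticConfig(
            **{
                **cfg.synthetic.__dict__,
                "seed": base_seed if k == 0 else base_seed + 100 + k,
            }
        )
        out[var] = synthetic.generate_landscape(sub)
        out[var].meta["variable"] = var
    return out


def _recovered_node_sets(
    table: genetics.GenotypeTable,
    clusters: clustering.ClusterSet,
    raster: Raster,
) -> dict:
    """Unique lek cells per recovered cluster, from member coordinates."""
    assign = clusters.assignment()
    node_sets: dict = {}
    for i, ind in enumerate(table.ids):
        cid = assign.get(str(ind))
        if cid is None:
            continue
        cell = raster.cell_index(table.x[i], table.y[i])
        node_sets.setdefault(cid, set()).add(cell)
    return {cid: sorted(cells) for cid, cells in node_sets.items()}


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------ inputs
    if cfg.genotypes_path:
        table = io.read_genotypes(cfg.genotypes_path)
        rasters = {
            var: read_ascii_grid(path) for var, path in cfg.raster_paths.items()
        }
        if set(cfg.variables) - set(rasters):
            raise PipelineError("raster_paths must cover all variables")
    else:
        rasters = _synthetic_variable_rasters(cfg)
        habitat = rasters[cfg.variables[0]]
        min_sep = cfg.clustering_cut / cfg.synthetic.cell_size + 6.0
        true_sets = synthetic.generate_lek_clusters(
            habitat, cfg.synthetic, min_separation_cells=min_sep
        )
        true_surface = surfaces.threshold_surface(
            habitat,
            cfg.synthetic.true_threshold,
            "positive",
            cfg.synthetic.true_resistance,
            variable="true",
        )
        graph = circuit.build_graph(true_surface, neighborhood=cfg.neighborhood)
        r_true = circuit.effective_resistance_pairwise(graph, true_sets)
        table = synthetic.simulate_genotypes(
            true_sets, r_true, cfg.synthetic, raster=habitat
        )
        io.write_genotypes_delimited(table, out / "genotypes.csv")
        io.write_node_sets(true_sets, habitat, out / "true_lek_cells.csv")
    template = rasters[cfg.variables[0]]

    # ------------------------------------------------------ QC + clustering
    table = genetics.qc_filter(table, cfg.max_missing_loci)
    dists = clustering.geographic_distances(table.ids, table.x, table.y)
    coords = {str(i): (x, y) for i, x, y in zip(table.ids, table.x, table.y)}
    clusters = clustering.cluster_locations(dists, cfg.clustering_cut, coords)
    clusters = clustering.filter_clusters(clusters, cfg.min_individuals)
    if clusters.n_clusters < 3:
        raise PipelineError(
            f"only {clusters.n_clusters} clusters retained; need >= 3"
        )
    assign = clusters.assignment()
    keep = np.array([str(i) in assign for i in table.ids])
    table = table.subset(keep)
    table = table.with_clusters(
        np.array([assign[str(i)] for i in table.ids], dtype=object)
    )
    clusters.to_frame().to_csv(out / "clusters.csv", index=False)
    node_sets = _recovered_node_sets(table, clusters, template)

    # ------------------------------------------------------ differentiation
    freqs = genetics.allele_frequencies(table, group_by="cluster")
    gst = genetics.pairwise_differentiation(freqs, cfg.differentiation)
    gst.write_csv(out / f"{cfg.differentiation}.csv")
    summary = zone_summary(table, cfg.differentiation)
    summary.to_csv(out / "zone_summary.csv", index=False)

    # ------------------------------------------------------ null distances
    geo_null = circuit.null_distance_matrix(
        template, node_sets, neighborhood=cfg.neighborhood
    )
    geo_null.write_csv(out / "geo_null.csv")

    # -------------------------------------------- resistance value search
    selected: dict = {}
    audits: dict = {}
    candidate_mats: dict = {}
    for var in cfg.variables:
        spec = cfg.spec_for(var)
        r_low, r_high, audit = surfaces.select_resistance_values(
            {"zone": rasters[var]},
            spec,
            {"zone": node_sets},
            {"zone": geo_null},
            corr_limit=cfg.corr_limit,
            neighborhood=cfg.neighborhood,
        )
        selected[var] = (r_low, r_high)
        audits[var] = audit
        audit.to_csv(out / f"resistance_selection_{var}.csv", index=False)
        mats = {}
        for surf in surfaces.candidate_surfaces(
            rasters[var], spec, (r_low, r_high)
        ):
            g = circuit.build_graph(surf, neighborhood=cfg.neighborhood)
            mats[surf.label] = (
                circuit.effective_resistance_pairwise(g, node_sets),
                surf,
            )
        candidate_mats[var] = mats

    # -------------------------------------------- within-variable selection
    within: dict = {}
    for var in cfg.variables:
        mats = {lab: m for lab, (m, _s) in candidate_mats[var].items()}
        res = within_variable_selection(gst, mats, geo_null)
        within[var] = res
        res.table.to_csv(out / f"within_{var}.csv", index=False)
        log.info(
            "%s: best surface %s (dAIC vs distance %.2f, significant=%s)",
            var, res.best_label, res.delta_aic_vs_distance,
            res.decision.significant,
        )

    # -------------------------------------------- between-variable table
    between_candidates: dict = {}
    significant_surfs = []
    for var in cfg.variables:
        res = within[var]
        mat, surf = candidate_mats[var][res.best_label]
        if res.decision.significant:
            between_candidates[res.best_label] = mat
            significant_surfs.append(surf)
    if len(significant_surfs) > 1:
        landsum = surfaces.combine_surfaces(significant_surfs)
        g = circuit.build_graph(landsum, neighborhood=cfg.neighborhood)
        between_candidates["landsum"] = circuit.effective_resistance_pairwise(
            g, node_sets
        )
    if not between_candidates:
        log.warning("no significant variables; comparing best fits anyway")
        for var in cfg.variables:
            res = within[var]
            between_candidates[res.best_label] = candidate_mats[var][
                res.best_label
            ][0]
    between = between_variable_selection(gst, between_candidates, geo_null)
    between.to_csv(out / "between_variable_table.csv", index=False)

    # -------------------------------------------- CV + flow map
    top_label = between["surface"].iloc[0]
    if top_label in ("distance",):
        # fall back to the best non-null surface for validation/mapping
        non_null = between[between["surface"] != "distance"]
        top_label = non_null["surface"].iloc[0]
    top_mat = between_candidates[top_label]
    cv = validation.monte_carlo_cv(
        gst,
        top_mat,
        geo_null,
        iterations=cfg.cv_iterations,
        train_fraction=cfg.cv_train_fraction,
        n_bins=cfg.cv_bins,
        seed=cfg.seed + 7,
    )
    cv.summary().to_csv(out / "cv_summary.csv", index=False)
    cv.to_frame().to_csv(out / "cv_iterations.csv", index=False)

    if top_label == "landsum":
        top_surface = surfaces.combine_surfaces(significant_surfs)
    else:
        for var in cfg.variables:
            if top_label in candidate_mats[var]:
                top_surface = candidate_mats[var][top_label][1]
                break
    g = circuit.build_graph(top_surface, neighborhood=cfg.neighborhood)
    flow = circuit.all_to_one_flow(g, node_sets)
    write_ascii_grid(flow.raster, out / "flow_map.asc")
    write_ascii_grid(top_surface, out / "top_surface.asc")
    with open(out / "top_surface.asc.json", "w") as fh:
        json.dump(
            {
                "variable": top_surface.variable,
                "threshold": top_surface.threshold,
                "direction": top_surface.direction,
                "resistance": top_surface.nonhabitat_resistance,
            },
            fh,
            indent=2,
        )
    validation.plot_cv(cv, out / "cv_errors.png")

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "selected_resistances": {k: list(v) for k, v in selected.items()},
        "top_surface": top_label,
        "n_clusters": clusters.n_clusters,
        "significant": {
            var: bool(within[var].decision.significant) for var in cfg.variables
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return PipelineResult(
        config=cfg,
        clusters=clusters,
        node_sets=node_sets,
        gst=gst,
        geo_null=geo_null,
        selected_resistances=selected,
        within=within,
        between=between,
        top_surface_label=top_label,
        top_matrix=top_mat,
        cv=cv,
        flow=flow,
        summary=summary,
        rasters=rasters,
        audits=audits,
    )
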