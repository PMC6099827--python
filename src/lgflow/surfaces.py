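"""Binary habitat/nonhabitat resistance surfaces from continuous rasters.

Each landscape or habitat raster is split at a threshold into habitat
(resistance 1) and nonhabitat (resistance r > 1).  For variables positively
associated with grouse (habitat index, sagebrush cover) cells *at or above*
the threshold are habitat; for negatively associated variables (canopy,
tillage, disturbance, terrain) cells *at or below* the threshold are habitat.
Three thresholds x two nonhabitat resistance values give six candidate
surfaces per variable.  The two resistance values are picked by a
decorrelation search: the smallest candidate whose pairwise-resistance
matrices decorrelate (mean Pearson r <= 0.7) from the geographic null (first
set {5, 10, 20}) and from the first-chosen value's matrices (second set
{50, 100, 200}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circuit
from .matrices import PairwiseMatrix
from .raster import Raster, RasterError, grids_aligned

log = logging.getLogger(__name__)

CANDIDATE_RESISTANCES_LOW = (5.0, 10.0, 20.0)
CANDIDATE_RESISTANCES_HIGH = (50.0, 100.0, 200.0)
DEFAULT_CORR_LIMIT = 0.7


class SurfaceError(ValueError):
    pass


@dataclass
class ThresholdSpec:
    """Candidate thresholds and resistances for one landscape variable."""

    variable: str
    direction: str  # "positive" | "negative"
    thresholds: tuple
    threshold_mode: str = "absolute"  # or "percentile" (top-X% mass)
    resistances_low: tuple = CANDIDATE_RESISTANCES_LOW
    resistances_high: tuple = CANDIDATE_RESISTANCES_HIGH

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise SurfaceError("direction must be positive or negative")
        self.thresholds = tuple(sorted(self.thresholds))
        if any(r <= 1 for r in self.resistances_low + self.resistances_high):
            raise SurfaceError("candidate resistances must exceed 1")


@dataclass
class ResistanceSurface(Raster):
    """A resistance raster: habitat cells 1, nonhabitat cells > 1."""

    variable: str = ""
    threshold: float = float("nan")
    direction: str = "positive"
    nonhabitat_resistance: float = float("nan")

    @property
    def label(self) -> str:
        """Surface code: variable_threshold_resistance (e.g. ``BH_0.5_20``)."""
        return (
            f"{self.variable}_{self.threshold:g}_{self.nonhabitat_resistance:g}"
        )


def percentile_threshold(raster: Raster, top_percent: float) -> float:
    """Value v such that ``top_percent`` % of non-masked cells lie >= v."""
    if not 0 < top_percent < 100:
        raise SurfaceError("top_percent must be in (0, 100)")
    vals = raster.grid[~raster.mask]
    if vals.size == 0:
        raise SurfaceError("raster is fully masked")
    return float(np.quantile(vals, 1.0 - top_percent / 100.0))


def threshold_surface(
    raster: Raster,
    threshold: float,
    direction: str = "positive",
    nonhabitat_resistance: float = 20.0,
    variable: str = "",
) -> ResistanceSurface:
    """Binary habitat (1) / nonhabitat (r) surface from a continuous raster."""
    if nonhabitat_resistance <= 1:
        raise SurfaceError("nonhabitat resistance must exceed 1")
    if direction not in ("positive", "negative"):
        raise SurfaceError("direction must be positive or negative")
    vals = raster.grid[~raster.mask]
    if vals.size and not (np.nanmin(vals) <= threshold <= np.nanmax(vals)):
        log.warning(
            "threshold %g outside observed range [%g, %g] for %s",
            threshold, np.nanmin(vals), np.nanmax(vals), variable or "raster",
        )
    if direction == "positive":
        habitat = raster.grid >= threshold
    else:
        habitat = raster.grid <= threshold
    grid = np.where(habitat, 1.0, nonhabitat_resistance)
    grid[raster.mask] = np.nan
    if not np.any(grid[~raster.mask] == 1.0):
        log.warning("surface %s_%g has no habitat cells", variable, threshold)
    return ResistanceSurface(
        grid,
        cell_size=raster.cell_size,
        origin=raster.origin,
        variable=variable,
        threshold=float(threshold),
        direction=direction,
        nonhabitat_resistance=float(nonhabitat_resistance),
    )


def combine_surfaces(surfaces: list) -> ResistanceSurface:
    """Additive combined surface: 1 + sum of each surface's excess resistance.

    Habitat everywhere in all inputs stays at resistance 1; a cell that is
    nonhabitat for several variables accumulates their excesses additively.
    """
    if not surfaces:
        raise SurfaceError("no surfaces to combine")
    first = surfaces[0]
    for s in surfaces[1:]:
        if not grids_aligned(first, s) or not np.array_equal(first.mask, s.mask):
            raise SurfaceError("surfaces must share grid geometry and mask")
    excess = np.zeros(first.shape)
    for s in surfaces:
        excess += np.where(s.mask, 0.0, s.grid - 1.0)
    grid = 1.0 + excess
    grid[first.mask] = np.nan
    return ResistanceSurface(
        grid,
        cell_size=first.cell_size,
        origin=first.origin,
        variable="landsum",
        threshold=float("nan"),
        direction="positive",
        nonhabitat_resistance=float(np.nanmax(grid)),
    )


def resolve_thresholds(raster: Raster, spec: ThresholdSpec) -> list[float]:
    """Absolute threshold values (percentile specs evaluated on the raster)."""
    if spec.threshold_mode == "percentile":
        return [percentile_threshold(raster, t) for t in spec.thresholds]
    return list(spec.thresholds)


def candidate_surfaces(
    raster: Raster, spec: ThresholdSpec, resistances: tuple
) -> list[ResistanceSurface]:
    out = []
    for thr_spec, thr in zip(spec.thresholds, resolve_thresholds(raster, spec)):
        for r in resistances:
            s = threshold_surface(
                raster, thr, spec.direction, r, variable=spec.variable
            )
            s.meta["threshold_spec"] = thr_spec
            out.append(s)
    return out


def _mean_offdiag_corr(mats_a: list, mats_b: list) -> float:
    """Mean Pearson correlation between condensed matrices: same-index pairs
    when the lists have equal length (threshold-matched), else all crosses."""
    rs = []
    if len(mats_a) == len(mats_b):
        pairs = list(zip(mats_a, mats_b))
    else:
        pairs = [(a, b) for a in mats_a for b in mats_b]
    for a, b in pairs:
        va, vb = a.condensed(), b.condensed()
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() < 3 or np.std(va[ok]) == 0 or np.std(vb[ok]) == 0:
            rs.append(1.0)  # degenerate: treat as fully correlated
            continue
        rs.append(float(np.corrcoef(va[ok], vb[ok])[0, 1]))
    return float(np.mean(rs))


def _resistance_matrices(
    raster, spec, resistance, node_sets, neighborhood
) -> list[PairwiseMatrix]:
    mats = []
    for thr in resolve_thresholds(raster, spec):
        surf = threshold_surface(
            raster, thr, spec.direction, resistance, variable=spec.variable
        )
        graph = circuit.build_graph(surf, neighborhood=neighborhood)
        mats.append(circuit.effective_resistance_pairwise(graph, node_sets))
    return mats


def select_resistance_values(
    rasters_by_zone: dict,
    spec: ThresholdSpec,
    node_sets_by_zone: dict,
    null_by_zone: dict,
    corr_limit: float = DEFAULT_CORR_LIMIT,
    neighborhood: int = 8,
):
    """Choose the two nonhabitat resistance values for one variable.

    ``r_low``: smallest candidate in the first set whose three threshold-
    specific resistance matrices have mean Pearson correlation with the
    geographic null <= ``corr_limit`` in at least one zone.  ``r_high``:
    smallest candidate in the second set whose matrices' mean correlation
    with the ``r_low`` matrices is <= ``corr_limit`` in any zone.  Returns
    ``(r_low, r_high, audit)`` where ``audit`` is a tidy DataFrame of every
    correlation examined.
    """
    audit_rows = []
    low_mats_by_zone_candidate: dict = {}

    def zone_corrs(resistance, against_by_zone):
        corrs = {}
        for zone, raster in rasters_by_zone.items():
            mats = _resistance_matrices(
                raster, spec, resistance, node_sets_by_zone[zone], neighborhood
            )
            low_mats_by_zone_candidate[(zone, resistance)] = mats
            against = against_by_zone[zone]
            r = _mean_offdiag_corr(
                mats, against if isinstance(against, list) else [against]
            )
            corrs[zone] = r
        return corrs

    r_low = None
    for cand in spec.resistances_low:
        corrs = zone_corrs(cand, null_by_zone)
        for zone, r in corrs.items():
            audit_rows.append(
                {"set": "low", "candidate": cand, "zone": zone,
                 "against": "geo_null", "mean_r": r}
            )
        if r_low is None and any(r <= corr_limit for r in corrs.values()):
            r_low = cand
    if r_low is None:
        r_low = spec.resistances_low[-1]
        log.warning(
            "%s: no low candidate decorrelated from distance; using %g",
            spec.variable, r_low,
        )
    low_ref = {
        zone: low_mats_by_zone_candidate[(zone, r_low)]
        for zone in rasters_by_zone
    }

    r_high = None
    for cand in spec.resistances_high:
        corrs = zone_corrs(cand, low_ref)
        for zone, r in corrs.items():
            audit_rows.append(
                {"set": "high", "candidate": cand, "zone": zone,
                 "against": f"r_low={r_low:g}", "mean_r": r}
            )
        if r_high is None and any(r <= corr_limit for r in corrs.values()):
            r_high = cand
    if r_high is None:
        r_high = spec.resistances_high[-1]
        log.warning(
            "%s: no high candidate decorrelated from r_low; using %g",
            spec.variable, r_high,
        )
    return float(r_low), float(r_high), pd.DataFrame(audit_rows)
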