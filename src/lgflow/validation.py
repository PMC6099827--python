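"""Model validation: Monte Carlo cross-validation and individual-based rerun.

The cross-validation asks whether the selected resistance surface predicts
genetic differentiation for held-out pairs better than the geographic null:
pairs are split 80/20 at random, MLPE models ``y ~ RD`` and ``y ~ distance``
are fitted on the training pairs, and the mean absolute prediction error of
the fixed-effects prediction is summarized within equal-width bins of
observed differentiation (random effects of held-out structure are zero by
construction of the split).

The individual-based rerun repeats the between-variable comparison with
Bray-Curtis dissimilarity between individuals as the response, expanding
cluster-level resistance predictors to individual pairs by cluster lookup and
excluding within-cluster pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix, aligned
from .mlpe import MLPEError, MLPERegressor, between_variable_selection

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    bin_edges: np.ndarray
    # (iterations, n_bins) per-iteration bin mean absolute errors; NaN = empty
    errors_top: np.ndarray = field(repr=False)
    errors_distance: np.ndarray = field(repr=False)
    split_unit: str = "pair"

    def _summary(self, arr: np.ndarray) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0)
        return pd.DataFrame(
            {
                "bin": np.arange(len(mean)),
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "mean_abs_error": mean,
                "sd_abs_error": sd,
            }
        )

    def summary(self) -> pd.DataFrame:
        top = self._summary(self.errors_top).assign(model="top_surface")
        dist = self._summary(self.errors_distance).assign(model="distance")
        return pd.concat([top, dist], ignore_index=True)

    def pooled_mae(self) -> dict:
        return {
            "top_surface": float(np.nanmean(self.errors_top)),
            "distance": float(np.nanmean(self.errors_distance)),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, arr in (
            ("top_surface", self.errors_top),
            ("distance", self.errors_distance),
        ):
            for it in range(arr.shape[0]):
                for b in range(arr.shape[1]):
                    rows.append(
                        {
                            "iteration": it,
                            "bin": b,
                            "model": model,
                            "mean_abs_error": arr[it, b],
                        }
                    )
        return pd.DataFrame(rows)


def plot_cv(result: CVResult, path=None):
    """Grouped bar chart of per-bin prediction error for both models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = result.summary()
    top = s[s["model"] == "top_surface"]
    dist = s[s["model"] == "distance"]
    x = np.arange(len(top))
    width = 0.38
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - width / 2, top["mean_abs_error"], width,
           yerr=top["sd_abs_error"], label="top surface", color="#3b6ea5")
    ax.bar(x + width / 2, dist["mean_abs_error"], width,
           yerr=dist["sd_abs_error"], label="distance", color="#b5651d")
    ax.set_xticks(x)
    ax.set_xticklabels(
        [f"{lo:.2f}-{hi:.2f}" for lo, hi in
         zip(result.bin_edges[:-1], result.bin_edges[1:])],
        rotation=30,
    )
    ax.set_xlabel("observed differentiation bin")
    ax.set_ylabel("mean |predicted - actual|")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _cluster_split(rng, labels, pairs, train_fraction):
    n_groups = len(labels)
    idx = rng.permutation(n_groups)
    n_train = max(int(round(train_fraction * n_groups)), 2)
    train_groups = set(idx[:n_train])
    in_train = np.array(
        [(a in train_groups) and (b in train_groups) for a, b in pairs]
    )
    in_test = np.array(
        [(a not in train_groups) and (b not in train_groups) for a, b in pairs]
    )
    return np.flatnonzero(in_train), np.flatnonzero(in_test)


def monte_carlo_cv(
    y: PairwiseMatrix,
    rd_top: PairwiseMatrix,
    geo_null: PairwiseMatrix,
    iterations: int = 100,
    train_fraction: float = 0.8,
    n_bins: int = 5,
    seed: int = 0,
    split_unit: str = "pair",
) -> CVResult:
    """Monte Carlo cross-validation of predictive differentiation.

    ``split_unit='pair'`` splits pairwise observations directly (80% of the
    data); ``'cluster'`` holds out whole clusters, avoiding shared-population
    leakage between train and test.
    """
    ym, rdm, nullm = aligned(y, rd_top, geo_null)
    yv = ym.condensed()
    xv = rdm.condensed()
    dv = nullm.condensed()
    ok = np.isfinite(yv) & np.isfinite(xv) & np.isfinite(dv)
    pairs = ym.pair_index()[ok]
    yv, xv, dv = yv[ok], xv[ok], dv[ok]
    n = len(yv)
    if n < 20:
        raise MLPEError("need at least 20 pairs for cross-validation")

    lo, hi = float(yv.min()), float(yv.max())
    if hi <= lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    rng = np.random.default_rng(seed)
    err_top = np.full((iterations, n_bins), np.nan)
    err_dist = np.full((iterations, n_bins), np.nan)

    for it in range(iterations):
        if split_unit == "cluster":
            tr, te = _cluster_split(rng, ym.labels, pairs, train_fraction)
            if len(te) == 0 or len(np.unique(pairs[tr])) < 3:
                continue
        else:
            perm = rng.permutation(n)
            n_train = int(round(train_fraction * n))
            tr, te = perm[:n_train], perm[n_train:]
        m_top = MLPERegressor().fit(xv[tr], yv[tr], pairs=pairs[tr])
        m_dist = MLPERegressor().fit(dv[tr], yv[tr], pairs=pairs[tr])
        e_top = np.abs(m_top.predict(xv[te]) - yv[te])
        e_dist = np.abs(m_dist.predict(dv[te]) - yv[te])
        which = np.clip(np.digitize(yv[te], edges[1:-1]), 0, n_bins - 1)
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                err_top[it, b] = e_top[sel].mean()
                err_dist[it, b] = e_dist[sel].mean()
    empty = np.all(np.isnan(err_top), axis=0)
    if empty.any():
        log.warning(
            "bins %s empty across all iterations", list(np.flatnonzero(empty))
        )
    return CVResult(edges, err_top, err_dist, split_unit)


def expand_to_individuals(
    cluster_matrix: PairwiseMatrix,
    individual_ids: list,
    cluster_of: dict,
) -> PairwiseMatrix:
    """Expand a cluster-level predictor to individual pairs by cluster-pair
    lookup; within-cluster pairs become NaN (excluded downstream)."""
    ids = [str(i) for i in individual_ids]
    missing = [i for i in ids if i not in cluster_of]
    if missing:
        raise MLPEError(f"individuals without cluster assignment: {missing[:5]}")
    cidx = {c: k for k, c in enumerate(cluster_matrix.labels)}
    n = len(ids)
    vals = np.zeros((n, n))
    n_within = 0
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = str(cluster_of[ids[i]]), str(cluster_of[ids[j]])
            if ci == cj:
                vals[i, j] = vals[j, i] = np.nan
                n_within += 1
            else:
                vals[i, j] = vals[j, i] = cluster_matrix.values[
                    cidx[ci], cidx[cj]
                ]
    out = PairwiseMatrix(ids, vals, "resistance", {"within_pairs": n_within})
    return out


def individual_rerun(
    individual_bc: PairwiseMatrix,
    candidates: dict,
    geo_null: PairwiseMatrix,
    cluster_of: dict,
    method: str = "ML",
) -> pd.DataFrame:
    """Between-variable comparison with individual Bray-Curtis response.

    ``candidates`` and ``geo_null`` are cluster-level matrices; they are
    expanded to individual pairs via ``cluster_of`` (individual -> cluster),
    within-cluster pairs are excluded, and the model-table comparison is
    rerun with per-individual random effects.
    """
    ids = individual_bc.labels
    expanded = {
        label: expand_to_individuals(m, ids, cluster_of)
        for label, m in candidates.items()
    }
    null_exp = expand_to_individuals(geo_null, ids, cluster_of)
    null_exp.statistic = "geo_null"
    n_within = null_exp.meta.get("within_pairs", 0)
    if n_within:
        log.info("excluded %d within-cluster individual pairs", n_within)
    return between_variable_selection(
        individual_bc, expanded, null_exp, method=method
    )
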