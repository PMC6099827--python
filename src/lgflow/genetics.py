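"""Genotype data model and genetic differentiation statistics.

The sampling unit is a diploid individual genotyped at ``L`` codominant
(microsatellite-style) loci.  Group-level differentiation between pairs of
lek clusters is measured with Nei's :math:`G_{ST}`, Hedrick's standardized
:math:`G'_{ST}` and Jost's :math:`D_{est}`; individual-level differentiation
uses Bray–Curtis dissimilarity over allele counts.  Marker-panel power is
summarized by the probability of identity.

Formulas (two groups, ``k = 2``)::

    H_S  = mean over groups of (1 - sum_a p_a^2)        (expected heterozygosity)
    H_T  = 1 - sum_a pbar_a^2,  pbar = mean frequency
    G_ST = (H_T - H_S) / H_T
    G'_ST = G_ST * (k - 1 + H_S) / ((k - 1) * (1 - H_S))     [Hedrick 2005]
    D    = ((H_T - H_S) / (1 - H_S)) * k / (k - 1)           [Jost 2008]

Multilocus values average ``H_S`` and ``H_T`` across loci *before* forming the
ratios (the Nei convention); loci lacking data in either group are dropped for
that pair.  Point estimates are clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix

MISSING = -1  # sentinel allele value for a missing locus


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with coordinates and zone labels.

    ``alleles`` has shape (n_individuals, n_loci, 2) with integer allele
    sizes; both entries of a locus are :data:`MISSING` when the locus failed
    (a half-called locus is invalid).
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    zone: np.ndarray
    alleles: np.ndarray
    locus_names: list[str] = field(default_factory=list)
    cluster_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.zone = np.asarray(self.zone, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=int)
        n = len(self.ids)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise GenotypeError("alleles must have shape (n, L, 2)")
        if self.alleles.shape[0] != n or any(
            len(a) != n for a in (self.x, self.y, self.zone)
        ):
            raise GenotypeError("column lengths disagree")
        if self.alleles.shape[1] < 1:
            raise GenotypeError("at least one locus required")
        if len(set(self.ids)) != n:
            raise GenotypeError("individual ids must be unique")
        if not self.locus_names:
            self.locus_names = [f"locus{i + 1}" for i in range(self.n_loci)]
        if len(self.locus_names) != self.n_loci:
            raise GenotypeError("locus_names length mismatch")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeError(
                f"half-called locus {self.locus_names[l]} for individual {self.ids[i]}"
            )
        if self.cluster_id is not None:
            self.cluster_id = np.asarray(self.cluster_id, dtype=object)
            if len(self.cluster_id) != n:
                raise GenotypeError("cluster_id length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_per_individual(self) -> np.ndarray:
        return (self.alleles[:, :, 0] == MISSING).sum(axis=1)

    def subset(self, keep: np.ndarray) -> "GenotypeTable":
        return replace(
            self,
            ids=self.ids[keep],
            x=self.x[keep],
            y=self.y[keep],
            zone=self.zone[keep],
            alleles=self.alleles[keep],
            cluster_id=None if self.cluster_id is None else self.cluster_id[keep],
        )

    def with_clusters(self, cluster_id: np.ndarray) -> "GenotypeTable":
        return replace(self, cluster_id=np.asarray(cluster_id, dtype=object))

    def groups(self, group_by: str = "cluster") -> np.ndarray:
        if group_by == "cluster":
            if self.cluster_id is None:
                raise GenotypeError("table has no cluster assignment")
            return self.cluster_id
        if group_by == "zone":
            return self.zone
        raise GenotypeError(f"unknown grouping {group_by!r}")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "individual_id": self.ids,
            "x": self.x,
            "y": self.y,
            "zone": self.zone,
        }
        if self.cluster_id is not None:
            data["cluster_id"] = self.cluster_id
        df = pd.DataFrame(data)
        for l, name in enumerate(self.locus_names):
            df[f"{name}_a1"] = self.alleles[:, l, 0]
            df[f"{name}_a2"] = self.alleles[:, l, 1]
        return df


def qc_filter(table: GenotypeTable, max_missing_loci: int = 5) -> GenotypeTable:
    """Drop individuals missing more than ``max_missing_loci`` loci, then
    drop exact multilocus duplicates (first occurrence kept)."""
    keep = table.missing_per_individual() <= max_missing_loci
    filtered = table.subset(keep)
    seen: set[bytes] = set()
    keep2 = np.ones(filtered.n_individuals, dtype=bool)
    for i in range(filtered.n_individuals):
        key = filtered.alleles[i].tobytes()
        if key in seen:
            keep2[i] = False
        else:
            seen.add(key)
    return filtered.subset(keep2)


@dataclass
class AlleleFrequencies:
    """Observed allele frequencies per (group, locus).

    ``freqs[g][l]`` maps allele -> frequency over called alleles only;
    ``n[g][l]`` is the number of diploid individuals with data.
    """

    group_labels: list[str]
    locus_names: list[str]
    freqs: dict
    n: dict

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def allele_frequencies(
    table: GenotypeTable, group_by: str = "cluster"
) -> AlleleFrequencies:
    groups = table.groups(group_by)
    labels = sorted({str(g) for g in groups})
    freqs: dict = {}
    counts: dict = {}
    for g in labels:
        sel = np.array([str(v) == g for v in groups])
        freqs[g] = {}
        counts[g] = {}
        any_data = False
        for l, name in enumerate(table.locus_names):
            a = table.alleles[sel, l, :].ravel()
            a = a[a != MISSING]
            counts[g][name] = len(a) // 2
            if len(a) == 0:
                freqs[g][name] = {}
                continue
            any_data = True
            vals, cnt = np.unique(a, return_counts=True)
            freqs[g][name] = {int(v): c / len(a) for v, c in zip(vals, cnt)}
        if not any_data:
            raise GenotypeError(f"group {g!r} has no called alleles at any locus")
    return AlleleFrequencies(labels, list(table.locus_names), freqs, counts)


def _expected_het(p: dict) -> float:
    return 1.0 - sum(v * v for v in p.values())


def pairwise_differentiation(
    freqs: AlleleFrequencies,
    statistic: str = "gst_prime",
    bias_correction: bool = False,
) -> PairwiseMatrix:
    """Pairwise multilocus differentiation between all groups.

    ``statistic`` is one of ``gst_prime`` (Hedrick), ``gst`` (Nei) or
    ``jost_d``.  With ``bias_correction`` the Nei–Chesser small-sample
    estimators are used: ``H_S`` is scaled by ``2ñ/(2ñ-1)`` (ñ the harmonic
    mean sample size of the pair) and ``H_T`` gains the ``+H_S/(2ñk)`` term,
    removing the upward bias of the plug-in statistic at small samples.
    """
    if statistic not in ("gst_prime", "gst", "jost_d"):
        raise GenotypeError(f"unknown differentiation statistic {statistic!r}")
    if freqs.n_groups < 2:
        raise GenotypeError("need at least two groups")
    k = 2.0  # statistics are pairwise throughout
    labels = freqs.group_labels
    out = np.zeros((len(labels), len(labels)))
    for (i, gi), (j, gj) in combinations(enumerate(labels), 2):
        hs_terms, ht_terms = [], []
        for name in freqs.locus_names:
            pi, pj = freqs.freqs[gi][name], freqs.freqs[gj][name]
            if not pi or not pj:
                continue
            hs = (_expected_het(pi) + _expected_het(pj)) / 2
            alleles = set(pi) | set(pj)
            pbar = {a: (pi.get(a, 0.0) + pj.get(a, 0.0)) / 2 for a in alleles}
            ht = _expected_het(pbar)
            if bias_correction:
                ni, nj = freqs.n[gi][name], freqs.n[gj][name]
                if ni > 0 and nj > 0:
                    n_tilde = 2.0 / (1.0 / ni + 1.0 / nj)
                    hs = hs * 2 * n_tilde / (2 * n_tilde - 1)
                    ht = ht + hs / (2 * n_tilde * k)
            hs_terms.append(hs)
            ht_terms.append(ht)
        if not hs_terms:
            raise GenotypeError(f"groups {gi!r}/{gj!r} share no called loci")
        hs = float(np.mean(hs_terms))
        ht = float(np.mean(ht_terms))
        if ht <= 0:
            value = 0.0
        else:
            gst = (ht - hs) / ht
            if statistic == "gst":
                value = gst
            elif statistic == "gst_prime":
                value = 1.0 if hs >= 1 else gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
            else:
                value = 0.0 if hs >= 1 else (ht - hs) / (1 - hs) * k / (k - 1)
        out[i, j] = out[j, i] = min(max(value, 0.0), 1.0)
    return PairwiseMatrix(labels, out, statistic)


def bray_curtis_individual(table: GenotypeTable) -> PairwiseMatrix:
    """Bray–Curtis dissimilarity between individuals' allele-count vectors.

    Each locus called in both individuals contributes two allele counts per
    individual; BC = 1 - 2*sum(min)/sum(total) over shared loci.  Pairs with
    no shared called loci are flagged missing (NaN) and counted in
    ``meta['missing_pairs']``.
    """
    n = table.n_individuals
    if n < 2:
        raise GenotypeError("need at least two individuals")
    out = np.zeros((n, n))
    called = table.alleles[:, :, 0] != MISSING
    any_missing_pair = False
    for i, j in combinations(range(n), 2):
        shared = called[i] & called[j]
        if not shared.any():
            out[i, j] = out[j, i] = np.nan
            any_missing_pair = True
            continue
        num = 0.0
        tot = 0
        for l in np.flatnonzero(shared):
            ci: dict[int, int] = {}
            cj: dict[int, int] = {}
            for a in table.alleles[i, l]:
                ci[a] = ci.get(a, 0) + 1
            for a in table.alleles[j, l]:
                cj[a] = cj.get(a, 0) + 1
            num += sum(min(ci[a], cj.get(a, 0)) for a in ci)
            tot += 4
        bc = 1.0 - 2.0 * num / tot
        out[i, j] = out[j, i] = bc
    m = PairwiseMatrix(list(table.ids), out, "bray_curtis")
    if any_missing_pair:
        m.meta["missing_pairs"] = int(np.isnan(out).sum() // 2)
    return m


def probability_identity(freqs: AlleleFrequencies) -> tuple[dict, float]:
    """Probability of identity per locus and its product across loci.

    PID_l = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2, frequencies pooled over the
    single group in ``freqs`` (pass a table grouped by a constant label to
    pool everything).
    """
    if freqs.n_groups != 1:
        raise GenotypeError("probability of identity expects pooled frequencies")
    g = freqs.group_labels[0]
    per_locus: dict[str, float] = {}
    overall = 1.0
    for name in freqs.locus_names:
        p = list(freqs.freqs[g][name].values())
        if not p:
            continue
        pid = sum(v**4 for v in p)
        for a, b in combinations(p, 2):
            pid += (2 * a * b) ** 2
        per_locus[name] = pid
        overall *= pid
    return per_locus, overall
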