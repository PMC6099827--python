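"""Labeled symmetric pairwise matrices.

All stages of the pipeline exchange square, labeled, zero-diagonal matrices:
genetic differentiation between lek clusters, effective resistance between
cluster supernodes, and the geographic-null resistance.  Effective-resistance
matrices may contain non-finite entries marking pairs of clusters that fall in
different connected components of the landscape graph; every other statistic
must be finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STATISTICS = {
    "gst_prime",
    "gst",
    "jost_d",
    "bray_curtis",
    "resistance",
    "geo_null",
    "geo_distance",
}


class MatrixError(ValueError):
    pass


@dataclass
class PairwiseMatrix:
    labels: list[str]
    values: np.ndarray
    statistic: str = "gst_prime"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(lab) for lab in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixError("duplicate labels")
        if self.values.shape != (n, n):
            raise MatrixError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.statistic not in VALID_STATISTICS:
            raise MatrixError(f"unknown statistic {self.statistic!r}")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite & finite.T, self.values.T, 0.0),
            atol=1e-10,
            rtol=0.0,
        ) or not np.array_equal(finite, finite.T):
            raise MatrixError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise MatrixError("diagonal must be zero")
        if (
            self.statistic not in ("resistance", "geo_null", "bray_curtis")
            and not finite.all()
        ):
            raise MatrixError(f"{self.statistic} matrix must be finite")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair_index(self) -> np.ndarray:
        """(n_pairs, 2) int array of upper-triangle index pairs (i < j)."""
        iu = np.triu_indices(self.n, k=1)
        return np.column_stack(iu)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def finite_pairs(self) -> np.ndarray:
        """Boolean mask over condensed entries: True where finite."""
        return np.isfinite(self.condensed())

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(str(lab)) for lab in labels]
        return PairwiseMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.statistic,
            dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        pairs = self.pair_index()
        return pd.DataFrame(
            {
                "id1": [self.labels[i] for i in pairs[:, 0]],
                "id2": [self.labels[j] for j in pairs[:, 1]],
                "value": self.condensed(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path, statistic: str) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), statistic)

    @classmethod
    def from_condensed(
        cls, labels, condensed: np.ndarray, statistic: str
    ) -> "PairwiseMatrix":
        labels = [str(lab) for lab in labels]
        n = len(labels)
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals[iu] = condensed
        vals = vals + vals.T
        return cls(labels, vals, statistic)


def aligned(*matrices: PairwiseMatrix) -> list[PairwiseMatrix]:
    """Reorder all matrices to the first one's labels; error on mismatch."""
    ref = matrices[0]
    out = [ref]
    for m in matrices[1:]:
        if set(m.labels) != set(ref.labels):
            raise MatrixError(
                f"label sets differ: {sorted(set(ref.labels) ^ set(m.labels))}"
            )
        out.append(m if m.labels == ref.labels else m.reorder(ref.labels))
    return out
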