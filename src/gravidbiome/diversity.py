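"""Alpha diversity, Good's coverage, Bray-Curtis dissimilarity, and PCoA.

Alpha metrics are computed on unrarefied counts; read depth is handled
downstream as a model covariate rather than by rarefying.  Shannon H uses
log base 2 by default, and evenness is H / log2(Sobs) (defined as 1 for a
single-taxon sample).  Chao1 uses the bias-corrected estimator so it
stays finite when there are no doubletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from gravidbiome.feature_tables import CountTable


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def sobs(counts) -> int:
    """Observed richness: number of taxa with a positive count."""
    return int((_as_counts(counts) > 0).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton and doubleton counts.

    Bias-corrected form ``S + F1(F1-1) / (2(F2+1))`` by default; the
    classic ``S + F1^2 / (2 F2)`` is available (infinite when F2=0 with
    singletons present).
    """
    arr = _as_counts(counts)
    s = sobs(arr)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float("inf") if f1 > 0 else float(s)
    return s + f1 * f1 / (2.0 * f2)


def shannon(counts, log_base: float = 2.0) -> tuple[float, float]:
    """Shannon diversity H and evenness H / log(Sobs).

    Evenness is defined as 1.0 when the sample has at most one taxon.
    """
    arr = _as_counts(counts).astype(float)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no diversity")
    p = arr[arr > 0] / total
    h = float(-(p * (np.log(p) / np.log(log_base))).sum())
    s = len(p)
    if s <= 1:
        return 0.0, 1.0
    return h, h / (np.log(s) / np.log(log_base))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: fraction of reads from seen-twice+ taxa."""
    arr = _as_counts(counts)
    n = arr.sum()
    if n == 0:
        raise ValueError("empty library has undefined coverage")
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / float(n)


def alpha_table(table: CountTable, log_base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha-diversity table.

    Columns: ``sobs, chao1, shannon_h, evenness, goods``, indexed by
    sample id in table order.
    """
    records = []
    for sample in table.samples:
        v = table.data[sample].to_numpy()
        h, e = shannon(v, log_base=log_base)
        records.append(
            {
                "sample_id": sample,
                "sobs": sobs(v),
                "chao1": chao1(v),
                "shannon_h": h,
                "evenness": e,
                "goods": goods_coverage(v),
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


def bray_curtis(table: CountTable, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    With ``normalize=True`` (default) samples are first converted to
    relative abundances, so libraries of very different depth remain
    comparable; raw-count mode is available for completeness.
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    if normalize:
        profiles = table.relative_abundance().to_numpy().T
    else:
        if (table.depths() == 0).any():
            raise ValueError("a sample with zero total has undefined dissimilarity")
        profiles = table.data.to_numpy().T.astype(float)
    condensed = pdist(profiles, metric="braycurtis")
    return DistanceMatrix(table.samples, squareform(condensed))


@dataclass
class Ordination:
    """PCoA coordinates with per-axis eigenvalues and variance explained."""

    ids: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def gower_center(dm_values: np.ndarray) -> np.ndarray:
    """Gower-centered -D^2/2 matrix used by classical scaling and PERMANOVA."""
    a = -0.5 * np.asarray(dm_values, dtype=float) ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposes the Gower-centered matrix; axes are ordered by
    decreasing eigenvalue.  Negative eigenvalues (non-Euclidean part of
    the dissimilarity) are dropped and excluded from the
    variance-explained denominator.
    """
    g = gower_center(dm.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, abs(eigvals[0]) * 1e-10) if len(eigvals) else 0.0
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    rank = len(pos_vals)
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but positive rank is {rank}; truncating",
            stacklevel=2,
        )
        n_axes = rank
    coords = pos_vecs[:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    total = pos_vals.sum()
    explained = pos_vals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return Ordination(list(dm.ids), coords, pos_vals[:n_axes], explained)
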