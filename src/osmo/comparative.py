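"""Global response comparison: PCA, Cityblock cladograms, Jukes-Cantor
distances and Mantel-style distance-matrix correlation.

Fold-change matrices (rows = organism or organism/stress-level samples,
columns = metabolites) are compared globally by principal components and
by Cityblock (Manhattan) distances; phylogenetic distances come from the
Jukes-Cantor correction of pairwise mismatch fractions on an aligned
small-subunit rRNA alignment. The association between the metabolic and
phylogenetic distance structures is assessed by a permutation Mantel
test with a secondary (approximate) t statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ValidationError

GAP_CHARS = {"-", ".", "N", "?"}


# ---------------------------------------------------------------------------
# PCA


def pca_scores(fc_matrix) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a samples x metabolites fold-change matrix via SVD.

    Missing fold-changes are imputed to 0 (= unchanged relative to the
    control) before column-centering. Returns (scores, loadings,
    explained variance fractions); scores @ loadings.T reconstructs the
    centered matrix.
    """
    df = pd.DataFrame(fc_matrix).astype(float)
    if df.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 rows")
    x = df.fillna(0.0).to_numpy()
    if np.allclose(x, 0):
        raise ValidationError("all-zero matrix has no principal components")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    ev = s**2
    frac = ev / ev.sum()
    k = len(s)
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=df.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=df.columns, columns=pcs)
    return scores, loadings, frac


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str = ""
    undefined: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape must match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = self.values[np.isfinite(self.values)]
        if (finite < 0).any():
            raise ValidationError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def cityblock_distances(fc_matrix) -> DistanceMatrix:
    """Pairwise Cityblock (Manhattan) distances between matrix rows.

    Each pair is summed over its pairwise-complete (both non-missing)
    columns, so missing fold-changes do not dilute the distance.
    """
    df = pd.DataFrame(fc_matrix).astype(float)
    x = df.to_numpy()
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if not both.any():
                raise ValidationError(
                    f"rows {df.index[i]!r} and {df.index[j]!r} share no columns"
                )
            d[i, j] = d[j, i] = np.abs(x[i, both] - x[j, both]).sum()
    return DistanceMatrix([str(i) for i in df.index], d, metric="cityblock")


# ---------------------------------------------------------------------------
# hierarchical clustering with Newick export


@dataclass
class ClusterTree:
    """Rooted binary merge tree from agglomerative clustering."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> DistanceMatrix:
        d = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(self.labels, squareform(d), metric="cophenetic")

    def to_newick(self) -> str:
        """Newick string; branch lengths are half the merge-height gaps so
        that the leaf-to-leaf path length equals the cophenetic distance."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        for row, (a, b, h, _) in enumerate(self.linkage):
            heights[n + row] = h

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage[i - n]
            parts = []
            for child in (int(a), int(b)):
                bl = (h - heights[child]) / 2.0
                parts.append(f"{node(child)}:{bl:.10g}")
            return "(" + ",".join(parts) + ")"

        return node(n + len(self.linkage) - 1) + ";"


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a distance matrix.

    Ties are broken deterministically by scipy's left-to-right order of
    the condensed matrix, which follows label order.
    """
    if linkage not in {"single", "complete", "average", "ward"}:
        raise ValidationError(f"unsupported linkage {linkage!r}")
    z = hierarchy.linkage(d.condensed(), method=linkage)
    return ClusterTree(labels=list(d.labels), linkage=z)


# ---------------------------------------------------------------------------
# Jukes-Cantor distances


def jukes_cantor_pair(a: str, b: str) -> float:
    """Jukes-Cantor distance between two aligned sequences.

    The mismatch fraction p is computed over columns where both
    sequences have non-gap characters; d = -3/4 ln(1 - 4p/3). p >= 3/4
    (beyond the model's saturation point) yields NaN.
    """
    if len(a) != len(b):
        raise ValidationError("sequences must be aligned to equal length")
    arr_a = np.frombuffer(a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(b.upper().encode(), dtype="S1")
    gaps = np.isin(arr_a, [g.encode() for g in GAP_CHARS]) | np.isin(
        arr_b, [g.encode() for g in GAP_CHARS]
    )
    both = ~gaps
    n = int(both.sum())
    if n == 0:
        raise ValidationError("no comparable (both non-gap) columns")
    p = float((arr_a[both] != arr_b[both]).sum()) / n
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def jukes_cantor_distances(alignment: dict[str, str]) -> DistanceMatrix:
    labels = list(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            dij = jukes_cantor_pair(alignment[labels[i]], alignment[labels[j]])
            d[i, j] = d[j, i] = dij
            if np.isnan(dij):
                undefined.add((labels[i], labels[j]))
    return DistanceMatrix(labels, d, metric="jukes-cantor", undefined=undefined)


# ---------------------------------------------------------------------------
# Mantel-style distance correlation


@dataclass
class MantelResult:
    r: float
    p_perm: float  # permutation p, one-sided for positive association
    p_t: float  # approximate t-based p, two-sided
    n_perm: int
    n_labels: int

    def summary(self) -> str:
        return (
            "Distance-matrix correlation (Mantel)\n"
            "====================================\n"
            f"{'labels':<22}{self.n_labels:>14}\n"
            f"{'Pearson R':<22}{self.r:>14.4f}\n"
            f"{'permutation p':<22}{self.p_perm:>14.4g}\n"
            f"{'approx. t-test p':<22}{self.p_t:>14.4g}\n"
            f"{'permutations':<22}{self.n_perm:>14}\n"
        )


def distance_correlation_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Correlate two distance matrices over matched labels.

    R is the Pearson correlation of the n(n-1)/2 upper-triangle entries.
    The primary p-value comes from a Mantel permutation null (relabeling
    one matrix, one-sided for positive association); a t statistic on R
    with n(n-1)/2 - 2 df is reported alongside as an approximation (the
    pairs are not independent, so it is optimistic).
    """
    if list(d1.labels) != list(d2.labels):
        if set(d1.labels) != set(d2.labels):
            raise ValidationError("distance matrices have different labels")
        order = [d2.labels.index(lb) for lb in d1.labels]
        d2 = DistanceMatrix(
            list(d1.labels), d2.values[np.ix_(order, order)], metric=d2.metric
        )
    n = len(d1.labels)
    if n < 4:
        raise ValidationError("need >= 4 labels")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    r = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    count = 0
    xm = d1.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = xm[np.ix_(perm, perm)][iu]
        yv = d2.values[iu]
        okp = np.isfinite(xp) & np.isfinite(yv)
        rp = np.corrcoef(xp[okp], yv[okp])[0, 1]
        if rp >= r:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)

    m = len(x)
    if abs(r) >= 1.0:
        p_t = 0.0
    else:
        t = r * np.sqrt((m - 2) / (1.0 - r**2))
        p_t = float(2 * stats.t.sf(abs(t), df=m - 2))
    return MantelResult(r=r, p_perm=p_perm, p_t=p_t, n_perm=n_perm, n_labels=n)
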