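"""Community-structure stage: band filtering, Bray-Curtis distances,
principal coordinates, UPGMA clustering, and multi-term PERMANOVA.

The PERMANOVA here is the sequential (Type I) partition of the Gower-centered
squared-distance matrix, ``dist ~ source + inoculum``: each term's sum of
squares is the trace increment of nested hat-matrix projections, pseudo-F
compares the term mean square to the residual mean square, and p-values come
from free permutation of sample labels (add-one estimator), switching to
exhaustive enumeration of all distinct label arrangements when that space is
small.  scikit-bio's one-way PERMANOVA covers only a single factor, which is
why the partition is computed directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sympy.utilities.iterables import multiset_permutations

from .data import BandMatrix, SampleTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "Dendrogram",
    "Permanova",
    "PermanovaResults",
    "filter_low_frequency",
    "bray_curtis",
    "pcoa",
    "upgma",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if d.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix size does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValidationError("distances must be nonnegative")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def filter_low_frequency(matrix: BandMatrix, min_freq: float = 0.25) -> BandMatrix:
    """Drop bands present (intensity > 0) in fewer than ``min_freq`` of samples.

    The boundary is inclusive: a band present in exactly ``min_freq`` of the
    samples is retained.  Sample set and band order are unchanged.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must lie in (0, 1]")
    freq = matrix.presence().mean(axis=0)
    keep = [b for b in matrix.band_ids if freq[b] >= min_freq - 1e-12]
    if not keep:
        raise ValidationError("frequency filter removed every band")
    return matrix.subset_bands(keep)


def bray_curtis(matrix: BandMatrix, normalize: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d = 1 - 2*sum(min)/(sum x + sum y).

    With ``normalize`` each sample row is rescaled to unit total first — gel
    lanes differ in total signal, so relative band intensities are compared
    by default.
    """
    if matrix.n_samples < 2:
        raise ValidationError("need at least 2 samples for distances")
    values = matrix.values()
    totals = values.sum(axis=1)
    if (totals == 0).any():
        zero = [s for s, t in zip(matrix.sample_ids, totals) if t == 0]
        raise ValidationError(f"all-zero samples have undefined distances: {zero}")
    if normalize:
        values = values / totals[:, None]
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(matrix.sample_ids, d)


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """Classical-scaling embedding of a distance matrix.

    ``eigenvalues`` holds the full nonincreasing spectrum of the
    Gower-centered matrix, negative values included; ``coordinates`` carries
    axes for positive eigenvalues only.  ``proportion_explained`` is each
    positive eigenvalue over the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dist: DistanceMatrix, k: int | None = None) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposes the double-centered ``-d**2/2`` matrix; axes are ordered
    by eigenvalue and scaled by sqrt(eigenvalue).  Axes of nonpositive
    eigenvalues are excluded from the coordinates (a warning is emitted if
    ``k`` exceeds the positive-eigenvalue count).
    """
    n = dist.n
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be at most n_samples - 1")
    g = _gower_center(dist.data)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals > 1e-10).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; reducing",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos = eigvals[eigvals > 1e-10]
    prop = pos / pos.sum() if len(pos) else np.array([])
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=dist.sample_ids, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Average-linkage merge history.

    ``merges`` follows the scipy linkage convention: row t merges cluster ids
    ``i`` and ``j`` (ids < n are leaves) at ``height`` into cluster ``n + t``
    of ``size`` leaves.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int] = field(default_factory=list)

    def cophenetic(self) -> DistanceMatrix:
        """Distance at which each leaf pair is first merged."""
        n = len(self.leaf_ids)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        d = np.zeros((n, n))
        for t, (i, j, h, _size) in enumerate(self.merges):
            for a in members[i]:
                for b in members[j]:
                    d[a, b] = d[b, a] = h
            members[n + t] = members.pop(i) + members.pop(j)
        return DistanceMatrix(self.leaf_ids, d)

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf depth equals half the root height."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_ids[i] for i in range(n)}
        for t, (i, j, h, _size) in enumerate(self.merges):
            bl_i = h / 2 - height[i] / 2
            bl_j = h / 2 - height[j] / 2
            node[n + t] = f"({node[i]}:{bl_i:g},{node[j]}:{bl_j:g})"
            height[n + t] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration.

    Ties between candidate merges are broken toward the lowest cluster-id
    pair, so the result is fully deterministic.  Average linkage is
    reducible, hence merge heights are nondecreasing.
    """
    n = dist.n
    if n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    d = {(i, j): dist.data[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((d[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        h, (i, j) = best
        new_size = size[i] + size[j]
        merges.append((i, j, h, new_size))
        for other in active:
            if other in (i, j):
                continue
            dij = (
                size[i] * d[(min(i, other), max(i, other))]
                + size[j] * d[(min(j, other), max(j, other))]
            ) / new_size
            d[(min(other, next_id), max(other, next_id))] = dij
        active = [a for a in active if a not in (i, j)] + [next_id]
        size[next_id] = new_size
        next_id += 1

    order: list[int] = []

    def _collect(node: int) -> None:
        if node < n:
            order.append(node)
        else:
            i, j, _, _ = merges[node - n]
            _collect(i)
            _collect(j)

    _collect(next_id - 1)
    return Dendrogram(dist.sample_ids, merges, order)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class PermanovaResults:
    """Sequential distance-based ANOVA table with permutation p-values."""

    def __init__(self, table: pd.DataFrame, n_permutations: int, exhaustive: bool):
        self.table = table
        self.n_permutations = n_permutations
        self.exhaustive = exhaustive

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def summary(self) -> str:
        mode = (
            f"exhaustive ({self.n_permutations} distinct arrangements)"
            if self.exhaustive
            else f"{self.n_permutations} free permutations"
        )
        lines = ["PERMANOVA (sequential sums of squares)", f"Permutations: {mode}", ""]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class Permanova:
    """Permutational multivariate ANOVA of a distance matrix.

    Parameters
    ----------
    dist : DistanceMatrix
        Between-sample dissimilarities (here: Bray-Curtis).
    samples : SampleTable or DataFrame
        Factor table indexed by sample id.
    terms : sequence of str
        Factor columns, fitted sequentially in the given order.
    """

    def __init__(self, dist: DistanceMatrix, samples: SampleTable | pd.DataFrame, terms=("source", "inoculum")):
        df = samples.table if isinstance(samples, SampleTable) else samples
        df = df.loc[dist.sample_ids]
        self.dist = dist
        self.terms = list(terms)
        for t in self.terms:
            if t not in df.columns:
                raise ValueError(f"term {t!r} is not a sample-table column")
            if df[t].nunique() < 2:
                raise ValidationError(f"factor {t!r} has a single level")
        self.labels = df[self.terms].copy()

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _hat(x: np.ndarray) -> np.ndarray:
        # pseudoinverse projector: robust to the rank deficiency of full
        # dummy codings (intercept + all factor levels)
        return x @ np.linalg.pinv(x)

    def _projectors(self, labels: pd.DataFrame):
        """Nested hat-matrix increments for the sequential partition."""
        n = len(labels)
        x = np.ones((n, 1))
        hats = [self._hat(x)]
        for t in self.terms:
            dummies = pd.get_dummies(labels[t].astype(str), dtype=float).to_numpy()
            x = np.hstack([x, dummies])
            hats.append(self._hat(x))
        increments = [hats[k + 1] - hats[k] for k in range(len(self.terms))]
        residual = np.eye(n) - hats[-1]
        dfs = [int(round(np.trace(p))) for p in increments]
        df_res = int(round(np.trace(residual)))
        return increments, residual, dfs, df_res

    def _f_stats(self, g: np.ndarray, increments, residual, dfs, df_res):
        ss = np.array([(p * g).sum() for p in increments])
        ss_res = (residual * g).sum()
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, f

    def _n_distinct(self) -> int:
        keys = [tuple(row) for row in self.labels.astype(str).to_numpy()]
        counts: dict[tuple, int] = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        total = math.factorial(len(keys))
        for c in counts.values():
            total //= math.factorial(c)
        return total

    # -- fitting -----------------------------------------------------------
    def fit(self, n_permutations: int = 9999, seed: int | None = None, exhaustive: str | bool = "auto") -> PermanovaResults:
        """Partition the distance matrix and attach permutation p-values.

        ``exhaustive='auto'`` enumerates every distinct label arrangement
        when there are at most 10,000 of them (exact p, identity included);
        otherwise ``n_permutations`` free label permutations are drawn and
        the add-one estimator p = (1 + #{F* >= F}) / (1 + n_perm) is used.
        """
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        g = _gower_center(self.dist.data)
        increments, residual, dfs, df_res = self._projectors(self.labels)
        ss, ss_res, f_obs = self._f_stats(g, increments, residual, dfs, df_res)
        ss_total = float(np.trace(g))

        n_distinct = self._n_distinct()
        use_exhaustive = (
            exhaustive is True or (exhaustive == "auto" and n_distinct <= 10_000)
        )
        if use_exhaustive:
            exceed = np.zeros(len(self.terms))
            count = 0
            rows = [tuple(r) for r in self.labels.astype(str).to_numpy()]
            for arrangement in multiset_permutations(rows):
                perm_labels = pd.DataFrame(
                    arrangement, index=self.labels.index, columns=self.terms
                )
                inc_p, res_p, dfs_p, dfr_p = self._projectors(perm_labels)
                _, _, f_perm = self._f_stats(g, inc_p, res_p, dfs_p, dfr_p)
                exceed += f_perm >= f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))
                count += 1
            p = exceed / count
            n_reported = count
        else:
            if seed is None:
                raise ValueError("a seed is required for random permutations")
            rng = np.random.default_rng(seed)
            exceed = np.zeros(len(self.terms))
            n = self.dist.n
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                gp = g[np.ix_(perm, perm)]
                _, _, f_perm = self._f_stats(gp, increments, residual, dfs, df_res)
                exceed += f_perm >= f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))
            p = (1.0 + exceed) / (1.0 + n_permutations)
            n_reported = n_permutations

        rows = []
        for k, t in enumerate(self.terms):
            rows.append(
                {
                    "df": dfs[k],
                    "SS": ss[k],
                    "F": f_obs[k],
                    "R2": ss[k] / ss_total,
                    "p": p[k],
                }
            )
        rows.append(
            {"df": df_res, "SS": ss_res, "F": np.nan, "R2": ss_res / ss_total, "p": np.nan}
        )
        rows.append({"df": self.dist.n - 1, "SS": ss_total, "F": np.nan, "R2": 1.0, "p": np.nan})
        table = pd.DataFrame(rows, index=[*self.terms, "Residual", "Total"])
        return PermanovaResults(table, n_reported, use_exhaustive)


def permanova(
    dist: DistanceMatrix,
    samples: SampleTable | pd.DataFrame,
    terms=("source", "inoculum"),
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: str | bool = "auto",
) -> PermanovaResults:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(dist, samples, terms).fit(n_perm, seed, exhaustive)
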