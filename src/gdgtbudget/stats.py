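"""Community/lipid multivariate statistics: Bray-Curtis, NMDS, Mantel.

These are deliberately self-contained implementations (the package's tests
cross-check them against independent references):

* Bray-Curtis dissimilarity BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i),
  bounded in [0, 1] for non-negative vectors. Not scale-invariant, which is
  why community rows are converted to relative abundances first.
* Non-metric multidimensional scaling (NMDS) by iterated Guttman updates
  with monotone (isotonic, pool-adjacent-violators) regression of
  configuration distances on the input dissimilarities, minimizing Kruskal
  stress-1 = sqrt(sum(d - dhat)^2 / sum d^2) where d are configuration
  distances and dhat the fitted monotone disparities. Ties in the
  dissimilarities are handled by the primary (weak) approach. Best of
  ``n_restarts`` random starts; a monotone safeguard stops an iteration that
  would increase stress, so the recorded stress history is non-increasing.
* Mantel test: Pearson correlation of the strictly-upper triangles, with a
  one-tailed (positive association) permutation p-value
  p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), permuting the rows and
  columns of the second matrix jointly.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import DataError, UndefinedResultError


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DataError("vectors must be 1-D and of equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise DataError("abundances must be non-negative")
    denom = float((xa + ya).sum())
    if denom == 0:
        raise UndefinedResultError("Bray-Curtis undefined: both vectors are all zero")
    return float(np.abs(xa - ya).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame, relative: bool = True) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between the rows of a samples x
    features table. Rows are converted to relative abundances first by
    default (Bray-Curtis is not scale-invariant)."""
    mat = np.asarray(table, dtype=float)
    ids = [str(i) for i in table.index] if isinstance(table, pd.DataFrame) else [str(i) for i in range(len(mat))]
    sums = mat.sum(axis=1)
    if (sums == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sums == 0)]
        raise DataError(f"all-zero rows: {bad}")
    if relative:
        mat = mat / sums[:, None]
    n = len(mat)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(mat[i], mat[j])
    return DistanceMatrix(out, ids)


# ---------------------------------------------------------------------------
# NMDS

def _pava(y: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit (pool adjacent violators)."""
    values: list[float] = []
    weights: list[float] = []
    counts: list[int] = []
    for v in y:
        values.append(float(v))
        weights.append(1.0)
        counts.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            w = weights[-2] + weights[-1]
            values[-2] = (values[-2] * weights[-2] + values[-1] * weights[-1]) / w
            weights[-2] = w
            counts[-2] += counts[-1]
            del values[-1], weights[-1], counts[-1]
    return np.repeat(values, counts)


def _disparities(delta: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Monotone regression of configuration distances d on dissimilarities
    delta. Ties in delta are pre-sorted by d (primary/weak tie handling), so
    tied dissimilarities do not force pooling."""
    order = np.lexsort((d, delta))
    out = np.empty_like(d)
    out[order] = _pava(d[order])
    return out


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0:
        return np.inf
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def kruskal_stress(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of an existing configuration against a square
    dissimilarity matrix (direct evaluation of the stress formula)."""
    delta = np.asarray(dissimilarities, dtype=float)[np.triu_indices(len(dissimilarities), 1)]
    d = pdist(np.asarray(coordinates, dtype=float))
    return _stress1(d, _disparities(delta, d))


def _guttman(X: np.ndarray, d: np.ndarray, dhat: np.ndarray, n: int) -> np.ndarray:
    ratio = np.zeros_like(d)
    nz = d > 0
    ratio[nz] = dhat[nz] / d[nz]
    B = -squareform(ratio)
    B[np.diag_indices(n)] = -B.sum(axis=1)
    Xn = B @ X / n
    return Xn - Xn.mean(axis=0)


def _as_square(D) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(D, DistanceMatrix):
        return np.asarray(D.data, dtype=float), list(D.ids)
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise DataError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise DataError("distance matrix must have a zero diagonal")
    if (arr < 0).any():
        raise DataError("distances must be non-negative")
    return arr, None


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n x ndim, centered at the origin
    stress: float
    converged: bool
    n_restarts_used: int
    stress_history: list[float]
    ids: list[str] | None = None


class NMDS:
    """Non-metric MDS with a fit-style interface.

    Parameters
    ----------
    n_components : target dimensionality (2 for ordination plots).
    n_restarts : random initializations; the lowest-stress solution wins.
    max_iter, tol : per-restart iteration cap and stress-decrease tolerance.
    seed : seed for the restart initializations (fixed seed => fixed result).

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (n, n_components) coordinates, centered at the origin.
    stress_ : final Kruskal stress-1.
    converged_ : whether the stress decrease fell below ``tol``.
    stress_history_ : stress after each accepted iteration of the best
        restart; non-increasing by construction.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 20,
                 max_iter: int = 300, tol: float = 1e-6, seed: int | None = None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, D) -> "NMDS":
        mat, ids = _as_square(D)
        n = mat.shape[0]
        if n < 3:
            raise DataError("NMDS needs at least 3 objects")
        iu = np.triu_indices(n, 1)
        delta = mat[iu]
        degenerate = bool(np.ptp(delta) < 1e-12)
        if degenerate:
            warnings.warn("all dissimilarities are equal; NMDS configuration is arbitrary",
                          stacklevel=2)
        rng = np.random.default_rng(self.seed)
        best: tuple[np.ndarray, float, bool, list[float]] | None = None
        for _ in range(self.n_restarts):
            X0 = rng.uniform(-1.0, 1.0, size=(n, self.n_components))
            run = self._single_run(delta, X0)
            if best is None or run[1] < best[1]:
                best = run
        assert best is not None
        X, stress, converged, history = best
        self.embedding_ = X - X.mean(axis=0)
        self.stress_ = stress
        self.converged_ = converged and not degenerate
        self.stress_history_ = history
        self.n_restarts_used_ = self.n_restarts
        self.ids_ = ids
        return self

    def _single_run(self, delta: np.ndarray, X0: np.ndarray):
        n = X0.shape[0]
        X = X0 - X0.mean(axis=0)
        d = pdist(X)
        dhat = _disparities(delta, d)
        s = _stress1(d, dhat)
        history = [s]
        converged = False
        for _ in range(self.max_iter):
            Xn = _guttman(X, d, dhat, n)
            dn = pdist(Xn)
            dhn = _disparities(delta, dn)
            sn = _stress1(dn, dhn)
            if sn > s + 1e-12:  # monotone safeguard: never accept a stress increase
                break
            X, d, dhat = Xn, dn, dhn
            history.append(sn)
            if s - sn < self.tol:
                s = sn
                converged = True
                break
            s = sn
        return X, history[-1], converged, history


def nmds(D, ndim: int = 2, n_restarts: int = 20, max_iter: int = 300,
         tol: float = 1e-6, seed: int | None = None) -> OrdinationResult:
    """Functional wrapper around :class:`NMDS`."""
    model = NMDS(n_components=ndim, n_restarts=n_restarts,
                 max_iter=max_iter, tol=tol, seed=seed).fit(D)
    return OrdinationResult(
        coordinates=model.embedding_,
        stress=model.stress_,
        converged=model.converged_,
        n_restarts_used=model.n_restarts_used_,
        stress_history=model.stress_history_,
        ids=model.ids_,
    )


# ---------------------------------------------------------------------------
# Mantel test

class MantelResult(NamedTuple):
    r: float
    p: float
    n_perm: int


def mantel(D1, D2, n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """One-tailed (positive association) permutation Mantel test.

    Requires identically labelled/ordered matrices. The permutation p-value
    uses the +1 correction, so its minimum is 1/(n_perm + 1).
    """
    m1, ids1 = _as_square(D1)
    m2, ids2 = _as_square(D2)
    if m1.shape != m2.shape:
        raise DataError("distance matrices differ in size")
    if ids1 is not None and ids2 is not None and ids1 != ids2:
        raise DataError("distance matrix labels do not match")
    n = m1.shape[0]
    if n < 4:
        raise DataError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, 1)
    v1 = m1[iu]
    v2 = m2[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise UndefinedResultError("Mantel r undefined: a matrix has zero variance")
    z1 = (v1 - v1.mean()) / v1.std()
    r = float((z1 * (v2 - v2.mean()) / v2.std()).mean())

    rng = np.random.default_rng(seed)
    # joint row/column permutations preserve the off-diagonal value multiset,
    # so the permuted mean and std equal those of v2
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = m2[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n*(n-1)/2)
    r_perm = (z1[None, :] * (permuted - v2.mean()) / v2.std()).mean(axis=1)
    p = float((1 + int((r_perm >= r).sum())) / (1 + n_perm))
    return MantelResult(r=r, p=p, n_perm=n_perm)
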