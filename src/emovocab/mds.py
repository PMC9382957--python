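"""Two-dimensional multidimensional scaling of vignette co-naming patterns.

Everything here is implemented from first principles: a classical
(Torgerson) scaling of the double-centered squared dissimilarities serves
as deterministic initialisation, and a SMACOF majorization loop minimises
stress, by default in nonmetric mode where each iteration re-fits
disparities by monotone (isotonic, pool-adjacent-violators) regression of
the configuration distances on the dissimilarity ranks, with Kruskal's
primary approach to ties (tied dissimilarities are free to receive
unequal disparities).  Fit is reported as Kruskal's stress-1,

    stress-1 = sqrt( sum (dhat_ij - dist_ij)^2 / sum dist_ij^2 ),

with the conventional benchmarks: < 0.01 near-perfect, < 0.05 excellent,
< 0.1 good.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrices import SimilarityMatrix


@dataclass
class DissimilarityMatrix:
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]
    vignette_ids: list[int] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any() or (self.d > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        if not self.vignette_ids:
            self.vignette_ids = list(range(1, n + 1))


@dataclass
class MDSResult:
    coords: np.ndarray  # (n, k), centered at the origin
    stress: float  # Kruskal stress-1
    n_iter: int
    converged: bool
    stress_history: list[float]
    config: dict
    vignette_ids: list[int] = field(default_factory=list)


def to_dissimilarity(
    sim: SimilarityMatrix, method: str = "pair_fraction"
) -> DissimilarityMatrix:
    """Turn co-naming counts into dissimilarities in [0, 1].

    ``pair_fraction`` (default): d_ij = 1 - s_ij / n_pairs_ij, the share of
    participants who did *not* co-name the pair — normalising by the number
    of answering participants keeps groups of different sizes comparable.
    ``max_count``: d_ij = 1 - s_ij / max(off-diagonal s).
    """
    n = sim.s.shape[0]
    off = ~np.eye(n, dtype=bool)
    if method == "pair_fraction":
        if (sim.n_pairs[off] == 0).any():
            raise ValueError("some vignette pair has no answering participants")
        with np.errstate(invalid="ignore"):
            d = 1.0 - sim.s / sim.n_pairs
    elif method == "max_count":
        m = sim.s[off].max()
        if m == 0:
            raise ValueError("no co-naming events at all")
        d = 1.0 - sim.s / m
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(d, list(sim.vignette_ids), source=method)


def _as_square(d) -> np.ndarray:
    if isinstance(d, DissimilarityMatrix):
        return d.d
    return np.asarray(d, dtype=float)


def classical_mds(d, k: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center the squared dissimilarities and
    take the top-k eigenvector scores (negative eigenvalues clipped at 0).

    Column signs are fixed deterministically (largest-magnitude entry
    positive), so the result is reproducible.
    """
    D = _as_square(d)
    n = D.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    X = vecs[:, idx] * np.sqrt(lam)
    for j in range(X.shape[1]):
        i = np.argmax(np.abs(X[:, j]))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return X - X.mean(axis=0)


def kruskal_stress(dhat: np.ndarray, dist: np.ndarray) -> float:
    """Stress-1 between disparities and configuration distances
    (condensed vectors)."""
    denom = float((dist ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((dhat - dist) ** 2).sum() / denom))


def _pava(y: np.ndarray) -> np.ndarray:
    """Least-squares nondecreasing fit (pool adjacent violators)."""
    n = len(y)
    level = y.astype(float).copy()
    weight = np.ones(n)
    # blocks stored as (value, weight, length) on a stack
    vals: list[float] = []
    wts: list[float] = []
    lens: list[int] = []
    for i in range(n):
        v, w, ln = level[i], weight[i], 1
        while vals and vals[-1] > v:
            pv, pw, pl = vals.pop(), wts.pop(), lens.pop()
            v = (pv * pw + v * w) / (pw + w)
            w += pw
            ln += pl
        vals.append(v)
        wts.append(w)
        lens.append(ln)
    out = np.empty(n)
    pos = 0
    for v, ln in zip(vals, lens):
        out[pos:pos + ln] = v
        pos += ln
    return out


def _disparities(delta: np.ndarray, dist: np.ndarray, nonmetric: bool) -> np.ndarray:
    if nonmetric:
        # primary tie approach: within a tie block of delta, order by the
        # current distances, so tied dissimilarities may get distinct
        # disparities
        order = np.lexsort((dist, delta))
        dhat = np.empty_like(dist)
        dhat[order] = _pava(dist[order])
    else:
        dhat = delta.astype(float).copy()
    ssq = (dhat ** 2).sum()
    if ssq > 0:
        dhat = dhat * np.sqrt((dist ** 2).sum() / ssq)
    return dhat


def smacof(
    d,
    k: int = 2,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
    nonmetric: bool = True,
) -> MDSResult:
    """Minimise stress by iterative majorization (Guttman transforms).

    Initialised from the classical solution by default, hence fully
    deterministic.  The per-iteration stress-1 sequence is recorded and is
    non-increasing, the defining property of majorization.
    """
    D = _as_square(d)
    if not np.all(np.isfinite(D)):
        raise ValueError("dissimilarities must be finite")
    n = D.shape[0]
    delta = squareform(D, checks=False)
    X = classical_mds(D, k) if init is None else np.array(init, dtype=float)
    if X.shape != (n, k):
        raise ValueError(f"init must have shape ({n}, {k})")
    X = X - X.mean(axis=0)

    history: list[float] = []
    converged = False
    stress = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        dist = pdist(X)
        dhat = _disparities(delta, dist, nonmetric)
        new_stress = kruskal_stress(dhat, dist)
        history.append(new_stress)
        if np.isfinite(stress) and stress - new_stress < tol:
            stress = new_stress
            converged = True
            break
        stress = new_stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        Bm = -squareform(ratio)
        np.fill_diagonal(Bm, -Bm.sum(axis=1))
        X = Bm @ X / n
        X = X - X.mean(axis=0)

    return MDSResult(
        coords=X,
        stress=float(stress),
        n_iter=it,
        converged=converged,
        stress_history=history,
        config={
            "mode": "nonmetric" if nonmetric else "metric",
            "init": "classical" if init is None else "user",
            "tol": tol,
            "max_iter": max_iter,
        },
        vignette_ids=list(d.vignette_ids) if isinstance(d, DissimilarityMatrix) else [],
    )


def orient(result: MDSResult, valence) -> MDSResult:
    """Normalise rotation and reflection of a solution.

    Axis 1 is aligned with the first principal axis of the configuration
    and its sign chosen so the centroid of positive-valence vignettes has
    a positive coordinate; remaining axis signs are fixed by making the
    largest-magnitude entry positive.  ``valence`` is either a sequence of
    +/-1 aligned with the rows or a mapping vignette id -> +/-1.
    """
    X = result.coords - result.coords.mean(axis=0)
    if hasattr(valence, "get"):
        ids = result.vignette_ids or list(range(1, X.shape[0] + 1))
        val = np.array([valence[i] for i in ids], dtype=float)
    else:
        val = np.asarray(valence, dtype=float)
    if not ((val > 0).any() and (val < 0).any()):
        raise ValueError("need both positive and negative valences")
    # rotate to principal axes
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    Y = X @ Vt.T
    if Y[val > 0, 0].mean() < 0:
        Y[:, 0] = -Y[:, 0]
    for j in range(1, Y.shape[1]):
        i = np.argmax(np.abs(Y[:, j]))
        if Y[i, j] < 0:
            Y[:, j] = -Y[:, j]
    return MDSResult(
        coords=Y,
        stress=result.stress,
        n_iter=result.n_iter,
        converged=result.converged,
        stress_history=result.stress_history,
        config={**result.config, "oriented": True},
        vignette_ids=list(result.vignette_ids),
    )
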