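"""Dissimilarity, diversity, ordination and the Mantel test.

Community structure is summarised by Bray–Curtis dissimilarities between
samples (on rarefied counts), Shannon alpha diversity, non-metric
multidimensional scaling (NMDS, Kruskal stress-1), and Mantel permutation
tests of the community distance matrix against operational-factor
distances (feed, stage, sampling day).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.manifold import smacof

from .datamodel import AlignmentError, SampleRecord

log = logging.getLogger("adlink")


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k, centred
    stress: float  # Kruskal stress-1 of the best restart
    converged: bool
    n_restarts_used: int
    seed: int | None
    labels: list[str]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class DiversityRecord:
    sample_id: str
    shannon_h: float


def bray_curtis(counts) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples of a count table.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); zero-total samples are
    rejected (the quotient is undefined for them).
    """
    depths = counts.depths()
    zero = [s for s in counts.samples if depths[s] == 0]
    if zero:
        raise ValueError(f"zero-sum sample(s) {zero}: Bray-Curtis undefined")
    mat = counts.data.to_numpy(dtype=float).T  # samples x taxa
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=counts.samples)


def shannon(counts_column: Sequence[float]) -> float:
    """Shannon index H = -sum p ln p (natural-log units) of one sample."""
    x = np.asarray(counts_column, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an empty sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(counts) -> list[DiversityRecord]:
    return [
        DiversityRecord(sample_id=s, shannon_h=shannon(counts.column(s)))
        for s in counts.samples
    ]


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centring embedding, used as the NMDS warm start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    d: DistanceMatrix,
    k: int = 4,
    trymax: int = 100,
    seed: int | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    A metric (Torgerson) warm start plus up to ``trymax - 1`` seeded random
    restarts of non-metric SMACOF; the minimum-stress configuration is
    returned, centred.  ``converged`` is True when the two best restarts
    agree (relative stress gap < 1e-7 or Procrustes RMSE < 1e-6), or when a
    near-perfect embedding is found.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if n < k + 2:
        raise ValueError(f"nmds needs at least k+2={k + 2} samples, got {n}")
    rng = np.random.default_rng(seed)

    solutions: list[tuple[float, np.ndarray]] = []
    inits: list[np.ndarray | None] = [_classical_mds(dm, k)]
    inits += [None] * max(0, trymax - 1)
    for init in inits:
        if init is None:
            init = rng.uniform(-1.0, 1.0, size=(n, k)) * dm.max()
        coords, stress = smacof(
            dm,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            normalized_stress=True,
        )
        solutions.append((float(stress), coords))
        if stress < 1e-9:
            break
    solutions.sort(key=lambda t: t[0])
    best_stress, best = solutions[0]
    best = best - best.mean(axis=0)

    converged = best_stress < 1e-6
    if not converged and len(solutions) > 1:
        second_stress, second = solutions[1]
        if best_stress > 0 and (second_stress - best_stress) / best_stress < 1e-7:
            converged = True
        else:
            converged = _procrustes_rmse(best, second - second.mean(axis=0)) < 1e-6
    return OrdinationResult(
        coordinates=best,
        stress=best_stress,
        converged=converged,
        n_restarts_used=len(solutions),
        seed=seed,
        labels=list(d.ids),
    )


def _procrustes_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """RMSE between configurations after optimal rotation/scale alignment."""
    from scipy.spatial import procrustes

    try:
        m1, m2, _ = procrustes(a, b)
    except ValueError:
        return math.inf
    return float(np.sqrt(np.mean((m1 - m2) ** 2)))


def _triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(d, k=-1)
    return d[i, j]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        from scipy.stats import rankdata

        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    method: str = "pearson",
    seed: int | None = None,
) -> MantelResult:
    """One-sided (upper-tail) Mantel test between two distance matrices.

    The statistic is the correlation of the strictly-lower-triangle entries.
    The null distribution permutes the sample labels of ``d2``.  When the
    full permutation group is no larger than ``n_permutations`` it is
    enumerated exhaustively and p is the exact fraction of permutations
    (including the identity) with r >= observed; otherwise p uses sampled
    permutations with the standard +1 correction,
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations)``.
    """
    if list(d1.ids) != list(d2.ids):
        raise AlignmentError("mantel: distance matrices must share ids and order")
    m1 = np.asarray(d1.data, dtype=float)
    m2 = np.asarray(d2.data, dtype=float)
    t1, t2 = _triangle(m1), _triangle(m2)
    if np.ptp(t1) == 0 or np.ptp(t2) == 0:
        log.warning("mantel: zero variance in a distance triangle; degenerate")
        return MantelResult(
            r=math.nan, p=1.0, n_permutations=0, method=method, degenerate=True
        )
    r_obs = _corr(t1, t2, method)
    n = m1.shape[0]

    n_total = math.factorial(n)
    if n_total <= n_permutations:
        count = 0
        for perm in iter_permutations(range(n)):
            idx = np.asarray(perm)
            r_perm = _corr(t1, _triangle(m2[np.ix_(idx, idx)]), method)
            if r_perm >= r_obs - 1e-12:
                count += 1
        return MantelResult(
            r=r_obs, p=count / n_total, n_permutations=n_total, method=method
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        r_perm = _corr(t1, _triangle(m2[np.ix_(idx, idx)]), method)
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations, method=method)


def factor_distance(
    meta: Sequence[SampleRecord], factor: str, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Distance matrix encoding an operational factor.

    Categorical factors (feed, stage) become 0/1 mismatch distances; day
    becomes |Δday| rescaled to [0, 1] over the observed range.
    """
    by_id = {r.sample_id: r for r in meta}
    order = list(ids) if ids is not None else [r.sample_id for r in meta]
    missing = [s for s in order if s not in by_id]
    if missing:
        raise ValueError(f"factor_distance: no metadata for sample(s) {missing}")
    recs = [by_id[s] for s in order]
    if factor in ("feed", "stage"):
        vals = [getattr(r, factor).value for r in recs]
        arr = np.array(vals)
        d = (arr[:, None] != arr[None, :]).astype(float)
    elif factor == "day":
        days = np.array([r.day for r in recs], dtype=float)
        span = np.ptp(days)
        d = np.abs(days[:, None] - days[None, :])
        if span > 0:
            d /= span
    else:
        raise ValueError(f"unknown factor {factor!r}")
    return DistanceMatrix(d, ids=order)
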