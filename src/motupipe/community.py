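"""Community-level statistics over MOTU abundance vectors.

Each station is an ordered vector of MOTU counts.  Compositional overlap
between two stations is the cosine of the angle between their vectors,

    S(a, b) = x_a . x_b / (|x_a| |x_b|)  in [0, 1] for count data,

a measure of shared composition that does not downweight rare MOTUs -- the
right choice for singleton-heavy, non-quantitative sledge samples.  The
battery around it:

* geographic distances between stations (plain Euclidean on decimal
  degrees, plus great-circle km as a sanity alternative);
* non-metric multidimensional scaling (Kruskal stress-1, monotone
  regression, multiple seeded restarts);
* one-way ANOSIM on ranked dissimilarities (Clarke's R, permutation p);
* the Mantel test (Pearson r over lower triangles, simultaneous row/column
  permutation).

All permutation p-values use the add-one convention
p = (#{permuted >= observed} + 1) / (n_permutations + 1) and are
bit-reproducible given (seed, n_permutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .distances import DistanceMatrix
from .seq_io import StationRecord

__all__ = [
    "OrdinationResult",
    "TestResult",
    "cosine_similarity_matrix",
    "similarity_to_distance",
    "geographic_distance_matrix",
    "nmds",
    "anosim",
    "mantel",
    "plot_nmds",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centered
    stress: float  # Kruskal stress-1, minimum over restarts
    n_restarts: int
    seed: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str = ""
    tail: str = ""


def cosine_similarity_matrix(cm: pd.DataFrame) -> DistanceMatrix:
    """Pairwise cosine similarity between the rows (stations) of a count matrix."""
    x = cm.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    norms = np.linalg.norm(x, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero abundance row(s): {list(cm.index[zero])}")
    sims = (x @ x.T) / np.outer(norms, norms)
    sims = np.clip(sims, 0.0, 1.0)
    np.fill_diagonal(sims, 1.0)
    sims = (sims + sims.T) / 2.0
    return DistanceMatrix(
        list(cm.index.astype(str)), sims, metric_name="cosine", kind="similarity"
    )


def similarity_to_distance(sm: DistanceMatrix) -> DistanceMatrix:
    """d = 1 - s."""
    if sm.kind != "similarity":
        raise ValueError("expected a similarity matrix")
    vals = 1.0 - sm.values
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(
        sm.labels, vals, metric_name=f"1-{sm.metric_name}", kind="distance"
    )


def geographic_distance_matrix(
    stations: Sequence[StationRecord], mode: str = "euclidean_degrees"
) -> DistanceMatrix:
    """Pairwise geographic distances between stations.

    ``euclidean_degrees`` (default): sqrt(dlat^2 + dlon^2) on decimal
    degrees.  ``haversine_km``: great-circle distance -- degrees are
    anisotropic away from the equator, so the km mode is the physically
    meaningful sanity check.
    """
    lat = np.array([s.latitude for s in stations])
    lon = np.array([s.longitude for s in stations])
    if mode == "euclidean_degrees":
        vals = np.sqrt(
            (lat[:, None] - lat[None, :]) ** 2 + (lon[:, None] - lon[None, :]) ** 2
        )
    elif mode == "haversine_km":
        phi = np.radians(lat)
        lam = np.radians(lon)
        dphi = phi[:, None] - phi[None, :]
        dlam = lam[:, None] - lam[None, :]
        h = (
            np.sin(dphi / 2) ** 2
            + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
        )
        vals = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(
        [s.station_id for s in stations], vals, metric_name=f"geo_{mode}"
    )


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

def _stress1(d_config: np.ndarray, d_input: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarities."""
    order = rankdata(d_input, method="average")
    iso = IsotonicRegression(increasing=True)
    d_hat = iso.fit_transform(order, d_config)
    denom = float(np.sum(d_config**2))
    if denom == 0.0:
        return 0.0
    return math.sqrt(float(np.sum((d_config - d_hat) ** 2)) / denom)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS of a distance (or similarity, via d = 1 - s) matrix.

    Minimizes Kruskal stress-1 by SMACOF with monotone regression; the best
    of ``n_restarts`` seeded starts is returned with coordinates centered
    at the origin.
    """
    from sklearn.manifold import MDS

    if dm.kind == "similarity":
        dm = similarity_to_distance(dm)
    n = len(dm)
    if k >= n:
        raise ValueError(f"k={k} must be < number of samples ({n})")
    mds = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    coords = mds.fit_transform(dm.values)
    coords = coords - coords.mean(axis=0)
    iu = np.triu_indices(n, k=1)
    d_config = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    stress = _stress1(d_config, dm.values[iu])
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dm.labels, columns=[f"axis{i+1}" for i in range(k)]
        ),
        stress=stress,
        n_restarts=n_restarts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, m: int) -> float:
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return (r_between - r_within) / (m / 2.0)


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> TestResult:
    """One-way analysis of similarity (Clarke's R) with permutation p.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranked dissimilarities (average ranks for ties).  The p
    value permutes group labels over samples and counts permuted R >=
    observed, add-one corrected.  With ``exhaustive=True`` every label
    permutation is enumerated (identity included) and p is the exact
    fraction with permuted R >= observed -- feasible for small n only.
    """
    if dm.kind == "similarity":
        dm = similarity_to_distance(dm)
    labels = np.array([groups[l] for l in dm.labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    n = len(dm)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.values[iu], method="average")
    m = n * (n - 1) // 2
    same = labels[iu[0]] == labels[iu[1]]
    observed = _anosim_r(ranks, same, m)
    if exhaustive:
        from itertools import permutations as _perms

        count = total = 0
        for order in _perms(range(n)):
            perm = labels[list(order)]
            mask = perm[iu[0]] == perm[iu[1]]
            total += 1
            if _anosim_r(ranks, mask, m) >= observed - 1e-12:
                count += 1
        p = count / total
        n_permutations = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            mask = perm[iu[0]] == perm[iu[1]]
            if _anosim_r(ranks, mask, m) >= observed:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return TestResult(
        statistic=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        method="anosim",
        tail="greater",
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _triangle_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a**2).sum()) * float((b**2).sum()))
    if denom == 0.0:
        raise ValueError("zero variance in a matrix triangle")
    return float((a * b).sum() / denom)


def mantel(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_permutations: int = 5000,
    seed: int = 0,
    tail: str = "observed",
    exhaustive: bool = False,
) -> TestResult:
    """Mantel test: Pearson r between two labeled square matrices.

    The matrices are correlated as given (a similarity matrix may be passed
    directly; the sign of r then carries the similarity orientation).  The
    null distribution permutes rows and columns of ``m2`` simultaneously.
    ``tail``: "observed" (one-tailed in the direction of the observed r,
    the default), "greater", "less", or "two-sided".  ``exhaustive=True``
    enumerates all n! relabelings (identity included) and returns the exact
    fraction as p.
    """
    if m1.labels != m2.labels:
        if set(m1.labels) != set(m2.labels):
            raise ValueError("matrices have different labels")
        m2 = m2.reorder(m1.labels)
    n = len(m1)
    if n < 4:
        raise ValueError("Mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    x = m1.values[iu]
    observed = _triangle_corr(x, m2.values[iu])
    if tail == "observed":
        tail = "greater" if observed >= 0 else "less"
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")

    def _hit(r: float) -> bool:
        eps = 1e-12
        if tail == "greater":
            return r >= observed - eps
        if tail == "less":
            return r <= observed + eps
        return abs(r) >= abs(observed) - eps

    if exhaustive:
        from itertools import permutations as _perms

        count = total = 0
        for order in _perms(range(n)):
            perm = np.array(order)
            total += 1
            if _hit(_triangle_corr(x, m2.values[np.ix_(perm, perm)][iu])):
                count += 1
        p = count / total
        n_permutations = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if _hit(_triangle_corr(x, m2.values[np.ix_(perm, perm)][iu])):
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return TestResult(
        statistic=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        method="mantel",
        tail=tail,
    )


def plot_nmds(
    result: OrdinationResult,
    groups: Mapping[str, str],
    path: str,
    title: str = "",
) -> None:
    """Scatter the first two nMDS axes, colored by group, to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    coords = result.coordinates
    for g in sorted(set(groups.values())):
        idx = [s for s in coords.index if groups[s] == g]
        ax.scatter(coords.loc[idx, "axis1"], coords.loc[idx, "axis2"], label=g)
    for s in coords.index:
        ax.annotate(s, (coords.loc[s, "axis1"], coords.loc[s, "axis2"]), fontsize=6)
    ax.set_xlabel("nMDS axis 1")
    ax.set_ylabel("nMDS axis 2")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(title or f"2-D stress = {result.stress:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
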