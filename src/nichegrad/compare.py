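"""Community-structure comparisons: distances, NMDS, ANOSIM and Mantel.

The permutation tests report one-sided p-values with the convention
``p = (1 + #{null >= observed}) / (1 + n_permutations)``, which never
yields p = 0 and matches the conventional 999-permutation setups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .model import (DistanceMatrix, OtuTable, RelativeAbundanceTable,
                    SampleMetadata, to_relative_abundance)

__all__ = [
    "PermutationTestResult",
    "OrdinationResult",
    "bray_curtis",
    "spatial_distance",
    "environment_distance",
    "nmds",
    "anosim",
    "mantel",
    "permutation_pvalue",
]

logger = logging.getLogger(__name__)

#: metres per degree of latitude used by the local equirectangular
#: projection (longitude scales by cos of the mean latitude)
M_PER_DEG = 111_320.0


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame = field(repr=False)
    stress: float
    k: int
    converged: bool
    seed: int
    n_iter: int = 0


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """One-sided (greater) p with the (1+exceed)/(1+n) convention."""
    null = np.asarray(null, dtype=float)
    return float((1 + (null >= observed).sum()) / (1 + null.size))


def bray_curtis(x: RelativeAbundanceTable | OtuTable,
                on_counts: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    Computed on per-sample relative abundances by default, isolating
    composition from sequencing depth; pass ``on_counts=True`` with an
    :class:`OtuTable` to use raw counts.
    """
    if isinstance(x, OtuTable):
        x.require_positive_depths()
        frame = x.counts if on_counts else to_relative_abundance(x).fractions
    else:
        frame = x.fractions
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(frame.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(frame.index))


def spatial_distance(meta: SampleMetadata) -> DistanceMatrix:
    """3-D Euclidean distance (metres) from lon/lat/elevation.

    Longitude and latitude are projected to metres by a local
    equirectangular projection about the mean latitude (1 deg lat =
    111,320 m; 1 deg lon = 111,320 * cos(mean lat) m).
    """
    coords = meta.coordinates()
    lat_bar = math.radians(coords["latitude_deg"].mean())
    xyz = np.column_stack([
        coords["longitude_deg"].to_numpy() * M_PER_DEG * math.cos(lat_bar),
        coords["latitude_deg"].to_numpy() * M_PER_DEG,
        coords["elevation_m"].to_numpy(),
    ])
    return DistanceMatrix(squareform(pdist(xyz)), ids=list(coords.index))


def _bray_on_matrix(values: np.ndarray, ids) -> DistanceMatrix:
    # Bray-Curtis with the empty-vector convention: two all-zero rows are
    # identical (d=0), an all-zero vs a non-zero row are disjoint (d=1).
    n = values.shape[0]
    out = np.zeros((n, n))
    sums = values.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            denom = sums[i] + sums[j]
            if denom == 0:
                d = 0.0
            elif sums[i] == 0 or sums[j] == 0:
                d = 1.0
            else:
                d = np.abs(values[i] - values[j]).sum() / denom
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=list(ids))


def environment_distance(meta: SampleMetadata,
                         variable_set: str) -> DistanceMatrix | None:
    """Between-sample distance on one named covariate set.

    Numeric sets (``soil_vars``, ``plant_diversity``) use Euclidean
    distance on z-standardized variables; species importance-value sets
    (``tree_importance``, ``shrub_importance``) use Bray-Curtis.  Returns
    None with a warning if the set is absent from the metadata.
    """
    sub = meta.variable_group(variable_set)
    if sub is None:
        logger.warning(
            "variable set %r absent from metadata; dependent analysis "
            "skipped", variable_set,
        )
        return None
    values = sub.to_numpy(dtype=float)
    if np.isnan(values).any():
        logger.warning(
            "variable set %r has missing values; dependent analysis "
            "skipped", variable_set,
        )
        return None
    if variable_set in ("tree_importance", "shrub_importance"):
        return _bray_on_matrix(values, sub.index)
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        # every variable identical across samples: zero distances
        n = values.shape[0]
        return DistanceMatrix(np.zeros((n, n)), ids=list(sub.index))
    z = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    return DistanceMatrix(squareform(pdist(z)), ids=list(sub.index))


def _pcoa_coordinates(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))


def kruskal_stress(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against observed dissimilarities."""
    d_emb = pdist(coords)
    order = np.argsort(d_obs, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(d_emb)
    dhat[order] = iso.fit_transform(np.arange(order.size), d_emb[order])
    denom = (d_emb**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_emb - dhat) ** 2).sum() / denom))


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 8,
         max_iter: int = 300, tol: float = 1e-9,
         seed: int = 0) -> OrdinationResult:
    """Non-metric multidimensional scaling with Kruskal stress-1.

    Runs SMACOF majorization with isotonic regression on distance ranks
    (via scikit-learn) from ``n_starts`` random starts plus a PCoA start,
    keeps the best-stress solution, and Procrustes-rotates it onto the
    PCoA configuration for orientation stability.  Coordinates are
    centred.
    """
    n = d.shape[0]
    if not k < n:
        raise ValueError("k must be smaller than the number of samples")
    dm = d.data
    condensed = squareform(dm, checks=False)

    best = None
    pcoa = _pcoa_coordinates(dm, k)
    rng = np.random.default_rng(seed)
    inits = [pcoa] + [rng.normal(size=(n, k)) for _ in range(n_starts)]
    for init in inits:
        mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
                  n_init=1, max_iter=max_iter, eps=tol,
                  random_state=int(rng.integers(2**31)),
                  normalized_stress=True)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            coords = mds.fit_transform(dm, init=init)
        stress = kruskal_stress(condensed, coords)
        if best is None or stress < best[0]:
            best = (stress, coords, mds.n_iter_)
    stress, coords, n_iter = best

    coords = coords - coords.mean(axis=0)
    if np.linalg.norm(pcoa) > 0:
        from scipy.linalg import orthogonal_procrustes

        rot, _ = orthogonal_procrustes(coords, pcoa)
        coords = coords @ rot
    frame = pd.DataFrame(coords, index=list(d.ids),
                         columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=frame, stress=stress, k=k,
                            converged=n_iter < max_iter, seed=seed,
                            n_iter=n_iter)


def _group_labels(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        groups = groups.reindex(list(d.ids))
        if groups.isna().any():
            bad = groups.index[groups.isna()].tolist()
            raise ValueError(f"sample(s) missing a group label: {bad}")
        return groups.to_numpy()
    labels = np.asarray(groups)
    if labels.size != d.shape[0]:
        raise ValueError("group labels do not match the distance matrix")
    return labels


def anosim(d: DistanceMatrix, groups, n_perm: int = 999,
           seed: int = 0) -> PermutationTestResult:
    """Analysis of similarities (Clarke's R) with a permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    computed on the ranks of all off-diagonal distances; the null
    relabels samples at random.
    """
    labels = _group_labels(d, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        singles = uniq[counts < 2].tolist()
        raise ValueError(f"singleton group(s) not allowed: {singles}")

    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(squareform(d.data, checks=False))
    denom = n * (n - 1) / 4.0

    def r_stat(lab_rows: np.ndarray) -> np.ndarray:
        within = lab_rows[..., iu] == lab_rows[..., ju]
        rw = (ranks * within).sum(axis=-1) / within.sum(axis=-1)
        rb = (ranks * ~within).sum(axis=-1) / (~within).sum(axis=-1)
        return (rb - rw) / denom

    observed = float(r_stat(labels))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)
    null = r_stat(perms)
    return PermutationTestResult(
        statistic=observed, p_value=permutation_pvalue(observed, null),
        n_permutations=n_perm, seed=seed, method="anosim",
    )


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, method: str = "pearson") -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation of the lower
    triangles; the null jointly permutes rows and columns of the second
    matrix; p is one-sided (greater).  Which matrix is permuted does not
    affect the null distribution.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share the same sample ids "
                         "in the same order")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x = squareform(d1.data, checks=False)
    m2 = d2.data
    y = squareform(m2, checks=False)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: a distance matrix is constant")

    if method == "spearman":
        x = rankdata(x)

    def corr(yv: np.ndarray) -> float:
        yv = rankdata(yv) if method == "spearman" else yv
        xc, yc = x - x.mean(), yv - yv.mean()
        return float((xc * yc).sum()
                     / np.sqrt((xc**2).sum() * (yc**2).sum()))

    observed = corr(y)
    rng = np.random.default_rng(seed)
    n = m2.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        null[k] = corr(squareform(m2[np.ix_(p, p)], checks=False))
    return PermutationTestResult(
        statistic=observed, p_value=permutation_pvalue(observed, null),
        n_permutations=n_perm, seed=seed, method=f"mantel_{method}",
    )


def nmds_distance_correlation(d: DistanceMatrix,
                              result: OrdinationResult) -> float:
    """Spearman correlation between input and embedded distances."""
    emb = pdist(result.coordinates.to_numpy())
    obs = squareform(d.data, checks=False)
    return float(spearmanr(obs, emb).statistic)
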