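"""Redundancy analysis (RDA) with Monte-Carlo permutation tests.

RDA is the principal component analysis of the fitted values of a
multivariate linear regression of a (transformed, centred) community
table Y on an explanatory table X.  The community table is
Hellinger-transformed by default (square root of within-sample relative
abundances), the standard pre-treatment that makes species data suitable
for a Euclidean-metric ordination; numeric explanatory variables are
z-standardized and factors expanded to treatment-coded indicators.

Model significance uses the pseudo-F statistic

.. math:: F = \\frac{SS_{fit}/q}{SS_{res}/(n-q-1)}

with q = rank of X, under row permutations of Y.  Per-variable
significance follows the envfit approach: each variable is regressed on
the constrained axes and its r-squared tested by permuting the variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .compare import PermutationTestResult, permutation_pvalue
from .model import OtuTable

__all__ = [
    "RdaResult",
    "rda",
    "permutation_test_model",
    "fit_variables",
    "hellinger",
    "build_design",
]

logger = logging.getLogger(__name__)


def hellinger(y: pd.DataFrame) -> pd.DataFrame:
    """Square root of within-sample relative abundances."""
    totals = y.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    return np.sqrt(y.div(totals, axis=0))


def build_design(x: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize numeric columns; expand factors to treatment dummies."""
    pieces = []
    for col in x.columns:
        s = x[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True,
                                     dtype=float)
            pieces.append(dummies)
        else:
            v = s.astype(float)
            sd = v.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                logger.warning("constant explanatory variable %r dropped", col)
                continue
            pieces.append(((v - v.mean()) / sd).to_frame(col))
    if not pieces:
        raise ValueError("no usable explanatory variables")
    return pd.concat(pieces, axis=1)


def _drop_aliased(xc: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal independent column subset (rank-revealing QR)."""
    if xc.shape[1] == 0:
        return xc, names
    _, r, piv = qr(xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(xc.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    if rank < xc.shape[1]:
        dropped = [names[i] for i in sorted(piv[rank:])]
        logger.warning("dropping aliased explanatory column(s): %s", dropped)
        keep = sorted(piv[:rank])
        return xc[:, keep], [names[i] for i in keep]
    return xc, names


@dataclass
class RdaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    constrained_fraction: float
    site_scores: pd.DataFrame = field(repr=False)
    variable_scores: pd.DataFrame = field(repr=False)
    total_variance: float = 0.0
    model_p: float = float("nan")
    per_variable: pd.DataFrame | None = None


def _prepare(y, x, hellinger_transform: bool):
    if isinstance(y, OtuTable):
        y = y.counts
    y = y.astype(float)
    if list(y.index) != list(x.index):
        x = x.reindex(y.index)
        if x.isna().any().any():
            raise ValueError("explanatory rows do not align with response rows")
    if hellinger_transform:
        y = hellinger(y)
    n = y.shape[0]
    design = build_design(x)
    xc = design.to_numpy() - design.to_numpy().mean(axis=0)
    xc, names = _drop_aliased(xc, list(design.columns))
    if n <= xc.shape[1] + 1:
        raise ValueError(
            f"need n_samples > n_explanatory + 1 (n={n}, q={xc.shape[1]})"
        )
    yc = y.to_numpy() - y.to_numpy().mean(axis=0)
    return y, yc, xc, names


def rda(y, x: pd.DataFrame, hellinger_transform: bool = True,
        n_axes: int | None = None) -> RdaResult:
    """Redundancy analysis of a community table on explanatory variables.

    Parameters
    ----------
    y : OtuTable or DataFrame
        Community table (samples x species) for one subgroup.
    x : DataFrame
        Explanatory variables aligned on the same samples.
    hellinger_transform : bool
        Apply the Hellinger transformation before centring (default).
    """
    yt, yc, xc, names = _prepare(y, x, hellinger_transform)
    n = yc.shape[0]

    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    yhat = xc @ beta
    resid = yc - yhat

    u, s, _ = np.linalg.svd(yhat, full_matrices=False)
    eig_c = (s**2) / (n - 1)
    keep_c = eig_c > eig_c.max() * 1e-12 if eig_c.size and eig_c.max() > 0 else []
    eig_c = eig_c[keep_c]
    site = (u * s)[:, keep_c]

    _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
    eig_r = (s_r**2) / (n - 1)
    eig_r = eig_r[eig_r > (eig_r.max() * 1e-12 if eig_r.size and eig_r.max() > 0 else 0)]

    total = (yc**2).sum() / (n - 1)
    constrained_fraction = float((yhat**2).sum() / (yc**2).sum())

    k = site.shape[1] if n_axes is None else min(n_axes, site.shape[1])
    axis_names = [f"RDA{i + 1}" for i in range(k)]
    site_scores = pd.DataFrame(site[:, :k], index=yt.index, columns=axis_names)
    # biplot scores: correlations of explanatory columns with site scores
    var_scores = np.zeros((len(names), k))
    for i in range(len(names)):
        for j in range(k):
            sd = site_scores.iloc[:, j].std(ddof=1)
            if sd > 0:
                var_scores[i, j] = np.corrcoef(xc[:, i], site_scores.iloc[:, j])[0, 1]
    variable_scores = pd.DataFrame(var_scores, index=names, columns=axis_names)

    return RdaResult(
        constrained_eigenvalues=eig_c,
        unconstrained_eigenvalues=eig_r,
        constrained_fraction=constrained_fraction,
        site_scores=site_scores,
        variable_scores=variable_scores,
        total_variance=float(total),
    )


def permutation_test_model(y, x: pd.DataFrame, n_perm: int = 999,
                           seed: int = 0,
                           hellinger_transform: bool = True
                           ) -> PermutationTestResult:
    """Monte-Carlo significance of the whole RDA model (pseudo-F)."""
    _, yc, xc, _ = _prepare(y, x, hellinger_transform)
    n, q = yc.shape[0], xc.shape[1]
    # hat matrix of the centred design
    h = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T

    def pseudo_f(ymat: np.ndarray) -> float:
        fit = h @ ymat
        ss_fit = (fit**2).sum()
        ss_res = ((ymat - fit) ** 2).sum()
        return (ss_fit / q) / (ss_res / (n - q - 1))

    observed = pseudo_f(yc)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = pseudo_f(yc[rng.permutation(n)])
    return PermutationTestResult(
        statistic=float(observed),
        p_value=permutation_pvalue(observed, null),
        n_permutations=n_perm, seed=seed, method="rda_pseudo_f",
    )


def fit_variables(coordinates: pd.DataFrame, variables: pd.DataFrame,
                  n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Envfit-style per-variable r-squared and permutation p on ordination axes.

    Each numeric variable is regressed on the (centred) coordinate axes;
    r-squared is the fraction of its variance explained, and p comes from
    permuting the variable's values.  Constant variables are reported with
    NaN r-squared and p.
    """
    axes = coordinates.to_numpy(dtype=float)
    axes = axes - axes.mean(axis=0)
    n = axes.shape[0]
    h = axes @ np.linalg.pinv(axes.T @ axes) @ axes.T
    rng = np.random.default_rng(seed)

    rows = []
    for col in variables.columns:
        v = variables[col].reindex(coordinates.index).to_numpy(dtype=float)
        if np.isnan(v).any():
            logger.warning("variable %r has missing values; skipped", col)
            rows.append({"variable": col, "r2": np.nan, "p": np.nan})
            continue
        vc = v - v.mean()
        tss = (vc**2).sum()
        if tss == 0:
            logger.warning("constant variable %r: r2 undefined", col)
            rows.append({"variable": col, "r2": np.nan, "p": np.nan})
            continue
        r2 = float(((h @ vc) ** 2).sum() / tss)
        perms = np.stack([vc[rng.permutation(n)] for _ in range(n_perm)], axis=1)
        null_r2 = ((h @ perms) ** 2).sum(axis=0) / tss
        rows.append({"variable": col, "r2": r2,
                     "p": permutation_pvalue(r2, null_r2)})
    return pd.DataFrame(rows).set_index("variable")


def rda_with_tests(y, x: pd.DataFrame, n_perm: int = 999, seed: int = 0,
                   hellinger_transform: bool = True) -> RdaResult:
    """RDA plus model permutation test and envfit-style variable tests."""
    result = rda(y, x, hellinger_transform=hellinger_transform)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = permutation_test_model(
            y, x, n_perm=n_perm, seed=seed,
            hellinger_transform=hellinger_transform,
        )
    result.model_p = model.p_value
    design = build_design(x)
    result.per_variable = fit_variables(
        result.site_scores, design, n_perm=n_perm, seed=seed + 1
    )
    return result
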