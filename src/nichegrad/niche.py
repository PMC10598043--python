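"""Levins niche breadth and null-model habitat-specialization classes.

For OTU *i* with occupancy proportions :math:`P_{ij}` over *r* resource
states (by default the individual samples of one soil layer),

.. math:: B_i = 1 / \\sum_{j=1}^{r} P_{ij}^2

ranges from 1 (all reads in one state) to *r* (perfectly even occupancy).
Each observed :math:`B_i` is compared against a permutation null obtained
by redistributing the OTU's reads across states; OTUs above the null's
95% quantile are habitat-generalized, below the 5% quantile habitat-
specialized, and neutral otherwise (ties fall to neutral).

Two null models are offered:

``replacement_multinomial`` (default)
    The OTU's total reads are re-dealt across states by a multinomial
    draw with probabilities proportional to state total reads (sampling
    individuals with replacement).  A naive within-row shuffle is *not*
    offered: Levins B is invariant to state order, which would make such
    a null degenerate.
``quasiswap``
    B is recomputed from whole-matrix randomizations that preserve both
    row (OTU) and column (state) read totals, drawn with Patefield's
    algorithm (:func:`scipy.stats.random_table`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import OtuTable, SampleMetadata, STAND_TYPES

__all__ = [
    "NicheBreadthResult",
    "levins_breadth",
    "null_breadth_distribution",
    "classify_niche",
    "classify_niche_table",
    "aggregate_states",
    "rarefy_to_min_depth",
]

logger = logging.getLogger(__name__)

NICHE_CLASSES = ("generalized", "neutral", "specialized")
_NULL_METHODS = ("replacement_multinomial", "quasiswap")


def levins_breadth(p) -> float:
    """Levins niche breadth of a proportion vector over r states."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero proportion vector: OTU absent from every state")
    p = p / total
    return float(1.0 / (p**2).sum())


@dataclass
class NicheBreadthResult:
    """Per-OTU observed breadth, null quantiles and niche class."""

    assignments: pd.DataFrame = field(repr=False)  # B_obs, null_q05, null_q95, niche_class
    r: int
    n_permutations: int
    method: str
    seed: int
    lower_q: float = 0.05
    upper_q: float = 0.95
    n_excluded: int = 0

    @property
    def otu_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def niche_class(self) -> pd.Series:
        return self.assignments["niche_class"]

    def otus_in(self, niche_class: str) -> list[str]:
        if niche_class not in NICHE_CLASSES:
            raise ValueError(f"unknown niche class {niche_class!r}")
        a = self.assignments
        return list(a.index[a["niche_class"] == niche_class])

    def groups(self) -> dict[str, list[str]]:
        return {g: self.otus_in(g) for g in NICHE_CLASSES}


def aggregate_states(t: OtuTable, meta: SampleMetadata | None = None,
                     state_definition: str = "sample") -> OtuTable:
    """Sum counts into resource states (identity for ``sample`` states)."""
    if state_definition == "sample":
        return t
    if state_definition != "stand_type":
        raise ValueError(
            f"unknown state_definition {state_definition!r}; "
            "allowed: 'sample', 'stand_type'"
        )
    if meta is None:
        raise ValueError("stand_type aggregation requires sample metadata")
    labels = meta.stand_type.reindex(t.sample_ids)
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"sample(s) missing a stand_type label: {bad}")
    grouped = t.counts.groupby(labels).sum()
    order = [s for s in STAND_TYPES if s in grouped.index]
    return OtuTable(grouped.loc[order])


def _state_probabilities(counts: np.ndarray) -> np.ndarray:
    """Redistribution probabilities: per-state read totals (otus x states in)."""
    state_totals = counts.sum(axis=0, dtype=float)
    if state_totals.sum() == 0:
        raise ValueError("every state has zero total reads")
    return state_totals / state_totals.sum()


def null_breadth_distribution(t: OtuTable, otu_id: str, n_perm: int = 1000,
                              method: str = "replacement_multinomial",
                              seed: int = 0) -> np.ndarray:
    """Null Levins-B values for one OTU.  Deterministic given ``seed``."""
    if method not in _NULL_METHODS:
        raise ValueError(f"unknown method {method!r}; allowed: {_NULL_METHODS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = t.counts.to_numpy().T  # otus x states
    try:
        row = t.otu_ids.index(otu_id)
    except ValueError:
        raise KeyError(f"unknown otu_id {otu_id!r}") from None
    total = int(counts[row].sum())
    if total == 0:
        raise ValueError(f"OTU {otu_id!r} absent from every state")
    rng = np.random.default_rng(seed)
    if method == "replacement_multinomial":
        draws = rng.multinomial(total, _state_probabilities(counts), size=n_perm)
        p = draws / total
        return 1.0 / (p**2).sum(axis=1)
    # quasiswap: whole-matrix fixed-margin randomization
    rt = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
    tables = rt.rvs(size=n_perm, random_state=rng)
    p = tables[:, row, :] / total
    return 1.0 / (p**2).sum(axis=1)


def classify_niche(B_obs: float, null: np.ndarray, lower_q: float = 0.05,
                   upper_q: float = 0.95) -> str:
    """Compare observed breadth with null quantiles (type-7 empirical).

    Ties with a quantile fall to ``neutral``.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    q_lo, q_hi = np.quantile(null, [lower_q, upper_q])
    if B_obs > q_hi:
        return "generalized"
    if B_obs < q_lo:
        return "specialized"
    return "neutral"


def classify_niche_table(t: OtuTable, n_perm: int = 1000,
                         method: str = "replacement_multinomial",
                         seed: int = 0, lower_q: float = 0.05,
                         upper_q: float = 0.95,
                         chunk_size: int = 256) -> NicheBreadthResult:
    """Classify every OTU of a (layer-restricted) table in one pass.

    Observed breadth uses the OTU's raw read counts over states; the null
    is drawn per OTU as in :func:`null_breadth_distribution` but batched
    across OTUs for speed.  OTUs with zero total reads are excluded with a
    logged count.
    """
    if method not in _NULL_METHODS:
        raise ValueError(f"unknown method {method!r}; allowed: {_NULL_METHODS}")
    counts = t.counts.to_numpy().T.astype(np.int64)  # otus x states
    otu_ids = np.array(t.otu_ids)
    totals = counts.sum(axis=1)
    present = totals > 0
    n_excluded = int((~present).sum())
    if n_excluded:
        logger.warning(
            "%d OTU(s) absent from every state were excluded from niche "
            "classification", n_excluded,
        )
    counts = counts[present]
    otu_ids = otu_ids[present]
    totals = totals[present]
    n_otus, r = counts.shape

    B_obs = 1.0 / ((counts / totals[:, None]) ** 2).sum(axis=1)

    rng = np.random.default_rng(seed)
    q_lo = np.empty(n_otus)
    q_hi = np.empty(n_otus)
    if method == "replacement_multinomial":
        probs = _state_probabilities(counts)
        for start in range(0, n_otus, chunk_size):
            sl = slice(start, min(start + chunk_size, n_otus))
            n_mat = np.broadcast_to(
                totals[sl, None], (sl.stop - sl.start, n_perm)
            )
            draws = rng.multinomial(n_mat, probs)
            p = draws / totals[sl, None, None]
            B_null = 1.0 / (p**2).sum(axis=2)
            q_lo[sl], q_hi[sl] = np.quantile(
                B_null, [lower_q, upper_q], axis=1
            )
    else:
        rt = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
        B_null = np.empty((n_otus, n_perm))
        for k in range(n_perm):
            tab = rt.rvs(random_state=rng)
            B_null[:, k] = 1.0 / ((tab / totals[:, None]) ** 2).sum(axis=1)
        q_lo, q_hi = np.quantile(B_null, [lower_q, upper_q], axis=1)

    niche_class = np.where(
        B_obs > q_hi, "generalized",
        np.where(B_obs < q_lo, "specialized", "neutral"),
    )
    assignments = pd.DataFrame(
        {
            "B_obs": B_obs,
            "null_q05": q_lo,
            "null_q95": q_hi,
            "niche_class": niche_class,
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    return NicheBreadthResult(
        assignments=assignments, r=r, n_permutations=n_perm, method=method,
        seed=seed, lower_q=lower_q, upper_q=upper_q, n_excluded=n_excluded,
    )


def rarefy_to_min_depth(t: OtuTable, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to the minimum depth.

    Off by default in the pipeline; offered because unequal depths shift
    the niche null.
    """
    t.require_positive_depths()
    depth = int(t.sample_depths().min())
    rng = np.random.default_rng(seed)
    out = np.empty_like(t.counts.to_numpy())
    for i, row in enumerate(t.counts.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(pd.DataFrame(out, index=t.counts.index,
                                 columns=t.counts.columns))
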