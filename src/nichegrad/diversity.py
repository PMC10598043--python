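"""Alpha-diversity indices, subgroup decomposition and ANOVA letters.

Six quantities per sample (or per sample x subgroup): Shannon-Wiener
diversity (natural log), unbiased Simpson diversity, Shannon evenness,
Simpson evenness, Pielou evenness and species richness.

Simpson diversity is computed in its unbiased finite-sample form

.. math:: D = 1 - \\sum_i n_i (n_i - 1) / (N (N - 1))

with integer read counts :math:`n_i` and :math:`N = \\sum n_i`; for
non-integer abundance vectors (plant importance values) the plug-in form
:math:`1 - \\sum P_i^2` is available behind an explicit flag.

All logarithms are natural by default, which makes Shannon evenness and
Pielou evenness coincide (their formulas then do); a base-10 switch exists
for comparison with sources that mix bases.
"""

from __future__ import annotations

import logging
import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import OtuTable

__all__ = [
    "shannon",
    "simpson_unbiased",
    "simpson_plugin",
    "evenness_suite",
    "alpha_profile",
    "subgroup_alpha_table",
    "one_way_anova_letters",
]

logger = logging.getLogger(__name__)

METRICS = ("shannon", "simpson", "shannon_evenness", "simpson_evenness",
           "pielou_evenness", "richness")


def _log(x, base: float | None):
    return np.log(x) if base is None else np.log(x) / math.log(base)


def _positive_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    return c


def shannon(counts, base: float | None = None) -> float:
    """Shannon-Wiener diversity, -sum P_i log P_i (0 log 0 := 0)."""
    c = _positive_counts(counts)
    p = c / c.sum()
    return float(-(p * _log(p, base)).sum())


def simpson_unbiased(counts) -> float:
    """Unbiased Simpson diversity 1 - sum n_i(n_i-1)/(N(N-1))."""
    c = _positive_counts(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError(
            "unbiased Simpson requires integer counts; use simpson_plugin "
            "for proportion-valued abundances"
        )
    N = c.sum()
    if N < 2:
        raise ValueError("unbiased Simpson requires at least 2 individuals")
    return float(1.0 - (c * (c - 1)).sum() / (N * (N - 1)))


def simpson_plugin(abundances) -> float:
    """Plug-in Simpson diversity 1 - sum P_i^2 (for non-count data)."""
    c = _positive_counts(abundances)
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def evenness_suite(counts, base: float | None = None) -> tuple[float, float, float]:
    """(shannon_evenness, simpson_evenness, pielou_evenness).

    Each index divides by log(m), m = number of species with positive
    counts; undefined (NaN) for m < 2.  With a uniform log base the
    Shannon and Pielou evenness indices coincide.
    """
    c = _positive_counts(counts)
    m = c.size
    if m < 2:
        return (math.nan, math.nan, math.nan)
    logm = float(_log(m, base))
    h = shannon(c, base=base)
    d = simpson_unbiased(c)
    return (h / logm, d / logm, h / logm)


def alpha_profile(counts, base: float | None = None) -> dict[str, float]:
    """All six indices for one count vector; NaN where undefined."""
    c = _positive_counts(counts)
    m = int(c.size)
    out = {"richness": float(m), "shannon": shannon(c, base=base)}
    out["simpson"] = simpson_unbiased(c) if c.sum() >= 2 else math.nan
    se, de, pe = evenness_suite(c, base=base) if m >= 2 else (math.nan,) * 3
    out["shannon_evenness"] = se
    out["simpson_evenness"] = de
    out["pielou_evenness"] = pe
    return out


def subgroup_alpha_table(t: OtuTable, groups: dict[str, list[str]],
                         base: float | None = None) -> pd.DataFrame:
    """Per sample x subgroup diversity profile (long format).

    ``groups`` maps subgroup label to OTU ids (e.g. from
    ``AbundanceClassification.groups()`` or ``NicheBreadthResult.groups()``).
    Indices are computed on the raw subgroup-restricted counts (they are
    scale-free within a sample).  Subgroups with zero reads in a sample
    are reported absent (NaN row).
    """
    rows = []
    for label, otus in groups.items():
        sub = t.counts[list(otus)] if otus else None
        for sid in t.sample_ids:
            rec = {"sample_id": sid, "subgroup": label}
            vec = sub.loc[sid].to_numpy() if sub is not None else np.array([])
            if vec.size and vec.sum() > 0:
                rec.update(alpha_profile(vec, base=base))
            else:
                rec.update({m: math.nan for m in METRICS})
            rows.append(rec)
    return pd.DataFrame(rows).set_index(["sample_id", "subgroup"])


def _compact_letter_display(groups: list[str], means: dict[str, float],
                            distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Groups sharing a letter are *not* significantly different.  Standard
    insert-and-absorb construction over the significant-pair constraints.
    """
    order = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = [set(order)]
    for a, b in distinct:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    # absorb: drop sets contained in others (already ensured), keep stable order
    letters = {}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    ordered_sets = sorted(letter_sets, key=lambda s: min(order.index(g) for g in s))
    for k, s in enumerate(ordered_sets):
        for g in s:
            letters[g] = letters.get(g, "") + alphabet[k % len(alphabet)]
    return {g: "".join(sorted(letters[g])) for g in order}


def one_way_anova_letters(values_by_group: dict[str, np.ndarray],
                          alpha: float = 0.05) -> dict:
    """Classical one-way ANOVA plus Tukey-HSD compact letter display.

    Groups with fewer than 2 observations are excluded with a warning.
    Returns a dict with ``F``, ``p``, a per-group summary frame (mean, sd,
    n, letters) and the Tukey pairwise p-value table.  Groups sharing a
    letter are not significantly different at ``alpha``.
    """
    clean = {}
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            logger.warning("group %r has < 2 observations and was excluded", g)
            continue
        clean[g] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")

    labels = list(clean)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings
        F, p = stats.f_oneway(*clean.values())
    if not np.isfinite(F):
        allv = np.concatenate(list(clean.values()))
        if np.ptp(allv) == 0:  # degenerate: every observation identical
            F, p = 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance fixtures
        tukey = stats.tukey_hsd(*clean.values())
    distinct = set()
    pair_p = pd.DataFrame(np.ones((len(labels), len(labels))),
                          index=labels, columns=labels)
    for i, j in combinations(range(len(labels)), 2):
        pv = float(tukey.pvalue[i, j])
        pair_p.iloc[i, j] = pair_p.iloc[j, i] = pv
        if pv < alpha:
            distinct.add((labels[i], labels[j]))

    means = {g: float(v.mean()) for g, v in clean.items()}
    letters = _compact_letter_display(labels, means, distinct)
    summary = pd.DataFrame(
        {
            "n": [clean[g].size for g in labels],
            "mean": [means[g] for g in labels],
            "sd": [float(clean[g].std(ddof=1)) for g in labels],
            "letters": [letters[g] for g in labels],
        },
        index=pd.Index(labels, name="group"),
    )
    return {"F": float(F), "p": float(p), "summary": summary,
            "pairwise_p": pair_p}
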