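"""Abundance-gradient classification of OTUs into six threshold categories.

An OTU's per-sample relative abundances within one analysis set (normally
one soil layer) are summarized by their minimum ``n`` and maximum ``m`` and
compared against two thresholds, by default 1% (``hi``) and 0.01% (``lo``)
of a sample's reads:

========  =============================================================
AAT       permanently abundant: above ``hi`` in every sample
ART       permanently rare: below ``lo`` in every sample
MT        moderate: within [``lo``, ``hi``] in every sample
CAT       conditionally abundant: never below ``lo``, above ``hi`` somewhere
CRT       conditionally rare: below ``lo`` somewhere, never above ``hi``
CRAT      conditionally rare-and-abundant: below ``lo`` somewhere *and*
          above ``hi`` somewhere
========  =============================================================

"Above"/"below" are strict inequalities, so threshold-equal values fall to
the middle categories.  The six categories partition all classified OTUs;
they collapse to three subgroups: AAT+CAT = abundant, ART+CRT = rare,
MT+CRAT = medium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import OtuTable, RelativeAbundanceTable

__all__ = [
    "CATEGORIES",
    "COLLAPSE",
    "AbundanceClassification",
    "classify_abundance",
    "subgroup_summary",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("AAT", "ART", "MT", "CAT", "CRT", "CRAT")

COLLAPSE = {
    "AAT": "abundant",
    "CAT": "abundant",
    "ART": "rare",
    "CRT": "rare",
    "MT": "medium",
    "CRAT": "medium",
}

COLLAPSED = ("abundant", "medium", "rare")


@dataclass
class AbundanceClassification:
    """Per-OTU abundance category over one analyzed sample set."""

    assignments: pd.DataFrame = field(repr=False)  # min_ra, max_ra, category, collapsed
    hi: float
    lo: float
    sample_ids: list[str]
    n_excluded: int = 0

    @property
    def otu_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def category(self) -> pd.Series:
        return self.assignments["category"]

    @property
    def collapsed(self) -> pd.Series:
        return self.assignments["collapsed"]

    def otus_in(self, subgroup: str) -> list[str]:
        """OTU ids of a category or collapsed subgroup."""
        a = self.assignments
        if subgroup in CATEGORIES:
            return list(a.index[a["category"] == subgroup])
        if subgroup in COLLAPSED:
            return list(a.index[a["collapsed"] == subgroup])
        raise ValueError(f"unknown subgroup {subgroup!r}")

    def groups(self, collapsed: bool = True) -> dict[str, list[str]]:
        labels = COLLAPSED if collapsed else CATEGORIES
        return {g: self.otus_in(g) for g in labels}


def classify_abundance(r: RelativeAbundanceTable, hi: float = 0.01,
                       lo: float = 0.0001) -> AbundanceClassification:
    """Assign every OTU present in the sample set to one of six categories.

    Parameters
    ----------
    r : RelativeAbundanceTable
        Already restricted to the sample set under analysis (one soil
        layer in the standard workflow).
    hi, lo : float
        Upper and lower relative-abundance thresholds as fractions
        (defaults 0.01 and 0.0001, i.e. 1% and 0.01% of a sample's reads).

    OTUs absent from every sample in the set are excluded (counted, not
    classified).
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    frac = r.fractions
    present = frac.sum(axis=0) > 0
    n_excluded = int((~present).sum())
    if n_excluded:
        logger.warning(
            "%d OTU(s) absent from all %d samples were excluded from "
            "abundance classification", n_excluded, frac.shape[0],
        )
    frac = frac.loc[:, present]

    mn = frac.min(axis=0).to_numpy()
    mx = frac.max(axis=0).to_numpy()

    category = np.where(
        mn > hi, "AAT",
        np.where(
            mx < lo, "ART",
            np.where(
                (mn >= lo) & (mx <= hi), "MT",
                np.where(
                    (mn >= lo) & (mx > hi), "CAT",
                    np.where((mn < lo) & (mx <= hi), "CRT", "CRAT"),
                ),
            ),
        ),
    )
    assignments = pd.DataFrame(
        {
            "min_ra": mn,
            "max_ra": mx,
            "category": category,
            "collapsed": [COLLAPSE[c] for c in category],
        },
        index=frac.columns.rename("otu_id"),
    )
    return AbundanceClassification(
        assignments=assignments, hi=hi, lo=lo,
        sample_ids=list(frac.index), n_excluded=n_excluded,
    )


def subgroup_summary(t: OtuTable, c: AbundanceClassification,
                     collapsed: bool = True) -> pd.DataFrame:
    """Per-subgroup OTU-count fraction and read-abundance fraction.

    Columns ``otu_fraction`` and ``read_fraction`` each sum to 1 over the
    reported subgroups; empty subgroups are reported as 0, not omitted.
    """
    counts = t.counts.loc[c.sample_ids, c.otu_ids]
    total_otus = len(c.otu_ids)
    total_reads = counts.to_numpy().sum()
    labels = COLLAPSED if collapsed else CATEGORIES
    rows = []
    for g in labels:
        otus = c.otus_in(g)
        reads = counts[otus].to_numpy().sum() if otus else 0
        rows.append(
            {
                "subgroup": g,
                "n_otus": len(otus),
                "otu_fraction": len(otus) / total_otus if total_otus else 0.0,
                "read_fraction": reads / total_reads if total_reads else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")
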