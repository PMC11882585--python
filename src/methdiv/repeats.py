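"""DMC overlap with repeat classes and enrichment against control subsets.

A 1-based site position ``p`` overlaps an internal half-open interval
``[start, end)`` iff ``start <= p < end``.  A site under annotations of
two different classes is counted once for each class (multi-counting);
within one class, nested or overlapping intervals still count the site
once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmc import bh_fdr
from .io import RepeatAnnotation
from .resampling import EnrichmentReport, SubsetCollection, subset_ttest


def _class_hits(sites: pd.DataFrame, class_df: pd.DataFrame) -> np.ndarray:
    """Boolean per site: overlaps any interval of one class (sorted-array
    stabbing: #starts <= p minus #ends <= p is the number of covering
    intervals)."""
    hit = np.zeros(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom, g in class_df.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(g["start"].to_numpy(dtype=np.int64))
        ends = np.sort(g["end"].to_numpy(dtype=np.int64))
        p = pos[sel]
        covering = np.searchsorted(starts, p, side="right") - np.searchsorted(
            ends, p, side="right"
        )
        hit[sel] = covering > 0
    return hit


def overlap_by_class(
    sites: pd.DataFrame, repeats: RepeatAnnotation, by_name: bool = False
) -> pd.DataFrame:
    """Count of query sites overlapping each repeat class (or repeat name
    with ``by_name``); returns class, count and fraction of the query."""
    key = "name" if by_name else "repeat_class"
    n = len(sites)
    rows = []
    if len(repeats):
        for label, g in repeats.intervals.groupby(key, sort=True):
            c = int(_class_hits(sites, g).sum())
            rows.append({"repeat_class": label, "count": c,
                         "fraction": c / n if n else 0.0})
    return pd.DataFrame(rows, columns=["repeat_class", "count", "fraction"])


def class_enrichment(
    dmc_sites: pd.DataFrame,
    subsets: SubsetCollection,
    repeats: RepeatAnnotation,
    alpha: float = 0.05,
    by_name: bool = False,
) -> EnrichmentReport:
    """Per repeat class: observed DMC overlap count, the k subset counts,
    subset-vs-observed t-test, BH correction across classes, and the
    enrichment direction (observed above or below the subset mean)."""
    key = "name" if by_name else "repeat_class"
    if not len(repeats):
        empty = pd.DataFrame(
            columns=["repeat_class", "observed", "subset_mean", "subset_sd",
                     "t", "p", "q", "direction", "significant"]
        )
        return EnrichmentReport(empty, np.empty((0, subsets.k)))
    labels = sorted(repeats.intervals[key].unique())
    class_frames = {lab: g for lab, g in repeats.intervals.groupby(key)}

    def counts(sites: pd.DataFrame) -> np.ndarray:
        return np.array(
            [int(_class_hits(sites, class_frames[lab]).sum()) for lab in labels],
            dtype=float,
        )

    obs = counts(dmc_sites)
    sub = np.stack([counts(subsets.subset_sites(i)) for i in range(subsets.k)])
    rows = []
    for j, lab in enumerate(labels):
        res = subset_ttest(sub[:, j], obs[j])
        rows.append(
            {
                "repeat_class": lab,
                "observed": obs[j],
                "subset_mean": sub[:, j].mean(),
                "subset_sd": sub[:, j].std(ddof=1),
                "t": res.statistic,
                "p": res.pvalue,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"])
    table["direction"] = np.where(
        table["observed"] >= table["subset_mean"], "enriched", "depleted"
    )
    table["significant"] = table["q"] < alpha
    return EnrichmentReport(table, sub.T)
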