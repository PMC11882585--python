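"""Nearest-feature distances and cumulative-interval enrichment.

One code path serves both analyses that compare how often DMCs versus
random control subsets fall near a point-feature set: proximity to SNPs
and proximity to an external reference DMC list.  Distances are
strand-agnostic; a query on a chromosome with no features gets an
infinite sentinel, which is never counted in any bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PositionSet, ValidationError
from .resampling import EnrichmentReport, SubsetCollection, subset_ttest

DEFAULT_THRESHOLDS = (2, 10, 100, 2000)


def nearest_distance(
    query: dict[str, np.ndarray] | PositionSet, features: PositionSet
) -> dict[str, np.ndarray]:
    """Nearest-feature distance per query position, grouped by chromosome.

    Both inputs are sorted per chromosome; the lookup is a sorted-merge
    (searchsorted) over feature positions.  Chromosomes missing from the
    feature set yield ``inf`` for all their queries.
    """
    if isinstance(query, PositionSet):
        query = {c: query.positions(c) for c in query.chroms}
    out: dict[str, np.ndarray] = {}
    for chrom, q in query.items():
        q = np.asarray(q, dtype=np.int64)
        f = features.positions(chrom)
        if f.size == 0:
            out[chrom] = np.full(q.shape, np.inf)
            continue
        idx = np.searchsorted(f, q)
        left = np.where(idx > 0, np.abs(q - f[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(
            idx < f.size, np.abs(f[np.minimum(idx, f.size - 1)] - q), np.inf
        )
        out[chrom] = np.minimum(left, right).astype(float)
    return out


def nearest_distance_sites(
    sites: pd.DataFrame, features: PositionSet
) -> np.ndarray:
    """Nearest-feature distance aligned with the rows of a site table."""
    dist = np.full(len(sites), np.inf)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        dist[sel] = nearest_distance({chrom: pos[sel]}, features)[chrom]
    return dist


@dataclass
class ProximityBins:
    """Cumulative fraction of query sites within each distance threshold."""

    thresholds: tuple[int, ...]
    fractions: np.ndarray
    counts: np.ndarray
    n_query: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fractions) < 0):
            raise AssertionError("cumulative fractions must be non-decreasing")


def bin_cumulative(
    distances: np.ndarray, thresholds: Sequence[int] = DEFAULT_THRESHOLDS
) -> ProximityBins:
    """Fraction of sites with nearest distance <= t for each threshold t
    ("up to t" is inclusive).  Infinite sentinels are never counted."""
    th = tuple(int(t) for t in thresholds)
    if any(b <= a for a, b in zip(th, th[1:])):
        raise ValidationError(f"thresholds must be strictly increasing: {th}")
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValidationError("empty query: cumulative fractions undefined")
    counts = np.array([(d <= t).sum() for t in th], dtype=np.int64)
    return ProximityBins(th, counts / d.size, counts, int(d.size))


def proximity_enrichment(
    dmc_sites: pd.DataFrame,
    subsets: SubsetCollection,
    features: PositionSet,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> EnrichmentReport:
    """Per threshold: observed DMC near-feature fraction, the k subset
    fractions, and the subset-vs-observed t-test."""
    obs = bin_cumulative(nearest_distance_sites(dmc_sites, features), thresholds)

    def frac(sites: pd.DataFrame) -> np.ndarray:
        return bin_cumulative(
            nearest_distance_sites(sites, features), thresholds
        ).fractions

    sub = np.stack([frac(subsets.subset_sites(i)) for i in range(subsets.k)])
    rows = []
    for j, t in enumerate(obs.thresholds):
        res = subset_ttest(sub[:, j], obs.fractions[j])
        rows.append(
            {
                "threshold_bp": t,
                "observed": obs.fractions[j],
                "subset_mean": sub[:, j].mean(),
                "subset_sd": sub[:, j].std(ddof=1),
                "t": res.statistic,
                "p": res.pvalue,
            }
        )
    return EnrichmentReport(pd.DataFrame(rows), sub.T)
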