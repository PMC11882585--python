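"""Random control-cytosine subsets (r-Cs) and the subset-vs-observed test.

The empirical null used throughout the enrichment analyses: ``k`` subsets
of tested, non-differentially-methylated cytosines, each the size of the
DMC set, drawn uniformly without replacement.  A statistic computed on the
DMC set is compared against the k subset values with a t-type test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass
class SubsetCollection:
    """k same-size subsets of a site universe, reproducible from a seed.

    ``universe`` is a DataFrame of candidate sites (chrom, pos, ...);
    ``subsets`` holds integer row indices into it.  The universe is the
    tested-site list minus the DMCs, so no subset can contain a DMC.
    """

    universe: pd.DataFrame
    subsets: list[np.ndarray]
    seed: int
    n: int

    @property
    def k(self) -> int:
        return len(self.subsets)

    def subset_sites(self, i: int) -> pd.DataFrame:
        return self.universe.iloc[self.subsets[i]].reset_index(drop=True)

    def apply(self, fn: Callable[[pd.DataFrame], float]) -> np.ndarray:
        """Evaluate a per-site-set statistic on every subset."""
        return np.array([fn(self.subset_sites(i)) for i in range(self.k)])


def draw_subsets(
    universe: pd.DataFrame, n: int, k: int, seed: int
) -> SubsetCollection:
    """Draw k independent subsets of size n, uniformly without replacement.

    Subsets may overlap each other.  Subset i uses its own generator seeded
    ``seed + i``, so extending k never changes earlier subsets.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if n > len(universe):
        raise ValidationError(
            f"subset size {n} exceeds universe size {len(universe)}"
        )
    universe = universe.reset_index(drop=True)
    subsets = []
    for i in range(k):
        rng = np.random.default_rng(seed + i)
        idx = rng.choice(len(universe), size=n, replace=False)
        subsets.append(np.sort(idx))
    return SubsetCollection(universe, subsets, seed, n)


@dataclass
class TTestResult:
    statistic: float
    df: int
    pvalue: float


def subset_ttest(
    subset_stats: Sequence[float],
    observed: float,
    include_observed_variance: bool = True,
) -> TTestResult:
    """t-test of the k subset statistics against the observed DMC statistic.

    With ``include_observed_variance`` (default) the denominator is
    ``s * sqrt(1/k + 1)``: the observed statistic is itself one draw from
    the same sampling law as each subset statistic, so the comparison uses
    the prediction-interval scaling and holds its nominal level when the
    observed set is exchangeable with the subsets.  With the flag off the
    classic one-sample scaling ``s / sqrt(k)`` is used, which treats the
    observed value as a known constant and is strongly anti-conservative
    under exchangeability.  Either way df = k - 1, two-sided.
    """
    x = np.asarray(subset_stats, dtype=float)
    k = x.size
    if k < 2:
        raise ValidationError(f"need >= 2 subset statistics, got {k}")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        if observed == mean:
            return TTestResult(0.0, k - 1, 1.0)
        warnings.warn(
            "degenerate subset variance (all subset statistics equal); "
            "reporting p = 0",
            stacklevel=2,
        )
        return TTestResult(np.inf if mean < observed else -np.inf, k - 1, 0.0)
    scale = np.sqrt(1.0 / k + 1.0) if include_observed_variance else np.sqrt(1.0 / k)
    t = (mean - observed) / (sd * scale)
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    return TTestResult(float(t), k - 1, float(min(p, 1.0)))


@dataclass
class EnrichmentReport:
    """Observed-vs-subsets comparison, one row per bin or class.

    ``table`` columns: a label column, ``observed``, ``subset_mean``,
    ``subset_sd``, ``t``, ``p`` (plus ``q``/``direction`` where multiple
    classes are tested).  ``subset_values`` has shape (n_rows, k) with the
    raw per-subset statistics.
    """

    table: pd.DataFrame
    subset_values: np.ndarray
    extra: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        for j in range(self.subset_values.shape[1]):
            df[f"subset_{j}"] = self.subset_values[:, j]
        with open(path, "w") as fh:
            fh.write("# observed statistic vs random control subsets\n")
            df.to_csv(fh, sep="\t", index=False)


def subset_consistency_check(
    subsets: SubsetCollection, predicate_values: np.ndarray
) -> pd.DataFrame:
    """Compare each subset's predicate fraction with the universe fraction.

    ``predicate_values`` is a boolean array aligned with the universe rows
    (e.g. "within 100 bp of a SNP").  A subset is flagged when its hit
    count falls outside the central 99% binomial interval implied by the
    universe fraction.
    """
    vals = np.asarray(predicate_values, dtype=bool)
    if vals.shape[0] != len(subsets.universe):
        raise ValidationError("predicate values not aligned with universe")
    p_uni = vals.mean() if vals.size else 0.0
    lo, hi = stats.binom.interval(0.99, subsets.n, p_uni) if subsets.n else (0, 0)
    rows = []
    for i in range(subsets.k):
        hits = int(vals[subsets.subsets[i]].sum())
        rows.append(
            {
                "subset": i,
                "fraction": hits / subsets.n if subsets.n else 0.0,
                "hits": hits,
                "universe_fraction": p_uni,
                "flagged": not (lo <= hits <= hi),
            }
        )
    return pd.DataFrame(rows)
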