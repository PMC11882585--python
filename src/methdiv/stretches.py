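"""CpG stretch detection and stretch enrichment against control subsets.

A stretch is a maximal run of at least ``min_sites`` cytosines in which
every consecutive gap is at most ``max_gap`` bp (defaults 2 sites and
2000 bp).  Stretches are detected within the DMC set (or within each
control subset), not within all tested CpGs: the quantity of interest is
adjacency of differentially methylated cytosines.  Strands are pooled, so
the two cytosines of a dyad (1 bp apart) can seed a stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError
from .resampling import EnrichmentReport, SubsetCollection, subset_ttest

DISTANCE_CLASS_LABELS = ("1bp", "2-2000bp", ">2000bp")


@dataclass(frozen=True)
class Stretch:
    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> int:
        """Inclusive span in bp (end - start + 1)."""
        return self.end - self.start + 1


def _positions_by_chrom(sites: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, g in sites.groupby("chrom", sort=True):
        out[chrom] = np.unique(g["pos"].to_numpy(dtype=np.int64))
    return out


def next_distance_classes(
    sites: pd.DataFrame, boundaries: tuple[int, int] = (1, 2000)
) -> pd.DataFrame:
    """Classify each site's distance to the next site on its chromosome.

    Default classes: exactly 1 bp, 2..2000 bp, and more than 2000 bp.  The
    last site per chromosome contributes no distance.  Returns counts and
    fractions per class.
    """
    b1, b2 = boundaries
    counts = dict.fromkeys(DISTANCE_CLASS_LABELS, 0)
    for pos in _positions_by_chrom(sites).values():
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        counts["1bp"] += int((gaps <= b1).sum())
        counts["2-2000bp"] += int(((gaps > b1) & (gaps <= b2)).sum())
        counts[">2000bp"] += int((gaps > b2).sum())
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "class": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total if total else 0.0 for c in counts.values()],
        }
    )


def find_stretches(
    sites: pd.DataFrame, max_gap: int = 2000, min_sites: int = 2
) -> list[Stretch]:
    """Maximal runs of sites with consecutive gaps <= ``max_gap``.

    Single greedy pass per chromosome over the sorted positions; a run is
    emitted when it holds at least ``min_sites`` members.
    """
    if max_gap < 1:
        raise ValidationError(f"max_gap must be >= 1, got {max_gap}")
    if min_sites < 2:
        raise ValidationError(f"min_sites must be >= 2, got {min_sites}")
    out: list[Stretch] = []
    for chrom, pos in _positions_by_chrom(sites).items():
        if pos.size == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
        for run in np.split(pos, breaks):
            if run.size >= min_sites:
                out.append(
                    Stretch(chrom, int(run[0]), int(run[-1]), tuple(int(p) for p in run))
                )
    return out


def stretches_to_frame(stretches: list[Stretch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_sites": s.n_sites,
                "span_bp": s.span,
            }
            for s in stretches
        ],
        columns=["chrom", "start", "end", "n_sites", "span_bp"],
    )


def write_stretch_bed(stretches: list[Stretch], path) -> None:
    """BED output (0-based half-open), name column = member site count."""
    with open(path, "w") as fh:
        for s in stretches:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.n_sites}\n")


def in_stretch_fraction(
    sites: pd.DataFrame, max_gap: int = 2000, min_sites: int = 2
) -> float:
    """Fraction of sites that belong to some stretch."""
    if not len(sites):
        return 0.0
    n_in = sum(s.n_sites for s in find_stretches(sites, max_gap, min_sites))
    n_total = sum(p.size for p in _positions_by_chrom(sites).values())
    return n_in / n_total


def stretch_enrichment(
    dmc_sites: pd.DataFrame,
    subsets: SubsetCollection,
    max_gap: int = 2000,
    min_sites: int = 2,
) -> EnrichmentReport:
    """Compare the in-stretch site fraction of the DMC set against the k
    control subsets; next-CpG distance-class fractions for every set are
    attached under ``extra['distance_classes']``."""
    obs = in_stretch_fraction(dmc_sites, max_gap, min_sites)
    sub = subsets.apply(lambda s: in_stretch_fraction(s, max_gap, min_sites))
    res = subset_ttest(sub, obs)
    table = pd.DataFrame(
        [
            {
                "statistic": "in_stretch_fraction",
                "observed": obs,
                "subset_mean": sub.mean(),
                "subset_sd": sub.std(ddof=1),
                "t": res.statistic,
                "p": res.pvalue,
            }
        ]
    )
    classes = next_distance_classes(dmc_sites).set_index("class")["fraction"]
    class_rows = {"DMC": classes}
    for i in range(subsets.k):
        class_rows[f"subset_{i}"] = next_distance_classes(
            subsets.subset_sites(i)
        ).set_index("class")["fraction"]
    return EnrichmentReport(
        table, sub[None, :], extra={"distance_classes": pd.DataFrame(class_rows)}
    )
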