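"""Projecting DMCs onto a low-coverage multi-stage dataset.

The use case: a second bisulfite dataset with several developmental
stages, each with few shallow replicates.  Replicates are pooled within
stage, DMC sites covered in every stage are retained, and the per-stage
methylation profiles (optionally joined with external profiles such as
the two sperm groups) are hierarchically clustered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ValidationError
from .matrix import MethylationMatrix


@dataclass
class StageProfile:
    """Pooled per-stage counts over a shared site list."""

    sites: pd.DataFrame
    stages: list[str]
    meth: np.ndarray  # (n_sites, n_stages)
    unmeth: np.ndarray

    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def fractions(self) -> np.ndarray:
        cov = self.coverage()
        with np.errstate(invalid="ignore"):
            return np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)


def pool_replicates(
    matrix: MethylationMatrix, stage_sheet: Mapping[str, str] | None = None
) -> StageProfile:
    """Sum replicate counts site-wise within each stage.

    ``stage_sheet`` maps sample id -> stage; when omitted the matrix's own
    group labels are used as stages.  Every stage needs >= 1 replicate.
    """
    sheet = dict(stage_sheet) if stage_sheet is not None else dict(matrix.groups)
    missing = [s for s in matrix.samples if s not in sheet]
    if missing:
        raise ValidationError(f"samples without a stage: {missing}")
    stages = sorted(set(sheet[s] for s in matrix.samples))
    if not stages:
        raise ValidationError("no stages defined")
    meth = np.zeros((matrix.n_sites, len(stages)), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    for j, stage in enumerate(stages):
        cols = [i for i, s in enumerate(matrix.samples) if sheet[s] == stage]
        meth[:, j] = matrix.meth[:, cols].sum(axis=1)
        unmeth[:, j] = matrix.unmeth[:, cols].sum(axis=1)
    return StageProfile(matrix.sites.copy(), stages, meth, unmeth)


def stage_filter(
    profile: StageProfile, sites: pd.DataFrame, min_cov: int = 5
) -> pd.DataFrame:
    """Methylation fractions at the given sites (e.g. DMC positions) for
    sites with pooled coverage >= ``min_cov`` in every stage.

    Returns a DataFrame indexed by (chrom, pos) with one column per stage.
    """
    if min_cov < 1:
        raise ValidationError(f"min_cov must be >= 1, got {min_cov}")
    key = pd.MultiIndex.from_frame(profile.sites[["chrom", "pos"]])
    want = pd.MultiIndex.from_frame(sites[["chrom", "pos"]].drop_duplicates())
    present = key.isin(want)
    covered = (profile.coverage() >= min_cov).all(axis=1)
    keep = present & covered
    out = pd.DataFrame(
        profile.fractions()[keep], columns=profile.stages, index=key[keep]
    )
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str
    dropped: list[str]


def _to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = max(node.dist - node.get_left().dist, 0.0)
    dr = max(node.dist - node.get_right().dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hierarchical_cluster(
    fraction_df: pd.DataFrame,
    method: str = "average",
    metric: str = "correlation",
) -> ClusterResult:
    """Cluster profile columns; default distance 1 - Pearson correlation
    over shared non-missing sites, average linkage.

    Columns constant across sites (undefined correlation) are dropped with
    a warning.  ``metric="euclidean"`` switches to Euclidean distance on
    pairwise-complete rows.  Ties break deterministically by column order.
    """
    df = fraction_df.copy()
    if metric == "correlation":
        keep = [c for c in df.columns if df[c].dropna().nunique() > 1]
        dropped = [c for c in df.columns if c not in keep]
        if dropped:
            warnings.warn(
                f"dropping constant column(s) with undefined correlation: "
                f"{dropped}",
                stacklevel=2,
            )
        df = df[keep]
    else:
        dropped = []
    labels = list(df.columns)
    if len(labels) < 2 or len(df) < 2:
        raise ValidationError("need >= 2 columns and >= 2 sites to cluster")
    if metric == "correlation":
        corr = df.corr(method="pearson", min_periods=2)
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
    elif metric == "euclidean":
        x = df.to_numpy()
        n = x.shape[1]
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
                d = np.sqrt(np.nansum((x[ok, i] - x[ok, j]) ** 2))
                dist[i, j] = dist[j, i] = d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.isnan(dist).any():
        raise ValidationError("undefined pairwise distance (no shared sites)")
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    tree = hierarchy.to_tree(z)
    leaf_order = [labels[i] for i in hierarchy.leaves_list(z)]
    newick = _to_newick(tree, labels) + ";"
    return ClusterResult(z, labels, leaf_order, newick, dropped)
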