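"""Global descriptive statistics and sample PCA for the filtered matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError
from .matrix import MethylationMatrix


def global_methylation_stats(
    matrix: MethylationMatrix, meth_call_threshold: float = 0.5
) -> dict:
    """Mean methylation per sample and overall, plus the fraction of sites
    called methylated (pooled site fraction >= ``meth_call_threshold``)."""
    if not 0 <= meth_call_threshold <= 1:
        raise ValidationError("threshold must be in [0,1]")
    if matrix.n_sites == 0:
        raise ValidationError("empty matrix: no statistics defined")
    frac = matrix.fractions()
    per_sample = {
        s: float(np.nanmean(frac[:, j])) for j, s in enumerate(matrix.samples)
    }
    pooled_m = matrix.meth.sum(axis=1)
    pooled_cov = matrix.coverage().sum(axis=1)
    with np.errstate(invalid="ignore"):
        site_frac = np.where(pooled_cov > 0, pooled_m / np.maximum(pooled_cov, 1), np.nan)
    covered = ~np.isnan(site_frac)
    methylated_fraction = (
        float((site_frac[covered] >= meth_call_threshold).mean())
        if covered.any()
        else 0.0
    )
    return {
        "per_sample_mean": per_sample,
        "overall_mean": float(np.nanmean(frac)),
        "methylated_site_fraction": methylated_fraction,
        "n_sites": matrix.n_sites,
    }


@dataclass
class SampleProjection:
    """Sample coordinates on the leading principal components."""

    coords: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray


def pca_samples(
    matrix: MethylationMatrix, n_components: int = 2
) -> SampleProjection:
    """PCA of samples on site-centered methylation fractions.

    Fractions are centered per site, not scaled; sites with missing
    coverage in any sample are excluded (none remain after the all-sample
    coverage filter).  Sign convention: on each component the
    largest-magnitude sample coordinate is positive.
    """
    if matrix.n_samples < 3:
        raise ValidationError("PCA needs >= 3 samples")
    frac = matrix.fractions()
    complete = ~np.isnan(frac).any(axis=1)
    x = frac[complete].T  # samples x sites
    if x.shape[1] == 0:
        raise ValidationError("no sites with complete coverage")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, s.size)
    coords = u[:, :n_components] * s[:n_components]
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    total_var = (s**2).sum()
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return SampleProjection(
        pd.DataFrame(
            coords,
            index=matrix.samples,
            columns=[f"PC{j + 1}" for j in range(n_components)],
        ),
        evr,
    )


def plot_pca(
    projection: SampleProjection, groups: dict[str, str], path
) -> None:
    """Scatter of the first two components, colored by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    coords = projection.coords
    for g in sorted(set(groups.values())):
        sel = [s for s in coords.index if groups[s] == g]
        ax.scatter(coords.loc[sel, "PC1"], coords.loc[sel, "PC2"], label=g)
    evr = projection.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
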