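"""Per-CpG two-group differential methylation testing with FDR control.

The default per-site test is the likelihood-ratio test of the group
coefficient in a binomial logistic regression of methylation state on
group, computed on the pooled per-group counts.  With no overdispersion
term this is exactly the G-test of independence on the pooled 2x2 table
(methylated/unmethylated x group), which is how it is evaluated here in
vectorized form.  A replicate-aware quasi-binomial variant is available
behind ``method="quasibinomial"`` for data where per-sample variability
beyond binomial sampling is a concern.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import SnpSet, ValidationError
from .matrix import MethylationMatrix
from .proximity import nearest_distance_sites

logger = logging.getLogger(__name__)


def g_test(
    meth_a, unmeth_a, meth_b, unmeth_b
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized G-test on 2x2 tables [[meth_a, unmeth_a], [meth_b, unmeth_b]].

    Returns (G statistic, p-value from the chi-square 1-df tail).  Cells
    with zero observed count contribute zero to G.
    """
    o = np.stack(
        [np.asarray(x, dtype=float) for x in (meth_a, unmeth_a, meth_b, unmeth_b)],
        axis=-1,
    )
    row_a = o[..., 0] + o[..., 1]
    row_b = o[..., 2] + o[..., 3]
    col_m = o[..., 0] + o[..., 2]
    col_u = o[..., 1] + o[..., 3]
    total = row_a + row_b
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.stack(
            [row_a * col_m, row_a * col_u, row_b * col_m, row_b * col_u],
            axis=-1,
        ) / total[..., None]
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    g = np.where(np.isfinite(g), np.maximum(g, 0.0), 0.0)
    return g, stats.chi2.sf(g, df=1)


def site_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float:
    """P-value for one site from pooled (meth, unmeth) counts per group.

    Raises ``ValidationError`` when a group has zero total reads (the test
    is undefined there; ``call_dmcs`` skips such sites with a logged
    reason).
    """
    ma, ua = counts_a
    mb, ub = counts_b
    if ma + ua == 0 or mb + ub == 0:
        raise ValidationError("site_test undefined: zero total reads in a group")
    _, p = g_test(ma, ua, mb, ub)
    return float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _quasibinomial_pvalues(matrix: MethylationMatrix) -> np.ndarray:
    """Per-site Wald p for the group effect in a quasi-binomial GLM fitted
    on per-sample counts (Pearson-X2 scale estimate).  Slow; opt-in."""
    import statsmodels.api as sm

    ga, gb = matrix.group_labels
    x = np.array(
        [0.0 if matrix.groups[s] == ga else 1.0 for s in matrix.samples]
    )
    design = sm.add_constant(x)
    pvals = np.ones(matrix.n_sites)
    for i in range(matrix.n_sites):
        endog = np.column_stack([matrix.meth[i], matrix.unmeth[i]])
        if endog.sum() == 0:
            continue
        try:
            fit = sm.GLM(endog, design, family=sm.families.Binomial()).fit(
                scale="X2"
            )
            pvals[i] = fit.pvalues[1]
        except Exception:  # perfect separation etc.
            pvals[i] = 1.0
    return pvals


def call_dmcs(
    matrix: MethylationMatrix,
    fdr_threshold: float = 0.05,
    method: str = "pooled-lrt",
) -> pd.DataFrame:
    """Test every site and flag DMCs at the given FDR threshold.

    Returns a table sorted by (chrom, pos) with pooled per-group counts,
    count-weighted group methylation fractions ``frac_a``/``frac_b``
    (groups in sorted label order), ``delta = frac_a - frac_b``, p, BH q
    and ``is_dmc`` (q <= ``fdr_threshold``).  Sites where one group has
    zero pooled coverage are skipped with a logged count.
    """
    labels = matrix.group_labels
    if len(labels) != 2:
        raise ValidationError(
            f"differential testing needs exactly 2 groups, got {labels}"
        )
    ga, gb = labels
    ma, ua = matrix.pooled_counts(ga)
    mb, ub = matrix.pooled_counts(gb)
    tested = ((ma + ua) > 0) & ((mb + ub) > 0)
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info(
            "skipping %d site(s) with zero pooled coverage in a group",
            n_skipped,
        )

    df = matrix.sites.copy()
    df["meth_a"], df["unmeth_a"] = ma, ua
    df["meth_b"], df["unmeth_b"] = mb, ub
    df = df.loc[tested].reset_index(drop=True)
    if not len(df):
        for col in ("frac_a", "frac_b", "delta", "p", "q"):
            df[col] = pd.Series(dtype=float)
        df["is_dmc"] = pd.Series(dtype=bool)
        return df

    if method == "pooled-lrt":
        _, p = g_test(df["meth_a"], df["unmeth_a"], df["meth_b"], df["unmeth_b"])
    elif method == "quasibinomial":
        p = _quasibinomial_pvalues(matrix.subset_sites(tested))
    else:
        raise ValueError(f"unknown method {method!r}")

    df["frac_a"] = df["meth_a"] / (df["meth_a"] + df["unmeth_a"])
    df["frac_b"] = df["meth_b"] / (df["meth_b"] + df["unmeth_b"])
    df["delta"] = df["frac_a"] - df["frac_b"]
    df["p"] = p
    df["q"] = bh_fdr(p)
    df["is_dmc"] = df["q"] <= fdr_threshold
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def select_high_confidence(
    dmc_table: pd.DataFrame,
    snps: SnpSet,
    min_delta: float = 0.20,
    min_snp_dist: int = 100,
) -> pd.DataFrame:
    """High-confidence DMC subset: |delta| strictly above ``min_delta`` and
    nearest-SNP distance strictly above ``min_snp_dist`` bp (DMCs at or
    below the distance cutoff are excluded as possibly genetic in origin).
    Sites on chromosomes with no SNPs count as infinitely distant."""
    dmcs = dmc_table[dmc_table["is_dmc"]].copy()
    if not len(dmcs):
        dmcs["snp_dist"] = pd.Series(dtype=float)
        return dmcs
    dmcs["snp_dist"] = nearest_distance_sites(dmcs, snps)
    keep = (dmcs["delta"].abs() > min_delta) & (dmcs["snp_dist"] > min_snp_dist)
    return dmcs.loc[keep].reset_index(drop=True)


def write_dmc_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-site differential methylation test results\n")
        df.to_csv(fh, sep="\t", index=False)
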