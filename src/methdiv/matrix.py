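"""Multi-sample methylation count matrix and the two site filters.

The matrix is the unit every downstream stage consumes: an ordered site
list (chrom, pos, strand) with per-site x per-sample methylated and
unmethylated read counts, plus a sample sheet mapping sample ids to group
labels.  Sites are keyed by (chrom, pos); cytosines on opposite strands of
a CpG dyad sit at different positions and are kept as separate sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CpGRecord, SnpSet, ValidationError, warn_unshared_chromosomes


@dataclass
class MethylationMatrix:
    """Sites x samples methylation counts with group labels.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos, strand, sorted by (chrom, pos).
    meth, unmeth : int arrays of shape (n_sites, n_samples).
    samples : sample ids, column order of the count arrays.
    groups : mapping sample id -> group label.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    unmeth: np.ndarray
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise ValidationError("meth/unmeth shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValidationError("count arrays do not match sites x samples")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.groups[s] for s in self.samples))

    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def fractions(self) -> np.ndarray:
        """Per-site/sample methylation fraction; NaN where coverage is 0."""
        cov = self.coverage()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        return np.asarray(idx, dtype=int)

    def pooled_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Sum counts over the samples of one group -> (meth, unmeth) vectors."""
        cols = self.group_columns(group)
        return self.meth[:, cols].sum(axis=1), self.unmeth[:, cols].sum(axis=1)

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylationMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask],
            self.unmeth[mask],
            list(self.samples),
            dict(self.groups),
        )

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the wide TSV form: site columns then meth/unmeth per sample."""
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[f"{s}.meth"] = self.meth[:, j]
            df[f"{s}.unmeth"] = self.unmeth[:, j]
        with open(path, "w") as fh:
            fh.write("#groups\t" + "\t".join(
                f"{s}={self.groups[s]}" for s in self.samples) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylationMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#groups\t"):
                raise ValidationError(f"{path}: missing #groups header line")
            groups = dict(tok.split("=", 1) for tok in header.split("\t")[1:])
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "strand": str})
        samples = list(groups)
        # C order: reductions must sum in the same order as on fresh builds
        meth = np.ascontiguousarray(
            df[[f"{s}.meth" for s in samples]].to_numpy(dtype=np.int64)
        )
        unmeth = np.ascontiguousarray(
            df[[f"{s}.unmeth" for s in samples]].to_numpy(dtype=np.int64)
        )
        return cls(df[["chrom", "pos", "strand"]].copy(), meth, unmeth,
                   samples, groups)


def _records_frame(records: Sequence[CpGRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records[["chrom", "pos", "strand", "meth", "unmeth"]].copy()
    else:
        df = pd.DataFrame(
            [(r.chrom, r.pos, r.strand, r.meth, r.unmeth) for r in records],
            columns=["chrom", "pos", "strand", "meth", "unmeth"],
        )
    df["chrom"] = df["chrom"].astype(str)
    return df


def build_matrix(
    records_by_sample: Mapping[str, Sequence[CpGRecord] | pd.DataFrame],
    sample_sheet: Mapping[str, str] | pd.DataFrame,
) -> MethylationMatrix:
    """Assemble the union-of-sites matrix from per-sample record sets.

    ``sample_sheet`` maps sample id -> group label (or is a DataFrame with
    ``sample`` and ``group`` columns).  Sites absent from a sample get
    (0, 0) counts.  Every sheet sample must have a record collection.
    """
    if isinstance(sample_sheet, pd.DataFrame):
        if sample_sheet["sample"].duplicated().any():
            dup = sample_sheet.loc[sample_sheet["sample"].duplicated(), "sample"]
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dup))}")
        groups = dict(zip(sample_sheet["sample"], sample_sheet["group"]))
    else:
        groups = dict(sample_sheet)
    if not groups:
        raise ValidationError("empty sample sheet")
    missing = [s for s in groups if s not in records_by_sample]
    if missing:
        raise ValidationError(f"sample(s) in sheet with no records: {missing}")
    samples = list(groups)

    frames = []
    for s in samples:
        df = _records_frame(records_by_sample[s])
        if df.duplicated(["chrom", "pos"]).any():
            raise ValidationError(f"sample {s}: duplicate site positions")
        df["sample"] = s
        frames.append(df)
    all_df = pd.concat(frames, ignore_index=True)

    sites = (
        all_df.groupby(["chrom", "pos"], sort=True)["strand"]
        .agg(lambda s: next((x for x in s if x in "+-"), "."))
        .reset_index()
    )[["chrom", "pos", "strand"]]
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    row = pd.Series(np.arange(len(sites)), index=key)

    n = len(sites)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    for j, s in enumerate(samples):
        df = all_df[all_df["sample"] == s]
        r = row.loc[pd.MultiIndex.from_frame(df[["chrom", "pos"]])].to_numpy()
        meth[r, j] = df["meth"].to_numpy()
        unmeth[r, j] = df["unmeth"].to_numpy()
    return MethylationMatrix(sites.reset_index(drop=True), meth, unmeth,
                             samples, groups)


def filter_coverage(
    matrix: MethylationMatrix, min_cov: int, require_all: bool = True
) -> MethylationMatrix:
    """Keep sites with coverage >= ``min_cov`` in every sample
    (``require_all``) or in at least one sample otherwise."""
    if min_cov < 0:
        raise ValidationError(f"min_cov must be >= 0, got {min_cov}")
    cov = matrix.coverage()
    ok = cov >= min_cov
    keep = ok.all(axis=1) if require_all else ok.any(axis=1)
    return matrix.subset_sites(keep)


def mask_snp_positions(
    matrix: MethylationMatrix, snps: SnpSet, dyad_mode: bool = False
) -> tuple[MethylationMatrix, int]:
    """Remove sites whose cytosine position coincides with a SNP.

    With ``dyad_mode`` the guanine position of the dyad is also checked:
    pos+1 for forward-strand cytosines, pos-1 for reverse-strand ones, and
    both neighbors when the strand is unknown.  Returns the masked matrix
    and the number of removed sites.
    """
    warn_unshared_chromosomes(
        matrix.sites["chrom"].unique(), snps.chroms, context="matrix vs SNPs"
    )
    hit = np.zeros(matrix.n_sites, dtype=bool)
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    strand = matrix.sites["strand"].to_numpy()
    for chrom in np.unique(chroms):
        arr = snps.positions(chrom)
        if arr.size == 0:
            continue
        sel = chroms == chrom
        p = pos[sel]
        in_set = lambda q: np.isin(q, arr)  # noqa: E731 - local helper
        h = in_set(p)
        if dyad_mode:
            st = strand[sel]
            fwd = (st == "+") | (st == ".")
            rev = (st == "-") | (st == ".")
            h |= fwd & in_set(p + 1)
            h |= rev & in_set(p - 1)
        hit[sel] = h
    return matrix.subset_sites(~hit), int(hit.sum())
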