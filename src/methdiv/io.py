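"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions
----------------------
Point features (cytosines, SNPs, reference cytosine lists) are 1-based,
matching the bisulfite coverage format that dominates the inputs.  Interval
annotations (repeats) are kept half-open exactly as they appear on a BED
line; RepeatMasker rows (1-based inclusive) are shifted to that convention
on input.  A 1-based point ``p`` is considered inside an internal interval
``[start, end)`` iff ``start <= p < end``.

Chromosome names are matched by exact string equality everywhere; when two
inputs disagree on their chromosome sets a warning lists the unshared names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """The file is not in (or cannot be recognized as) an expected format."""


class ParseError(FormatError):
    """A specific line failed to parse; the message names the line number."""


class ValidationError(ValueError):
    """Parsed values violate a field invariant (range, sign, order)."""


@dataclass(frozen=True)
class CpGRecord:
    """One cytosine position with methylation counts for one sample.

    Positions are 1-based.  ``strand`` is ``'+'``, ``'-'`` or ``'.'`` when
    unknown.  Coverage is ``meth + unmeth``.
    """

    chrom: str
    pos: int
    meth: int
    unmeth: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.meth < 0 or self.unmeth < 0:
            raise ValidationError(
                f"negative count at {self.chrom}:{self.pos}: "
                f"meth={self.meth} unmeth={self.unmeth}"
            )

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


class PositionSet:
    """Sorted, unique 1-based point positions grouped by chromosome."""

    def __init__(self, positions: Mapping[str, Iterable[int]] | None = None):
        self._pos: dict[str, np.ndarray] = {}
        if positions:
            for chrom, pos in positions.items():
                arr = np.unique(np.asarray(list(pos), dtype=np.int64))
                if arr.size and arr[0] < 1:
                    raise ValidationError(f"positions must be >= 1 on {chrom}")
                if arr.size:
                    self._pos[str(chrom)] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return int(sum(a.size for a in self._pos.values()))

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos = site
        arr = self.positions(chrom)
        i = np.searchsorted(arr, pos)
        return bool(i < arr.size and arr[i] == pos)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": c, "pos": self._pos[c]}) for c in self.chroms
        ]
        if not frames:
            return pd.DataFrame({"chrom": pd.Series(dtype=str),
                                 "pos": pd.Series(dtype=np.int64)})
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PositionSet":
        return cls(
            {c: g["pos"].to_numpy() for c, g in df.groupby("chrom", sort=True)}
        )


class SnpSet(PositionSet):
    """Point SNP positions plus per-group alternate-allele frequencies.

    ``af`` maps chromosome -> array of shape (n_snps, 2) aligned with the
    sorted positions; columns follow the two group labels in order.
    """

    def __init__(
        self,
        positions: Mapping[str, Iterable[int]] | None = None,
        af: Mapping[str, np.ndarray] | None = None,
        group_labels: tuple[str, str] = ("group1", "group2"),
    ):
        super().__init__(positions)
        self.group_labels = group_labels
        self.af: dict[str, np.ndarray] = {}
        if af:
            for chrom, a in af.items():
                a = np.asarray(a, dtype=float)
                if a.size and (a.min() < 0 or a.max() > 1):
                    raise ValidationError(
                        f"allele frequency outside [0,1] on {chrom}"
                    )
                self.af[str(chrom)] = a

    def af_filter(self, min_af: float) -> "SnpSet":
        """Positions with alternate-allele frequency strictly above
        ``min_af`` in at least one group."""
        positions, afs = {}, {}
        for chrom in self.chroms:
            a = self.af[chrom]
            keep = (a[:, 0] > min_af) | (a[:, 1] > min_af)
            if keep.any():
                positions[chrom] = self.positions(chrom)[keep]
                afs[chrom] = a[keep]
        return SnpSet(positions, afs, self.group_labels)


@dataclass
class RepeatAnnotation:
    """Interval annotations with a repeat class/family and a repeat name.

    ``intervals`` has columns chrom, start, end (internal half-open),
    repeat_class, name.
    """

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "repeat_class", "name"]
        )
    )

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df):
            bad = df["start"] >= df["end"]
            if bad.any():
                row = df[bad].iloc[0]
                raise ValidationError(
                    f"empty/inverted interval {row['chrom']}:"
                    f"{row['start']}-{row['end']}"
                )
            if (df["repeat_class"].astype(str).str.len() == 0).any():
                raise ValidationError("empty repeat class label")

    @property
    def classes(self) -> list[str]:
        return sorted(self.intervals["repeat_class"].unique()) if len(
            self.intervals
        ) else []

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# coverage tables (6-column bisulfite coverage format)
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path) -> list[CpGRecord]:
    """Read a 6-column bisulfite coverage table for one sample.

    Columns: chrom, start, end, methylation percentage, methylated count,
    unmethylated count; coordinates 1-based inclusive.  The percentage
    column is ignored in favor of the counts.  Records are returned sorted
    by (chrom, pos).  An optional 7th column carries the strand.
    """
    records: list[CpGRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=6 columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                pos = int(parts[1])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            strand = parts[6] if len(parts) > 6 else "."
            try:
                records.append(
                    CpGRecord(chrom, pos, meth, unmeth, strand=strand)
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_coverage_table(records: Sequence[CpGRecord], path: str | Path) -> None:
    """Write records in the 6-column coverage format (plus strand column)."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            pct = 100.0 * r.meth / r.coverage if r.coverage else 0.0
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:.6g}\t{r.meth}\t"
                f"{r.unmeth}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def _read_snp_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    rows = []
    for var in vcf:
        af1 = var.INFO.get("AF1")
        af2 = var.INFO.get("AF2")
        if af1 is None and af2 is None:
            af = var.INFO.get("AF")
            af1 = af2 = af if af is not None else 0.0
        rows.append(
            (var.CHROM, var.POS, float(af1 or 0.0), float(af2 or 0.0))
        )
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "af1", "af2"])


def read_snp_table(path: str | Path, min_af: float = 0.10) -> SnpSet:
    """Read SNPs from a VCF or a 4-column TSV and apply the AF filter.

    A position is retained iff its alternate-allele frequency is strictly
    greater than ``min_af`` in at least one of the two groups.  VCF input
    reads per-group frequencies from INFO keys ``AF1``/``AF2`` (falling
    back to a shared ``AF``); TSV columns are chrom, pos, af_group1,
    af_group2.
    """
    if not 0 <= min_af <= 1:
        raise ValidationError(f"min_af must be in [0,1], got {min_af}")
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        df = _read_snp_vcf(path)
    else:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "af1", "af2"],
            dtype={"chrom": str},
        )
    if len(df):
        af = df[["af1", "af2"]].to_numpy(dtype=float)
        if af.min() < 0 or af.max() > 1:
            raise ValidationError(f"{path}: allele frequency outside [0,1]")
        keep = (af[:, 0] > min_af) | (af[:, 1] > min_af)
        df = df[keep]
    df = df.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    positions = {}
    afs = {}
    for chrom, g in df.groupby("chrom", sort=True):
        positions[chrom] = g["pos"].to_numpy(dtype=np.int64)
        afs[chrom] = g[["af1", "af2"]].to_numpy(dtype=float)
    return SnpSet(positions, afs)


# ---------------------------------------------------------------------------
# repeats and reference position sets
# ---------------------------------------------------------------------------

def _read_repeat_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: BED repeat rows need >=4 columns"
                )
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            rclass = parts[6] if len(parts) > 6 else name
            rows.append((chrom, start, end, rclass, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class", "name"])


def _read_repeatmasker_out(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] in ("SW", "score") or parts[0].startswith("#"):
                continue
            if len(parts) < 11:
                raise ParseError(
                    f"{path}: line {lineno}: RepeatMasker rows need >=11 fields"
                )
            chrom = parts[4]
            start1, end1 = int(parts[5]), int(parts[6])  # 1-based inclusive
            name, rclass = parts[9], parts[10]
            rows.append((chrom, start1 - 1, end1, rclass, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class", "name"])


def read_repeat_annotation(path: str | Path) -> RepeatAnnotation:
    """Read repeat intervals from BED (class in column 7, else the name
    column) or RepeatMasker ``.out``, normalized to half-open coordinates."""
    path = Path(path)
    if path.suffix == ".bed":
        df = _read_repeat_bed(path)
    elif path.suffix == ".out":
        df = _read_repeatmasker_out(path)
    else:
        raise FormatError(
            f"unknown repeat annotation extension {path.suffix!r} "
            f"(expected .bed or .out)"
        )
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return RepeatAnnotation(df)


def read_position_set(path: str | Path) -> PositionSet:
    """Read point positions from BED (``start+1`` as the 1-based point) or a
    2-column TSV (chrom, 1-based pos); deduplicated and sorted."""
    path = Path(path)
    rows: list[tuple[str, int]] = []
    is_bed = path.suffix == ".bed"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: need >=2 columns")
            try:
                if is_bed:
                    rows.append((parts[0], int(parts[1]) + 1))
                else:
                    rows.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in rows:
        by_chrom.setdefault(chrom, []).append(pos)
    return PositionSet(by_chrom)


def write_position_set(ps: PositionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\n")
        for chrom in ps.chroms:
            for pos in ps.positions(chrom):
                fh.write(f"{chrom}\t{pos}\n")


def warn_unshared_chromosomes(a: Iterable[str], b: Iterable[str],
                              context: str = "") -> None:
    """Warn when two inputs do not share the same chromosome names."""
    sa, sb = set(a), set(b)
    only_a, only_b = sorted(sa - sb), sorted(sb - sa)
    if only_a or only_b:
        warnings.warn(
            f"chromosome sets differ{f' ({context})' if context else ''}: "
            f"only in first: {only_a}; only in second: {only_b}",
            stacklevel=3,
        )
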