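"""Synthetic two-group RRBS count data with known ground truth.

The generator emulates the statistical regime the pipeline assumes:
bimodal CpG methylation (a low Beta mode and a high Beta mode), negative
binomial read coverage around a configurable mean, a set of planted
differentially methylated cytosines (constant methylation shift in one
group), spatial coupling of a configurable fraction of planted DMCs to
SNPs, planted runs of adjacent DMCs (stretches), and repeat intervals
whose classes can carry a boosted planted-DMC density.  Everything is
driven by a single seed and is reproducible byte-for-byte.

Planted roles are disjoint: a site is a stretch member, a SNP-coupled
DMC, or a plain (possibly repeat-weighted) DMC, never two of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RepeatAnnotation, SnpSet
from .matrix import MethylationMatrix
from .proximity import nearest_distance_sites


class ConfigError(ValueError):
    """The simulation configuration is infeasible."""


@dataclass
class RepeatClassSpec:
    """One simulated repeat class: interval count/length and the planted
    DMC density multiplier inside its intervals."""

    n_intervals: int = 60
    length: int = 1000
    dmc_multiplier: float = 1.0


def _default_repeats() -> dict[str, RepeatClassSpec]:
    return {
        "LTR/ERV2": RepeatClassSpec(60, 1000, 3.0),
        "rRNA/5S": RepeatClassSpec(30, 500, 3.0),
        "Satellite/BTSAT4": RepeatClassSpec(40, 1500, 3.0),
        "LINE/L1": RepeatClassSpec(80, 2000, 2.0),
        "SINE/tRNA": RepeatClassSpec(60, 300, 1.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the two-breed sperm comparison the pipeline targets:
    9 + 9 samples, ~30X mean coverage with a 10X-in-all downstream filter,
    ~30% of CpGs in the methylated mode, planted DMCs with a 0.4
    methylation shift, 30% of them within 100 bp of a SNP.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_cpg: int = 20_000
    samples_per_group: int = 9
    group_labels: tuple[str, ...] = ("H", "M")
    coverage_mean: float = 30.0
    coverage_dispersion: float = 15.0  # NB size; var = m + m^2/size
    meth_low: tuple[float, float] = (1.0, 10.0)  # Beta(a,b) unmethylated mode
    meth_high: tuple[float, float] = (10.0, 1.0)  # Beta(a,b) methylated mode
    high_mode_weight: float = 0.30
    n_planted_dmcs: int = 500
    delta: float = 0.40
    clip: tuple[float, float] = (0.02, 0.98)
    couple_fraction: float = 0.30
    d_couple: int = 100
    n_snps: int = 2000
    snp_on_cpg_fraction: float = 0.02
    snp_low_af_fraction: float = 0.05
    n_stretches: int = 12
    stretch_sites: int = 8
    stretch_gap: tuple[int, int] = (10, 500)
    repeat_classes: dict[str, RepeatClassSpec] = field(
        default_factory=_default_repeats
    )

    def validate(self) -> None:
        if self.n_planted_dmcs > self.n_cpg:
            raise ConfigError("more planted DMCs than CpG sites")
        if self.n_stretches * self.stretch_sites > self.n_planted_dmcs:
            raise ConfigError("stretch members exceed the planted-DMC budget")
        n_coupled = round(self.couple_fraction * self.n_planted_dmcs)
        plain = self.n_planted_dmcs - self.n_stretches * self.stretch_sites
        if n_coupled > plain:
            raise ConfigError(
                "coupled DMCs exceed the non-stretch planted budget"
            )
        if n_coupled > self.n_snps:
            raise ConfigError("coupled DMCs exceed the SNP budget")
        if not 0 <= self.high_mode_weight <= 1:
            raise ConfigError("high_mode_weight must be in [0,1]")
        if not 0 <= self.couple_fraction <= 1:
            raise ConfigError("couple_fraction must be in [0,1]")
        if len(self.group_labels) < 2:
            raise ConfigError("need >= 2 groups")
        if self.n_cpg > self.n_chromosomes * self.chrom_length // 4:
            raise ConfigError("CpG count too dense for the genome size")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimulatedTruth:
    """Ground truth for one bundle.

    ``sites`` rows are aligned with the emitted coverage files and carry
    chrom, pos, strand, the per-group methylation means (``p_<group>``),
    is_planted_dmc, planted_delta, stretch_id (-1 for none), repeat_class
    ("" for none), coupled flag and nearest_snp_bp recomputable from the
    emitted, AF-filtered SNP set.
    """

    sites: pd.DataFrame
    snps: SnpSet
    repeats: RepeatAnnotation
    config: SimulationConfig

    @property
    def group_p(self) -> np.ndarray:
        cols = [f"p_{g}" for g in self.config.group_labels]
        return self.sites[cols].to_numpy()


def _draw_distinct_positions(
    rng: np.random.Generator, n: int, length: int, taken: set[int]
) -> np.ndarray:
    out: list[int] = []
    while len(out) < n:
        cand = rng.integers(1, length + 1, size=max(2 * (n - len(out)), 16))
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return np.array(out, dtype=np.int64)


def generate_truth(config: SimulationConfig) -> SimulatedTruth:
    """Draw CpG positions, planted structure, SNPs and repeats for one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names
    taken: dict[str, set[int]] = {c: set() for c in chroms}

    # stretches first: runs of adjacent planted DMCs
    stretch_rows = []
    for sid in range(config.n_stretches):
        chrom = chroms[int(rng.integers(len(chroms)))]
        gaps = rng.integers(
            config.stretch_gap[0], config.stretch_gap[1] + 1,
            size=config.stretch_sites - 1,
        )
        span = int(gaps.sum())
        anchor = int(rng.integers(1, config.chrom_length - span))
        pos = anchor + np.concatenate([[0], np.cumsum(gaps)])
        if any(int(p) in taken[chrom] for p in pos):
            continue  # rare collision: drop and re-plant below
        for p in pos:
            taken[chrom].add(int(p))
            stretch_rows.append((chrom, int(p), sid))
    # re-plant any stretches dropped by collisions
    while len({r[2] for r in stretch_rows}) < config.n_stretches:
        existing = {r[2] for r in stretch_rows}
        sid = next(i for i in range(config.n_stretches) if i not in existing)
        chrom = chroms[int(rng.integers(len(chroms)))]
        gaps = rng.integers(
            config.stretch_gap[0], config.stretch_gap[1] + 1,
            size=config.stretch_sites - 1,
        )
        span = int(gaps.sum())
        anchor = int(rng.integers(1, config.chrom_length - span))
        pos = anchor + np.concatenate([[0], np.cumsum(gaps)])
        if any(int(p) in taken[chrom] for p in pos):
            continue
        for p in pos:
            taken[chrom].add(int(p))
            stretch_rows.append((chrom, int(p), sid))

    # background CpGs fill the remaining budget, uniform per chromosome
    n_stretch_sites = len(stretch_rows)
    n_base = config.n_cpg - n_stretch_sites
    base = rng.multinomial(n_base, np.full(len(chroms), 1 / len(chroms)))
    rows = [(c, p, sid) for c, p, sid in stretch_rows]
    for chrom, nb in zip(chroms, base):
        for p in _draw_distinct_positions(rng, int(nb), config.chrom_length,
                                          taken[chrom]):
            rows.append((chrom, int(p), -1))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "stretch_id"])
    sites["strand"] = np.where(rng.random(len(sites)) < 0.5, "+", "-")
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)

    # repeat intervals
    rep_rows = []
    for rclass, cspec in config.repeat_classes.items():
        for i in range(cspec.n_intervals):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - cspec.length))
            rep_rows.append(
                (chrom, start, start + cspec.length, rclass,
                 f"{rclass.split('/')[-1]}_{i}")
            )
    repeats = RepeatAnnotation(
        pd.DataFrame(
            rep_rows, columns=["chrom", "start", "end", "repeat_class", "name"]
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
    )

    # per-site repeat class (first matching class in sorted order) and
    # the planted-DMC selection weight from the class multipliers
    site_class = np.full(len(sites), "", dtype=object)
    weight = np.ones(len(sites))
    from .repeats import _class_hits  # sorted-array stabbing

    for rclass in sorted(config.repeat_classes):
        g = repeats.intervals[repeats.intervals["repeat_class"] == rclass]
        hits = _class_hits(sites, g)
        fresh = hits & (site_class == "")
        site_class[fresh] = rclass
        mult = config.repeat_classes[rclass].dmc_multiplier
        weight[hits] = np.maximum(weight[hits], mult)

    # planted DMC assignment: stretch members are planted by construction;
    # the remaining budget is drawn with repeat-class weighting
    is_planted = (sites["stretch_id"] >= 0).to_numpy()
    plain_needed = config.n_planted_dmcs - int(is_planted.sum())
    candidates = np.nonzero(~is_planted)[0]
    if plain_needed > 0:
        w = weight[candidates]
        chosen = rng.choice(
            candidates, size=plain_needed, replace=False, p=w / w.sum()
        )
        is_planted[chosen] = True
    plain_planted = np.nonzero(is_planted & (sites["stretch_id"].to_numpy() < 0))[0]

    # SNP-coupled planted DMCs
    n_coupled = round(config.couple_fraction * config.n_planted_dmcs)
    coupled = np.zeros(len(sites), dtype=bool)
    if n_coupled > 0:
        pick = rng.choice(plain_planted, size=n_coupled, replace=False)
        coupled[pick] = True

    # SNP placement: coupled SNPs near their DMC, background uniform;
    # a small fraction of background SNPs lands ON non-planted CpGs to
    # exercise masking, the rest avoids CpG positions entirely
    snp_rows = []  # (chrom, pos, af1, af2)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy(dtype=np.int64)

    def high_af() -> tuple[float, float]:
        hi = float(rng.uniform(0.15, 0.9))
        lo = float(rng.uniform(0.0, 0.5))
        return (hi, lo) if rng.random() < 0.5 else (lo, hi)

    for i in np.nonzero(coupled)[0]:
        chrom, p = chrom_arr[i], int(pos_arr[i])
        for _ in range(100):
            off = int(rng.integers(1, config.d_couple + 1))
            sp = p + off if rng.random() < 0.5 else p - off
            if sp >= 1 and sp not in taken[chrom]:
                taken[chrom].add(sp)
                snp_rows.append((chrom, sp, *high_af()))
                break
        else:  # pragma: no cover - practically unreachable
            raise ConfigError(f"cannot place coupled SNP near {chrom}:{p}")

    n_bg = config.n_snps - len(snp_rows)
    n_on_cpg = round(config.snp_on_cpg_fraction * n_bg)
    non_planted = np.nonzero(~is_planted)[0]
    if n_on_cpg > 0:
        on_idx = rng.choice(non_planted, size=n_on_cpg, replace=False)
        for i in on_idx:
            snp_rows.append((chrom_arr[i], int(pos_arr[i]), *high_af()))
    n_low = round(config.snp_low_af_fraction * n_bg)
    for j in range(n_bg - n_on_cpg):
        chrom = chroms[int(rng.integers(len(chroms)))]
        sp = int(
            _draw_distinct_positions(rng, 1, config.chrom_length, taken[chrom])[0]
        )
        if j < n_low:  # below the default AF filter in both groups
            af = (float(rng.uniform(0.0, 0.08)), float(rng.uniform(0.0, 0.08)))
        else:
            af = high_af()
        snp_rows.append((chrom, sp, *af))

    snp_df = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "af1", "af2"]
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    snps = SnpSet(
        {c: g["pos"].to_numpy() for c, g in snp_df.groupby("chrom")},
        {c: g[["af1", "af2"]].to_numpy() for c, g in snp_df.groupby("chrom")},
        group_labels=tuple(config.group_labels[:2]),
    )

    # methylation means: bimodal baseline, one randomly chosen group
    # shifted by +-delta at planted sites (direction avoids clipping)
    n = len(sites)
    lo_a, lo_b = config.meth_low
    hi_a, hi_b = config.meth_high
    is_high = rng.random(n) < config.high_mode_weight
    p0 = np.where(
        is_high, rng.beta(hi_a, hi_b, size=n), rng.beta(lo_a, lo_b, size=n)
    )
    p0 = np.clip(p0, config.clip[0], config.clip[1])
    groups = list(config.group_labels)
    p_mat = np.tile(p0[:, None], (1, len(groups)))
    planted_delta = np.zeros(n)
    planted_idx = np.nonzero(is_planted)[0]
    if planted_idx.size:
        shifted_group = rng.integers(len(groups), size=planted_idx.size)
        up_ok = p0[planted_idx] + config.delta <= config.clip[1]
        down_ok = p0[planted_idx] - config.delta >= config.clip[0]
        coin = rng.random(planted_idx.size) < 0.5
        sign = np.where(up_ok & down_ok, np.where(coin, 1.0, -1.0),
                        np.where(up_ok, 1.0, -1.0))
        for j, (i, g, s) in enumerate(zip(planted_idx, shifted_group, sign)):
            newp = np.clip(
                p0[i] + s * config.delta, config.clip[0], config.clip[1]
            )
            planted_delta[i] = newp - p0[i]
            p_mat[i, g] = newp

    out = sites[["chrom", "pos", "strand"]].copy()
    for j, g in enumerate(groups):
        out[f"p_{g}"] = p_mat[:, j]
    out["is_planted_dmc"] = is_planted
    out["planted_delta"] = planted_delta
    out["stretch_id"] = sites["stretch_id"].to_numpy()
    out["repeat_class"] = site_class
    out["coupled"] = coupled
    out["nearest_snp_bp"] = nearest_distance_sites(out, _af_filtered(snps, 0.10))
    return SimulatedTruth(out, snps, repeats, config)


def _af_filtered(snps: SnpSet, min_af: float) -> SnpSet:
    return snps.af_filter(min_af)


def sample_counts(
    truth: SimulatedTruth, config: SimulationConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Per-sample coverage records: coverage ~ NB(mean, dispersion), meth ~
    Binomial(coverage, group methylation mean); independent across sites
    and samples.  Returns sample id -> DataFrame(chrom, pos, strand, meth,
    unmeth)."""
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    n = len(truth.sites)
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    out: dict[str, pd.DataFrame] = {}
    base = truth.sites[["chrom", "pos", "strand"]]
    for j, g in enumerate(config.group_labels):
        pg = truth.group_p[:, j]
        for i in range(config.samples_per_group):
            cov = rng.negative_binomial(r, p_nb, size=n)
            meth = rng.binomial(cov, pg)
            df = base.copy()
            df["meth"] = meth
            df["unmeth"] = cov - meth
            out[f"{g}{i + 1}"] = df
    return out


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (f"{g}{i + 1}", g)
        for g in config.group_labels
        for i in range(config.samples_per_group)
    ]
    return pd.DataFrame(rows, columns=["sample", "group"])


def build_simulated_matrix(
    truth: SimulatedTruth, records: dict[str, pd.DataFrame] | None = None
) -> MethylationMatrix:
    """Matrix over all simulated sites (zero-coverage entries included),
    bypassing file I/O; equivalent to emitting and re-reading the bundle."""
    records = records or sample_counts(truth)
    sheet = sample_sheet(truth.config)
    samples = list(sheet["sample"])
    meth = np.column_stack([records[s]["meth"].to_numpy() for s in samples])
    unmeth = np.column_stack([records[s]["unmeth"].to_numpy() for s in samples])
    sites = truth.sites[["chrom", "pos", "strand"]].copy()
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    return MethylationMatrix(
        sites.iloc[order].reset_index(drop=True),
        meth[order],
        unmeth[order],
        samples,
        dict(zip(sheet["sample"], sheet["group"])),
    )


def _write_vcf(snps_df: pd.DataFrame, groups: tuple[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID=AF1,Number=1,Type=Float,Description='
            f'"Alt allele frequency, group {groups[0]}">\n'
        )
        fh.write(
            f'##INFO=<ID=AF2,Number=1,Type=Float,Description='
            f'"Alt allele frequency, group {groups[1]}">\n'
        )
        for chrom in sorted(snps_df["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps_df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\tC\tT\t.\tPASS\t"
                f"AF1={row.af1:.4f};AF2={row.af2:.4f}\n"
            )


def emit_files(
    records: dict[str, pd.DataFrame], truth: SimulatedTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write the complete bundle: per-sample coverage tables (covered
    positions only), SNP VCF with per-group AF, repeat BED, sample sheet
    and the truth table.  Returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    paths: dict[str, Path] = {}
    for sample, df in records.items():
        p = outdir / f"{sample}.cov"
        covered = df[(df["meth"] + df["unmeth"]) > 0]
        with open(p, "w") as fh:
            for row in covered.itertuples(index=False):
                cov = row.meth + row.unmeth
                pct = 100.0 * row.meth / cov
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.6g}\t"
                    f"{row.meth}\t{row.unmeth}\t{row.strand}\n"
                )
        paths[f"coverage:{sample}"] = p

    snp_rows = []
    for chrom in truth.snps.chroms:
        af = truth.snps.af[chrom]
        for p, (a1, a2) in zip(truth.snps.positions(chrom), af):
            snp_rows.append((chrom, int(p), float(a1), float(a2)))
    snp_df = pd.DataFrame(snp_rows, columns=["chrom", "pos", "af1", "af2"])
    paths["snps"] = outdir / "snps.vcf"
    _write_vcf(snp_df, tuple(config.group_labels[:2]), paths["snps"])

    paths["repeats"] = outdir / "repeats.bed"
    with open(paths["repeats"], "w") as fh:
        for row in truth.repeats.intervals.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t.\t+\t"
                f"{row.repeat_class}\n"
            )

    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    sheet = sample_sheet(config)
    sheet["path"] = [str(outdir / f"{s}.cov") for s in sheet["sample"]]
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("# simulated ground truth (synthetic)\n")
        truth.sites.to_csv(fh, sep="\t", index=False)
    return paths


def simulate_bundle(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Generate truth + counts and write the full bundle in one call."""
    truth = generate_truth(config)
    records = sample_counts(truth, config)
    return emit_files(records, truth, outdir)
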