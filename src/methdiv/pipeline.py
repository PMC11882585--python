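"""End-to-end orchestration: filter -> test -> resampling enrichments.

One configuration object drives the whole analysis; a JSON manifest
records package version, parameters, seed, input checksums and per-stage
site counts, and contains nothing time-dependent, so two runs with the
same inputs and seed produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dmc import call_dmcs, select_high_confidence, write_dmc_table
from .io import (
    ValidationError,
    read_coverage_table,
    read_position_set,
    read_repeat_annotation,
    read_snp_table,
)
from .matrix import MethylationMatrix, build_matrix, filter_coverage, mask_snp_positions
from .proximity import proximity_enrichment
from .qc import global_methylation_stats, pca_samples
from .repeats import class_enrichment
from .resampling import draw_subsets
from .stretches import (
    find_stretches,
    stretch_enrichment,
    stretches_to_frame,
    write_stretch_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and the master seed for one run.

    The defaults are the analysis' standard operating point: 10X coverage
    in every sample, FDR 0.05, 10 control subsets, cumulative proximity
    bins at 2/10/100/2000 bp, stretches of >= 2 sites with gaps <= 2000
    bp, high-confidence DMCs with |delta| > 0.20 further than 100 bp from
    any SNP, and a 10% allele-frequency cut for the SNP set.
    """

    sample_sheet: str = ""
    snps: str = ""
    repeats: str = ""
    reference_sets: dict[str, str] = field(default_factory=dict)
    outdir: str = "methdiv_out"
    min_cov: int = 10
    require_all: bool = True
    mask_dyad: bool = False
    fdr: float = 0.05
    k: int = 10
    thresholds: tuple[int, ...] = (2, 10, 100, 2000)
    max_gap: int = 2000
    min_sites: int = 2
    min_delta: float = 0.20
    min_snp_dist: int = 100
    min_af: float = 0.10
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_matrix_from_sheet(sheet_path: str | Path) -> MethylationMatrix:
    """Build the raw matrix from a sample sheet (sample, group, path)."""
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    for col in ("sample", "group", "path"):
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    records = {
        row.sample: read_coverage_table(row.path)
        for row in sheet.itertuples(index=False)
    }
    return build_matrix(records, sheet[["sample", "group"]])


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Stages: coverage filter -> SNP masking -> DMC calling -> control
    subsets -> SNP proximity enrichment -> reference-set proximity
    enrichment -> stretch analysis -> repeat enrichment -> high-confidence
    selection -> QC.  With ``resume`` the filtered matrix and DMC table
    are reloaded from a previous run's outputs when present.
    """
    if config.k < 2:
        raise ValidationError("k must be >= 2 (the subset t-test needs k >= 2)")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "methdiv",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "inputs": {},
        "counts": {},
        "outputs": {},
    }
    for name, p in [("sample_sheet", config.sample_sheet),
                    ("snps", config.snps), ("repeats", config.repeats),
                    *[(f"reference:{n}", p) for n, p in
                      config.reference_sets.items()]]:
        if p:
            manifest["inputs"][name] = _sha256(Path(p))

    snps = read_snp_table(config.snps, min_af=config.min_af)
    manifest["counts"]["snps_after_af_filter"] = len(snps)

    filtered_path = outdir / "filtered_matrix.tsv"
    if resume and filtered_path.exists():
        logger.info("resume: loading filtered matrix from %s", filtered_path)
        masked = MethylationMatrix.from_tsv(filtered_path)
        raw_sites = cov_sites = None
    else:
        raw = load_matrix_from_sheet(config.sample_sheet)
        manifest["counts"]["sites_raw_union"] = raw.n_sites
        raw_sites = raw.n_sites
        covered = filter_coverage(raw, config.min_cov, config.require_all)
        cov_sites = covered.n_sites
        masked, n_removed = mask_snp_positions(
            covered, snps, dyad_mode=config.mask_dyad
        )
        manifest["counts"]["snp_masked_sites_removed"] = n_removed
        masked.to_tsv(filtered_path)
    manifest["counts"]["sites_after_coverage_filter"] = (
        cov_sites if cov_sites is not None else "resumed"
    )
    manifest["counts"]["sites_after_snp_mask"] = masked.n_sites
    manifest["outputs"]["filtered_matrix"] = str(filtered_path)

    dmc_path = outdir / "dmc_table.tsv"
    if resume and dmc_path.exists():
        with open(dmc_path) as fh:
            fh.readline()
            dmc_table = pd.read_csv(
                fh, sep="\t", dtype={"chrom": str},
                float_precision="round_trip",
            )
    else:
        dmc_table = call_dmcs(masked, fdr_threshold=config.fdr)
        write_dmc_table(dmc_table, dmc_path)
    manifest["outputs"]["dmc_table"] = str(dmc_path)
    dmcs = dmc_table[dmc_table["is_dmc"]].reset_index(drop=True)
    manifest["counts"]["sites_tested"] = len(dmc_table)
    manifest["counts"]["dmcs"] = len(dmcs)

    universe = dmc_table.loc[~dmc_table["is_dmc"], ["chrom", "pos"]].reset_index(
        drop=True
    )
    if len(dmcs) == 0 or len(universe) < len(dmcs):
        raise ValidationError(
            "cannot draw control subsets: "
            f"{len(dmcs)} DMCs vs {len(universe)} non-DMC sites"
        )
    subsets = draw_subsets(universe, n=len(dmcs), k=config.k, seed=config.seed)
    subdir = outdir / "subsets"
    subdir.mkdir(exist_ok=True)
    for i in range(subsets.k):
        subsets.subset_sites(i).to_csv(
            subdir / f"subset_{i:02d}.tsv", sep="\t", index=False
        )
    # invariant: control subsets never contain a DMC
    dmc_keys = set(zip(dmcs["chrom"], dmcs["pos"]))
    for i in range(subsets.k):
        s = subsets.subset_sites(i)
        assert not any(k in dmc_keys for k in zip(s["chrom"], s["pos"]))

    prox = proximity_enrichment(dmcs, subsets, snps, config.thresholds)
    prox.to_tsv(outdir / "proximity_snps.tsv")
    manifest["outputs"]["proximity_snps"] = str(outdir / "proximity_snps.tsv")

    for name, path in config.reference_sets.items():
        ref = read_position_set(path)
        rep = proximity_enrichment(dmcs, subsets, ref, config.thresholds)
        out = outdir / f"proximity_{name}.tsv"
        rep.to_tsv(out)
        manifest["outputs"][f"proximity_{name}"] = str(out)

    st = find_stretches(dmcs, config.max_gap, config.min_sites)
    write_stretch_bed(st, outdir / "stretches.bed")
    stretches_to_frame(st).to_csv(
        outdir / "stretch_table.tsv", sep="\t", index=False
    )
    st_rep = stretch_enrichment(dmcs, subsets, config.max_gap, config.min_sites)
    st_rep.to_tsv(outdir / "stretch_report.tsv")
    st_rep.extra["distance_classes"].to_csv(
        outdir / "distance_classes.tsv", sep="\t"
    )
    manifest["counts"]["stretches"] = len(st)
    manifest["outputs"]["stretches"] = str(outdir / "stretches.bed")

    if config.repeats:
        repeats = read_repeat_annotation(config.repeats)
        rep_report = class_enrichment(dmcs, subsets, repeats)
        rep_report.to_tsv(outdir / "repeat_enrichment.tsv")
        manifest["outputs"]["repeat_enrichment"] = str(
            outdir / "repeat_enrichment.tsv"
        )
        manifest["counts"]["repeat_classes_enriched"] = int(
            (rep_report.table["significant"]
             & (rep_report.table["direction"] == "enriched")).sum()
        )

    hc = select_high_confidence(
        dmc_table, snps, config.min_delta, config.min_snp_dist
    )
    write_dmc_table(hc, outdir / "high_confidence.tsv")
    manifest["counts"]["high_confidence_dmcs"] = len(hc)
    manifest["outputs"]["high_confidence"] = str(outdir / "high_confidence.tsv")

    stats = global_methylation_stats(masked)
    proj = pca_samples(masked)
    stats["pca_explained_variance_ratio"] = [
        float(v) for v in proj.explained_variance_ratio
    ]
    with open(outdir / "qc_summary.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    with open(outdir / "pca.tsv", "w") as fh:
        fh.write(
            "# explained variance ratio: "
            + ", ".join(f"{v:.6g}" for v in proj.explained_variance_ratio)
            + "\n"
        )
        proj.coords.to_csv(fh, sep="\t")
    manifest["counts"]["methylated_site_fraction"] = stats[
        "methylated_site_fraction"
    ]
    manifest["outputs"]["qc_summary"] = str(outdir / "qc_summary.json")

    # stage counts only ever shrink
    if raw_sites is not None:
        assert raw_sites >= cov_sites >= masked.n_sites

    for key, p in list(manifest["outputs"].items()):
        manifest["outputs"][key] = {"path": p, "sha256": _sha256(Path(p))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
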