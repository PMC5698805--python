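"""Pipeline orchestration: QC -> linkage -> IBD -> prioritization.

``run`` executes every stage a config enables, writes the three tier
reports, LOD tables, IBD segments, a line-oriented log of per-stage
in/out record counts, and a machine-readable summary; the whole run is
deterministic given its inputs and seed.
"""
from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import io as pio
from .ibd import IBDSegment, call_segments, sharing_profile
from .linkage import (
    DEFAULT_THETA_GRID,
    DiseaseModel,
    LinkageScanResults,
    MarkerData,
    MarkerModel,
    ParametricLinkage,
)
from .prioritize import (
    GeneCluster,
    PrioritizedVariant,
    strategy_cross_family,
    strategy_known_genes,
    strategy_linkage,
)
from .qc import QCConfig, filter_genotypes, filter_sites


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    vcf: str
    ped: str
    annotations: str
    gene_list: str
    output_dir: str
    markers: Optional[str] = None             # marker map (enables linkage stage)
    marker_genotypes: Optional[str] = None
    lod_regions: Optional[str] = None         # precomputed regions bypass linkage
    haplotypes: Optional[str] = None          # founder-haplotype labels (IBD stage)
    qc: QCConfig = field(default_factory=QCConfig)
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    lod_threshold: float = 2.0
    maf_known_gene: float = 0.02
    maf_novel: float = 0.01
    cadd_min: float = 15.0
    ibd_window: int = 10
    ibd_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})")
        try:
            qc = QCConfig(**raw.pop("qc", {}))
            dm_raw = raw.pop("disease_model", {})
            if "penetrances" in dm_raw:
                dm_raw["penetrances"] = tuple(dm_raw["penetrances"])
            dm = DiseaseModel(**dm_raw)
            if "theta_grid" in raw:
                raw["theta_grid"] = tuple(raw["theta_grid"])
            cfg = cls(qc=qc, disease_model=dm, **raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}")
        for name in ("vcf", "ped", "annotations", "gene_list"):
            p = getattr(cfg, name)
            if not os.path.exists(p):
                raise ConfigError(f"{name} path does not exist: {p}")
        return cfg


@dataclass
class RunBundle:
    tier1: list[PrioritizedVariant]
    tier2: list[PrioritizedVariant]
    tier3: list[GeneCluster]
    segments: list[IBDSegment]
    scan: Optional[LinkageScanResults]
    filter_log: list[tuple[str, int, int]]    # (stage, n_in, n_out)
    summary: dict


def _tier_frame(rows: list[PrioritizedVariant]) -> pd.DataFrame:
    recs = []
    for pv in rows:
        chrom, pos, ref, alt = pv.key
        recs.append(
            {
                "gene": pv.gene,
                "chrom": chrom,
                "pos": pos,
                "nucleotide": f"{ref}>{alt}",
                "aa_change": pv.annotation.aa_change,
                "dbsnp": pv.annotation.dbsnp or "-",
                "maf": "" if pv.annotation.maf is None else pv.annotation.maf,
                "cadd": "" if pv.annotation.cadd is None else pv.annotation.cadd,
                "family": pv.family_id,
                "carriers": len(pv.carriers),
                "total": pv.n_affected_sequenced,
                "segregating": pv.segregating,
                "cadd_flag": pv.cadd_flag,
                "maf_flag": pv.maf_flag,
            }
        )
    df = pd.DataFrame(
        recs,
        columns=[
            "gene", "chrom", "pos", "nucleotide", "aa_change", "dbsnp", "maf",
            "cadd", "family", "carriers", "total", "segregating", "cadd_flag",
            "maf_flag",
        ],
    )
    return df.sort_values(["gene", "chrom", "pos", "family"]).reset_index(drop=True)


def summarize(bundle: RunBundle) -> dict:
    """Counts per tier; empty tiers yield zeros, never absent keys."""
    t1, t2, t3 = bundle.tier1, bundle.tier2, bundle.tier3
    t1_keys = {pv.key for pv in t1}
    by_gene: dict[str, set] = {}
    for pv in t1:
        by_gene.setdefault(pv.gene, set()).add(pv.key)
    caddvals = [pv.annotation.cadd for pv in t1 if pv.annotation.cadd is not None]
    caddvals2 = [pv.annotation.cadd for pv in t2 if pv.annotation.cadd is not None]
    return {
        "tier1_rows": len(t1),
        "tier1_unique_variants": len(t1_keys),
        "tier1_genes": len(by_gene),
        "tier1_families": len({pv.family_id for pv in t1}),
        "tier1_variants_multi_carrier": len(
            {pv.key for pv in t1 if len(pv.carriers) >= 2}
        ),
        "tier1_genes_multiple_variants": sum(1 for ks in by_gene.values() if len(ks) >= 2),
        "tier1_max_cadd": max(caddvals, default=0.0),
        "tier2_variants": len({pv.key for pv in t2}),
        "tier2_genes": len({pv.gene for pv in t2}),
        "tier2_families": len({pv.family_id for pv in t2}),
        "tier2_max_cadd": max(caddvals2, default=0.0),
        "tier3_clusters": len(t3),
        "tier3_identical_shared": sum(1 for c in t3 if c.identical_variant_shared),
        "tier3_families": len({f for c in t3 for f in c.families}),
        "n_ibd_segments": len(bundle.segments),
    }


def run(cfg: RunConfig) -> RunBundle:
    """Execute the configured stages and write the report bundle."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    log_lines: list[str] = []
    filter_log: list[tuple[str, int, int]] = []

    def log(stage: str, message: str):
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp}\t{stage}\t{message}")

    def stage_counts(stage: str, n_in: int, n_out: int):
        filter_log.append((stage, n_in, n_out))
        log(stage, f"in={n_in} out={n_out} removed={n_in - n_out}")

    pedigrees = pio.read_pedigree(cfg.ped)
    log("read_ped", f"families={len(pedigrees)}")
    variants = pio.read_variants(cfg.vcf)
    log("read_vcf", f"records={len(variants)}")
    annotations = pio.read_annotations(cfg.annotations)
    gene_list = pio.read_gene_list(cfg.gene_list)

    # QC
    n_in = len(variants)
    variants = [filter_genotypes(v, cfg.qc) for v in variants]
    stage_counts("qc_genotypes", n_in, len(variants))
    kept = filter_sites(variants, annotations, cfg.qc)
    stage_counts("qc_sites", len(variants), len(kept))
    variants = kept

    # linkage stage (or precomputed regions)
    scan: Optional[LinkageScanResults] = None
    regions: dict[str, list[pio.Region]] = {}
    if cfg.lod_regions:
        regions, _ = pio.read_lod_region_table(cfg.lod_regions)
        log("linkage", f"precomputed regions loaded for {len(regions)} families")
    elif cfg.markers and cfg.marker_genotypes:
        marker_map = pio.read_marker_map(cfg.markers)
        geno = pio.read_marker_genotypes(cfg.marker_genotypes)
        markers = [
            MarkerData(name, chrom, pos, MarkerModel(freqs), geno.get(name, {}))
            for name, chrom, pos, freqs in marker_map
        ]
        model = ParametricLinkage(pedigrees, markers, cfg.disease_model)
        scan = model.fit(cfg.theta_grid)
        scan.summary().to_csv(
            os.path.join(cfg.output_dir, "lod_table.tsv"), sep="\t", index=False
        )
        for reg in scan.lod_regions(cfg.lod_threshold):
            regions.setdefault(reg.family, []).append(
                pio.Region(reg.chrom, reg.start, reg.end, f"LOD={reg.max_lod:.2f}")
            )
        log("linkage", f"scan of {len(markers)} markers; {sum(len(v) for v in regions.values())} regions")
    else:
        log("linkage", "skipped (no marker data or precomputed regions)")

    # IBD stage
    segments: list[IBDSegment] = []
    if cfg.haplotypes:
        labels = pio.read_haplotype_labels(cfg.haplotypes)
        by_fam = {p.family_id: p for p in pedigrees}
        marker_positions = None
        if cfg.markers:
            mm = pio.read_marker_map(cfg.markers)
            marker_positions = {}
            for name, chrom, pos, _ in mm:
                marker_positions.setdefault(chrom, []).append(pos)
        for (fam, chrom), fam_labels in sorted(labels.items()):
            if fam not in by_fam:
                continue
            n = len(next(iter(fam_labels.values())))
            positions = (
                marker_positions.get(chrom, list(range(1, n + 1)))
                if marker_positions
                else list(range(1, n + 1))
            )
            sp = sharing_profile(by_fam[fam], fam_labels, chrom, positions[:n])
            segments.extend(call_segments(sp, cfg.ibd_window, cfg.ibd_threshold))
        with open(os.path.join(cfg.output_dir, "ibd_segments.bed"), "w") as fh:
            for s in segments:
                fh.write(
                    f"{s.chrom}\t{s.start_pos - 1}\t{s.end_pos}\t{s.family_id}"
                    f"\t{s.mean_sharing:.4f}\n"
                )
        log("ibd", f"segments={len(segments)}")
    else:
        log("ibd", "skipped (no haplotype labels)")

    # prioritization
    tier1 = strategy_known_genes(variants, annotations, gene_list, pedigrees, cfg.maf_known_gene)
    stage_counts("tier1", len(variants), len(tier1))
    tier2 = (
        strategy_linkage(variants, annotations, regions, pedigrees, cfg.maf_novel)
        if regions
        else []
    )
    stage_counts("tier2", len(variants), len(tier2))
    tier3 = (
        strategy_cross_family(
            variants, annotations, pedigrees, cfg.maf_novel, cfg.cadd_min,
            exclude_genes=gene_list,
        )
        if len(pedigrees) >= 2
        else []
    )
    stage_counts("tier3", len(variants), len(tier3))

    _tier_frame(tier1).to_csv(os.path.join(cfg.output_dir, "table1.tsv"), sep="\t", index=False)
    _tier_frame(tier2).to_csv(os.path.join(cfg.output_dir, "table2.tsv"), sep="\t", index=False)
    t3_rows = [
        {
            "gene": c.gene,
            "families": ",".join(sorted(c.families)),
            "n_variants": len(c.variants),
            "identical_variant_shared": c.identical_variant_shared,
        }
        for c in tier3
    ]
    pd.DataFrame(
        t3_rows, columns=["gene", "families", "n_variants", "identical_variant_shared"]
    ).to_csv(os.path.join(cfg.output_dir, "table3.tsv"), sep="\t", index=False)

    bundle = RunBundle(tier1, tier2, tier3, segments, scan, filter_log, {})
    bundle.summary = summarize(bundle)
    with open(os.path.join(cfg.output_dir, "summary.json"), "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
    log("summary", json.dumps(bundle.summary, sort_keys=True))
    with open(os.path.join(cfg.output_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return bundle
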