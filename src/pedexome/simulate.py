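"""Gene-dropping simulator for multiplex dominant-disease families.

Emulates the study design the pipeline targets: multi-generational
pedigrees segregating a rare, highly penetrant dominant variant, a
multi-allelic linkage marker panel with recombination, and an exome-style
variant table with annotation columns (population MAF, CADD, consequence,
gene).  Founders receive uniquely labelled haplotypes; each meiosis
transmits a recombinant mosaic of the parent's two label sequences, so
identity-by-descent is known exactly and every downstream stage can be
scored against simulator truth.

Defaults describe the emulated study: 23 three-generation multiplex
families rejection-sampled to >= 10 affecteds (the upper half of the
emulated 4-16 range; affecteds-only two-point LOD is bounded by
(n_affected - 1) * log10(2), so the LOD>2 tier is only robustly reachable
in the larger families), dominant penetrances (0, 1, 1) with disease
allele frequency 1e-4, microsatellite-style 10-allele markers every
~2 Mb (adjacent-marker recombination fraction 0.02), and a background of
rare-to-common exome variants whose MAF mixture deliberately straddles
the 1%/2% rarity thresholds so that filter behaviour is observable.
The planted causal variant is annotated at its anchor marker's map
position, consistent with the zero recombination between them.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import (
    write_annotations,
    write_haplotype_labels,
    write_pedigree,
    write_vcf,
)
from .linkage import MarkerData, MarkerModel
from .pedigree import Affection, Individual, Pedigree, Sex
from .variants import (
    Consequence,
    GenotypeCall,
    VariantAnnotation,
    VariantKey,
    VariantRecord,
)


@dataclass
class PedigreeTemplate:
    """Three-generation template: a founder couple, ``n_gen2`` children who
    each marry in an unrelated spouse, and ``n_gen3`` grandchildren per
    gen-2 couple."""

    n_gen2: int = 6
    n_gen3: int = 5

    def build(self, family_id: str) -> Pedigree:
        fa = Individual(f"{family_id}-F1", family_id, sex=Sex.MALE)
        mo = Individual(f"{family_id}-F2", family_id, sex=Sex.FEMALE)
        members = [fa, mo]
        for i in range(1, self.n_gen2 + 1):
            child = Individual(
                f"{family_id}-C{i}", family_id, father_id=fa.id, mother_id=mo.id, sex=Sex.MALE
            )
            spouse = Individual(f"{family_id}-S{i}", family_id, sex=Sex.FEMALE)
            members += [child, spouse]
            for j in range(1, self.n_gen3 + 1):
                members.append(
                    Individual(
                        f"{family_id}-G{i}.{j}",
                        family_id,
                        father_id=child.id,
                        mother_id=spouse.id,
                        sex=Sex.MALE if j % 2 else Sex.FEMALE,
                    )
                )
        return Pedigree(family_id, members)


@dataclass
class SimulationConfig:
    seed: int = 0
    template: PedigreeTemplate = field(default_factory=PedigreeTemplate)
    n_families: int = 23
    chrom: str = "1"
    n_markers: int = 15
    marker_spacing: int = 2_000_000
    marker_n_alleles: int = 10
    inter_marker_theta: float = 0.02
    causal_marker_index: int = 7        # marker the causal variant is fully linked to
    causal_pos_offset: int = 0          # annotated at the anchor marker's map position
    penetrances: tuple[float, float, float] = (0.0, 1.0, 1.0)
    q: float = 0.0001                   # disease allele frequency
    causal_maf: float = 0.0005          # annotated population MAF of the causal allele
    causal_cadd: float = 25.0
    n_background: int = 120
    background_common_frac: float = 0.25
    genotype_error_rate: float = 0.0
    missingness_rate: float = 0.0
    min_affected: Optional[int] = 10    # rejection-sample families to this many affecteds
    max_rejection_attempts: int = 1000

    def __post_init__(self):
        for name in (
            "inter_marker_theta",
            "q",
            "causal_maf",
            "background_common_frac",
            "genotype_error_rate",
            "missingness_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.causal_marker_index < self.n_markers:
            raise ValueError("causal_marker_index out of range")

    @property
    def marker_positions(self) -> list[int]:
        return [(i + 1) * self.marker_spacing for i in range(self.n_markers)]

    @property
    def causal_pos(self) -> int:
        return self.marker_positions[self.causal_marker_index] + self.causal_pos_offset

    @property
    def marker_freqs(self) -> tuple[float, ...]:
        k = self.marker_n_alleles
        return tuple([1.0 / k] * k)


def transmit_gamete(
    labels: np.ndarray, theta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Transmit one recombinant gamete from a parent's (2, n_markers) label
    array; returns (gamete labels, strand path).  The strand switches
    between adjacent markers with probability ``theta``."""
    n = labels.shape[1]
    strand = np.empty(n, dtype=np.int64)
    strand[0] = rng.integers(2)
    switches = rng.random(n - 1) < theta
    strand[1:] = (strand[0] + np.cumsum(switches)) % 2
    return labels[strand, np.arange(n)], strand


@dataclass
class FamilyDrop:
    """One family's gene-drop: exact founder-haplotype labels per member."""

    pedigree: Pedigree
    labels: dict[str, np.ndarray]           # individual -> (2, n_markers) labels
    founder_hap_of: dict[int, tuple[str, int]]  # label -> (founder id, strand)
    marker_alleles: dict[int, np.ndarray]   # label -> per-marker allele index
    carrier_labels: set[int] = field(default_factory=set)
    causal_copies: dict[str, int] = field(default_factory=dict)

    def marker_genotype(self, ind: str, marker: int) -> tuple[int, int]:
        l1, l2 = self.labels[ind][:, marker]
        return (int(self.marker_alleles[int(l1)][marker]), int(self.marker_alleles[int(l2)][marker]))


def gene_drop(cfg: SimulationConfig, family_id: str, rng: np.random.Generator) -> FamilyDrop:
    """Drop founder haplotypes through one pedigree with recombination."""
    ped = cfg.template.build(family_id)
    labels: dict[str, np.ndarray] = {}
    founder_hap_of: dict[int, tuple[str, int]] = {}
    marker_alleles: dict[int, np.ndarray] = {}
    next_label = 0
    for m in ped.members:
        if m.is_founder:
            pair = np.empty((2, cfg.n_markers), dtype=np.int64)
            for strand in range(2):
                pair[strand] = next_label
                founder_hap_of[next_label] = (m.id, strand)
                marker_alleles[next_label] = rng.integers(
                    cfg.marker_n_alleles, size=cfg.n_markers
                )
                next_label += 1
            labels[m.id] = pair
    # topological drop: parents always precede children in template order
    for m in ped.members:
        if m.is_founder:
            continue
        pat, _ = transmit_gamete(labels[m.father_id], cfg.inter_marker_theta, rng)
        mat, _ = transmit_gamete(labels[m.mother_id], cfg.inter_marker_theta, rng)
        labels[m.id] = np.vstack([pat, mat])
    return FamilyDrop(ped, labels, founder_hap_of, marker_alleles)


def plant_causal(cfg: SimulationConfig, drop: FamilyDrop, rng: np.random.Generator) -> FamilyDrop:
    """Place the causal allele on founder F1's first haplotype and sample
    affection from the penetrances given each member's causal-copy count.

    Other founder haplotypes carry the allele with probability ``q``, so a
    second independent origin is possible but (at the default 1e-4) rare.
    Affected individuals are marked sequenced; everyone stays genotyped.
    """
    ped = drop.pedigree
    first_founder = ped.founders[0].id
    carrier = {
        lab
        for lab, (fid, strand) in drop.founder_hap_of.items()
        if (fid == first_founder and strand == 0) or rng.random() < cfg.q
    }
    drop.carrier_labels = carrier
    f = cfg.penetrances
    for m in ped.members:
        at_causal = drop.labels[m.id][:, cfg.causal_marker_index]
        copies = int(sum(1 for lab in at_causal if int(lab) in carrier))
        drop.causal_copies[m.id] = copies
        affected = rng.random() < f[copies]
        m.affection = Affection.AFFECTED if affected else Affection.UNAFFECTED
        m.sequenced = affected
        m.genotyped = True
    return drop


def _simulate_family(cfg: SimulationConfig, family_id: str, rng: np.random.Generator) -> FamilyDrop:
    for _ in range(cfg.max_rejection_attempts):
        drop = plant_causal(cfg, gene_drop(cfg, family_id, rng), rng)
        n_aff = len(drop.pedigree.affected())
        if cfg.min_affected is None or n_aff >= cfg.min_affected:
            return drop
    raise RuntimeError(
        f"could not reach min_affected={cfg.min_affected} in "
        f"{cfg.max_rejection_attempts} attempts; template too small"
    )


@dataclass
class BackgroundVariant:
    key: VariantKey
    freq: float
    marker_index: int
    annotation: VariantAnnotation


@dataclass
class Study:
    """In-memory simulated study: the inputs every pipeline stage consumes
    plus the truth needed to score recovery."""

    cfg: SimulationConfig
    families: list[FamilyDrop]
    variants: list[VariantRecord]
    annotations: dict[VariantKey, VariantAnnotation]
    truth_causal_key: VariantKey

    @property
    def pedigrees(self) -> list[Pedigree]:
        return [f.pedigree for f in self.families]

    def marker_data(self) -> list[MarkerData]:
        """Marker panel in the form the linkage model consumes."""
        mm = MarkerModel(self.cfg.marker_freqs)
        out = []
        for i, pos in enumerate(self.cfg.marker_positions):
            genotypes = {
                fam.pedigree.family_id: {
                    m.id: fam.marker_genotype(m.id, i)
                    for m in fam.pedigree.members
                    if m.genotyped
                }
                for fam in self.families
            }
            out.append(MarkerData(f"M{i + 1}", self.cfg.chrom, pos, mm, genotypes))
        return out

    def haplotype_labels(self) -> dict[tuple[str, str], dict[str, list[tuple[int, int]]]]:
        out: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
        for fam in self.families:
            inds = {}
            for m in fam.pedigree.members:
                arr = fam.labels[m.id]
                inds[m.id] = [(int(arr[0, i]), int(arr[1, i])) for i in range(arr.shape[1])]
            out[(fam.pedigree.family_id, self.cfg.chrom)] = inds
        return out


def _background_catalog(cfg: SimulationConfig, rng: np.random.Generator) -> list[BackgroundVariant]:
    """Population catalogue of non-causal exome variants.

    MAFs are a mixture: a ``background_common_frac`` share is common
    (uniform 2-30%) and thus removed by the rarity filters, the rest
    log-uniform rare (3e-5..1e-2).  CADD is bimodal around the 15
    threshold and consequences include non-qualifying classes.
    """
    bases = "ACGT"
    out: list[BackgroundVariant] = []
    positions = set()
    for b in range(cfg.n_background):
        marker_index = int(rng.integers(cfg.n_markers))
        pos = int(
            cfg.marker_positions[marker_index]
            + rng.integers(1, cfg.marker_spacing // 2)
        )
        if pos == cfg.causal_pos or pos in positions:
            continue
        positions.add(pos)
        if rng.random() < cfg.background_common_frac:
            freq = float(rng.uniform(0.02, 0.30))
        else:
            freq = float(10 ** rng.uniform(-4.5, -2.0))
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        cadd = float(rng.uniform(0, 15)) if rng.random() < 0.5 else float(rng.uniform(15, 35))
        u = rng.random()
        consequence = (
            Consequence.MISSENSE if u < 0.8 else Consequence.SYNONYMOUS if u < 0.9 else Consequence.OTHER
        )
        key: VariantKey = (cfg.chrom, pos, ref, alt)
        out.append(
            BackgroundVariant(
                key,
                freq,
                marker_index,
                VariantAnnotation(
                    gene=f"GENE{b + 1:04d}",
                    consequence=consequence,
                    maf=freq,
                    cadd=cadd,
                    dbsnp=None,
                    map35=1.0,
                    map20=1.0,
                ),
            )
        )
    return out


def _noisy_call(
    dosage: int, cfg: SimulationConfig, rng: np.random.Generator
) -> GenotypeCall:
    if cfg.missingness_rate and rng.random() < cfg.missingness_rate:
        return GenotypeCall(None, None, depth=0, gq=0)
    if cfg.genotype_error_rate and rng.random() < cfg.genotype_error_rate:
        dosage = int(rng.choice([d for d in (0, 1, 2) if d != dosage]))
    a1, a2 = (0, 0) if dosage == 0 else (0, 1) if dosage == 1 else (1, 1)
    depth = int(rng.integers(20, 80))
    gq = int(rng.integers(60, 100))
    return GenotypeCall(a1, a2, depth=depth, gq=gq)


def simulate_study(cfg: SimulationConfig) -> Study:
    """Simulate the full study in memory; byte-reproducible given the seed."""
    rng = np.random.default_rng(cfg.seed)
    families = [
        _simulate_family(cfg, f"FAM{i + 1:02d}", rng) for i in range(cfg.n_families)
    ]
    background = _background_catalog(cfg, rng)

    causal_key: VariantKey = (cfg.chrom, cfg.causal_pos, "A", "G")
    causal_ann = VariantAnnotation(
        gene="GENE_CAUSAL",
        consequence=Consequence.MISSENSE,
        maf=cfg.causal_maf,
        cadd=cfg.causal_cadd,
        dbsnp=None,
        map35=1.0,
        map20=1.0,
        aa_change="Arg100Trp",
    )
    annotations: dict[VariantKey, VariantAnnotation] = {causal_key: causal_ann}
    calls: dict[VariantKey, dict[str, GenotypeCall]] = {causal_key: {}}

    for fam in families:
        for m in fam.pedigree.members:
            calls[causal_key][m.id] = _noisy_call(
                min(fam.causal_copies[m.id], 2), cfg, rng
            )
    for bv in background:
        annotations[bv.key] = bv.annotation
        site_calls: dict[str, GenotypeCall] = {}
        for fam in families:
            hap_carries = {
                lab: rng.random() < bv.freq for lab in fam.marker_alleles
            }
            for m in fam.pedigree.members:
                l1, l2 = fam.labels[m.id][:, bv.marker_index]
                dosage = int(hap_carries[int(l1)]) + int(hap_carries[int(l2)])
                site_calls[m.id] = _noisy_call(dosage, cfg, rng)
        calls[bv.key] = site_calls

    variants = [
        VariantRecord(
            chrom=k[0], pos=k[1], ref=k[2], alt=k[3], site_quality=8.0, calls=c
        )
        for k, c in sorted(calls.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]
    return Study(cfg, families, variants, annotations, causal_key)


def emit_study(cfg: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write a simulated study to disk in the pipeline's input formats.

    Produces VCF (exome variants), PED (+sequenced flag), the annotation
    table, founder-haplotype labels, the marker map with per-family marker
    genotypes, and a truth table of the planted causal key.
    """
    study = simulate_study(cfg)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "study.vcf"),
        "ped": os.path.join(out_dir, "study.ped"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "haplotypes": os.path.join(out_dir, "haplotypes.tsv"),
        "markers": os.path.join(out_dir, "markers.tsv"),
        "marker_genotypes": os.path.join(out_dir, "marker_genotypes.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    samples = [m.id for fam in study.families for m in fam.pedigree.members if m.genotyped]
    write_vcf(paths["vcf"], study.variants, samples)
    write_pedigree(paths["ped"], study.pedigrees)
    write_annotations(paths["annotations"], study.annotations)
    write_haplotype_labels(paths["haplotypes"], study.haplotype_labels())
    with open(paths["markers"], "w") as fh:
        fh.write("marker\tchrom\tpos\tfreqs\n")
        for md in study.marker_data():
            freqs = ",".join(repr(f) for f in md.model.freqs)
            fh.write(f"{md.marker}\t{md.chrom}\t{md.pos}\t{freqs}\n")
    with open(paths["marker_genotypes"], "w") as fh:
        fh.write("family\tindividual\tmarker\ta1\ta2\n")
        for fam in study.families:
            for m in fam.pedigree.members:
                for i in range(cfg.n_markers):
                    a1, a2 = fam.marker_genotype(m.id, i)
                    fh.write(
                        f"{fam.pedigree.family_id}\t{m.id}\tM{i + 1}\t{a1}\t{a2}\n"
                    )
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\n")
        k = study.truth_causal_key
        fh.write(f"{k[0]}\t{k[1]}\t{k[2]}\t{k[3]}\tGENE_CAUSAL\n")
    return paths
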