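"""The three variant-prioritization strategies and their report rows.

Tier 1 (known_gene): nonsynonymous/LOF variants in established disease
genes with MAF <= 2%; segregation is reported but not required.
Tier 2 (linkage_region): variants inside a family's LOD>2 region that
segregate in all sequenced affecteds, MAF <= 1%; CADD >= 15 is carried as
a ranking flag, not a hard filter.
Tier 3 (cross_family): genes with segregating, MAF <= 1%, CADD >= 15
variants in at least two distinct families.

A variant absent from the population database (``maf is None``) passes
every rarity threshold, with the missing-MAF condition recorded in
``maf_flag`` for auditability.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import Region
from .pedigree import Pedigree
from .variants import VariantAnnotation, VariantKey, VariantRecord

CADD_FLAG_MIN = 15.0
MAF_KNOWN_GENE = 0.02
MAF_NOVEL = 0.01


@dataclass
class PrioritizedVariant:
    key: VariantKey
    annotation: VariantAnnotation
    family_id: str
    strategy: str                    # known_gene | linkage_region | cross_family
    carriers: list[str]              # sequenced affecteds with >= 1 alt allele
    n_affected_sequenced: int        # sequenced affecteds with a non-missing call
    segregating: bool
    cadd_flag: bool
    maf_flag: str

    @property
    def gene(self) -> str:
        return self.annotation.gene


@dataclass
class GeneCluster:
    gene: str
    families: set[str]
    variants: set[VariantKey]
    identical_variant_shared: bool


class SegregationError(ValueError):
    pass


def _affected_calls(v: VariantRecord, p: Pedigree):
    """(carriers, evaluated) among sequenced affecteds with non-missing calls."""
    sequenced_affected = p.affected(sequenced_only=True)
    if not sequenced_affected:
        raise SegregationError(f"family {p.family_id}: no sequenced affected individuals")
    carriers, evaluated = [], []
    for m in sequenced_affected:
        call = v.calls.get(m.id)
        if call is None or call.is_missing:
            continue
        evaluated.append(m.id)
        if call.has_alt:
            carriers.append(m.id)
    return carriers, evaluated


def is_segregating(v: VariantRecord, p: Pedigree) -> bool:
    """True iff every sequenced affected with a non-missing call carries the
    alt allele (and at least one call is evaluable)."""
    carriers, evaluated = _affected_calls(v, p)
    return bool(evaluated) and len(carriers) == len(evaluated)


def _maf_passes(ann: VariantAnnotation, threshold: float) -> tuple[bool, str]:
    if ann.maf is None:
        return True, "maf_missing"
    return ann.maf <= threshold, f"maf<={threshold:g}"


def _make_pv(
    v: VariantRecord, ann: VariantAnnotation, p: Pedigree, strategy: str, maf_flag: str
) -> PrioritizedVariant:
    carriers, evaluated = _affected_calls(v, p)
    return PrioritizedVariant(
        key=v.key,
        annotation=ann,
        family_id=p.family_id,
        strategy=strategy,
        carriers=carriers,
        n_affected_sequenced=len(evaluated),
        segregating=bool(evaluated) and len(carriers) == len(evaluated),
        cadd_flag=ann.cadd is not None and ann.cadd >= CADD_FLAG_MIN,
        maf_flag=maf_flag,
    )


def strategy_known_genes(
    variants: Sequence[VariantRecord],
    annotations: dict[VariantKey, VariantAnnotation],
    gene_list: Sequence[str],
    pedigrees: Sequence[Pedigree],
    maf_max: float = MAF_KNOWN_GENE,
) -> list[PrioritizedVariant]:
    """Tier 1: rare nonsynonymous/LOF variants in known disease genes.

    One output row per (variant, family) with at least one affected
    carrier; segregation is not required — singleton carriers in a
    multiplex family may still be contributing alleles.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    genes = set(gene_list)
    out: list[PrioritizedVariant] = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None or ann.gene not in genes or not ann.is_nonsyn_lof:
            continue
        ok, flag = _maf_passes(ann, maf_max)
        if not ok:
            continue
        for p in pedigrees:
            carriers, _ = _affected_calls(v, p)
            if carriers:
                out.append(_make_pv(v, ann, p, "known_gene", flag))
    return out


def strategy_linkage(
    variants: Sequence[VariantRecord],
    annotations: dict[VariantKey, VariantAnnotation],
    regions: dict[str, list[Region]],
    pedigrees: Sequence[Pedigree],
    maf_max: float = MAF_NOVEL,
) -> list[PrioritizedVariant]:
    """Tier 2: segregating rare variants inside family-specific LOD>2 regions.

    ``regions`` maps family id to its linkage regions.  CADD >= 15 is
    annotated on each row (``cadd_flag``) but does not remove rows: low-CADD
    missense changes inside a strong linkage peak remain reportable.
    """
    by_family = {p.family_id: p for p in pedigrees}
    out: list[PrioritizedVariant] = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None or not ann.is_nonsyn_lof:
            continue
        ok, flag = _maf_passes(ann, maf_max)
        if not ok:
            continue
        for fam, fam_regions in regions.items():
            p = by_family.get(fam)
            if p is None:
                continue
            if not any(r.contains(v.chrom, v.pos) for r in fam_regions):
                continue
            carriers, _ = _affected_calls(v, p)
            if carriers and is_segregating(v, p):
                out.append(_make_pv(v, ann, p, "linkage_region", flag))
    return out


def strategy_cross_family(
    variants: Sequence[VariantRecord],
    annotations: dict[VariantKey, VariantAnnotation],
    pedigrees: Sequence[Pedigree],
    maf_max: float = MAF_NOVEL,
    cadd_min: float = CADD_FLAG_MIN,
    exclude_genes: Sequence[str] = (),
) -> list[GeneCluster]:
    """Tier 3: genes hit by qualifying variants in >= 2 distinct families.

    Qualifying means nonsynonymous/LOF, segregating in that family,
    MAF <= 1% (or absent) and CADD >= ``cadd_min`` (hard filter here).
    ``exclude_genes`` removes genes already handled by the known-gene tier
    so this tier reports novel candidates only.
    """
    if len(pedigrees) < 2:
        raise ValueError("cross-family clustering needs >= 2 families")
    excluded = set(exclude_genes)
    hits: dict[str, list[tuple[str, VariantKey]]] = {}
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None or not ann.is_nonsyn_lof or ann.gene in excluded:
            continue
        if ann.cadd is None or ann.cadd < cadd_min:
            continue
        if not _maf_passes(ann, maf_max)[0]:
            continue
        for p in pedigrees:
            carriers, _ = _affected_calls(v, p)
            if carriers and is_segregating(v, p):
                hits.setdefault(ann.gene, []).append((p.family_id, v.key))
    clusters: list[GeneCluster] = []
    for gene in sorted(hits):
        fam_vars = hits[gene]
        families = {f for f, _ in fam_vars}
        if len(families) < 2:
            continue
        keys = {k for _, k in fam_vars}
        identical = any(
            len({f for f, k in fam_vars if k == key}) >= 2 for key in keys
        )
        clusters.append(GeneCluster(gene, families, keys, identical))
    return clusters
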