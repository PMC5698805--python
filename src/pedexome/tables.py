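"""Packaged report-table fixtures: the published tier tables as a study.

The package ships the three published result tables (known-gene tier,
linkage-region tier, cross-family tier) as TSV data files, plus the
known-disease-gene list and a *synthetic* reconstruction of the three
family-specific LOD>2 regions (the underlying genotypes are unpublished,
so region bounds are chosen to span the reported variant positions).

``fixture_study`` rebuilds a minimal in-memory study from those rows:
one sibship pedigree per family with the printed number of sequenced
affecteds, and per-variant calls in which the printed carriers are
heterozygous.  Non-carrier affecteds are coded homozygous reference for
tier-1 rows (the source describes these variants as not fully
segregating) but *missing* for tier-2/3 rows, whose variants are
described as segregating in all evaluable affecteds; their true
genotypes are not recoverable from the printed tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import Region, read_gene_list
from .pedigree import Affection, Individual, Pedigree, Sex
from .variants import (
    Consequence,
    GenotypeCall,
    VariantAnnotation,
    VariantKey,
    VariantRecord,
)


def _data_path(name: str):
    return resources.files("pedexome.data").joinpath(name)


def load_table(n: int) -> pd.DataFrame:
    """Load packaged tier table 1, 2 or 3 as a DataFrame."""
    if n not in (1, 2, 3):
        raise ValueError("table number must be 1, 2 or 3")
    with _data_path(f"table{n}.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"family": str, "chrom": str})
    return df


def load_known_gene_list() -> list[str]:
    with resources.as_file(_data_path("known_ad_genes.txt")) as path:
        return read_gene_list(str(path))


def load_lod_regions() -> tuple[dict[str, list[Region]], dict[str, float]]:
    """Synthetic LOD>2 region fixture: ({family: regions}, {family: lod})."""
    with _data_path("lod_regions_synthetic.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"family": str, "chrom": str})
    regions: dict[str, list[Region]] = {}
    lods: dict[str, float] = {}
    for _, row in df.iterrows():
        fam = str(row["family"])
        regions.setdefault(fam, []).append(
            Region(str(row["chrom"]), int(row["start"]), int(row["end"]), f"LOD>{2}")
        )
        lods[fam] = float(row["lod"])
    return regions, lods


@dataclass
class FixtureStudy:
    variants: list[VariantRecord]
    annotations: dict[VariantKey, VariantAnnotation]
    pedigrees: list[Pedigree]
    gene_list: list[str]
    regions: dict[str, list[Region]]
    region_lods: dict[str, float]

    def pedigree(self, family_id: str) -> Pedigree:
        return next(p for p in self.pedigrees if p.family_id == family_id)


def _parse_alleles(nucleotide: str) -> tuple[str, str]:
    ref, alt = nucleotide.split(">")
    return ref.strip().upper(), alt.strip().upper()


def _affected_ids(family: str, n: int) -> list[str]:
    return [f"{family}-A{i}" for i in range(1, n + 1)]


def fixture_study() -> FixtureStudy:
    """Reconstruct an analyzable study from the packaged tier tables."""
    t1, t2, t3 = load_table(1), load_table(2), load_table(3)

    # family sizes: number of sequenced affecteds per family
    totals: dict[str, int] = {}
    for df, total_col in ((t1, "total"), (t2, "carriers"), (t3, "total")):
        for _, row in df.iterrows():
            fam = str(row["family"])
            totals[fam] = max(totals.get(fam, 0), int(row[total_col]))

    pedigrees = []
    for fam in sorted(totals, key=lambda f: (len(f), f)):
        father = Individual(f"{fam}-F", fam, sex=Sex.MALE, affection=Affection.UNKNOWN)
        mother = Individual(f"{fam}-M", fam, sex=Sex.FEMALE, affection=Affection.UNKNOWN)
        sibs = [
            Individual(
                iid,
                fam,
                father_id=father.id,
                mother_id=mother.id,
                affection=Affection.AFFECTED,
                sequenced=True,
            )
            for iid in _affected_ids(fam, totals[fam])
        ]
        pedigrees.append(Pedigree(fam, [father, mother, *sibs]))

    annotations: dict[VariantKey, VariantAnnotation] = {}
    calls: dict[VariantKey, dict[str, GenotypeCall]] = {}

    def add_rows(df: pd.DataFrame, noncarrier_missing: bool):
        for _, row in df.iterrows():
            fam = str(row["family"])
            ref, alt = _parse_alleles(str(row["nucleotide"]))
            key: VariantKey = (str(row["chrom"]), int(row["pos"]), ref, alt)
            cadd = row.get("cadd")
            consequence = (
                Consequence.FRAMESHIFT
                if "fs" in str(row["aa_change"])
                else Consequence.MISSENSE
            )
            annotations[key] = VariantAnnotation(
                gene=str(row["gene"]),
                consequence=consequence,
                maf=float(row["maf"]),
                cadd=None if pd.isna(cadd) or str(cadd).strip() == "-" else float(cadd),
                dbsnp=str(row["dbsnp"]),
                map35=1.0,
                map20=1.0,
                aa_change=str(row["aa_change"]),
            )
            n_car = int(row["carriers"])
            n_tot = int(row["total"]) if "total" in row.index else n_car
            fam_calls = calls.setdefault(key, {})
            for i, iid in enumerate(_affected_ids(fam, totals[fam])):
                if i < n_car:
                    fam_calls[iid] = GenotypeCall(0, 1, depth=50, gq=99)
                elif i < n_tot and not noncarrier_missing:
                    fam_calls[iid] = GenotypeCall(0, 0, depth=50, gq=99)
                # else: missing — simply omitted

    add_rows(t1, noncarrier_missing=False)
    add_rows(t2, noncarrier_missing=True)
    add_rows(t3, noncarrier_missing=True)

    variants = [
        VariantRecord(chrom=k[0], pos=k[1], ref=k[2], alt=k[3], site_quality=5.0, calls=c)
        for k, c in sorted(calls.items())
    ]
    regions, region_lods = load_lod_regions()
    return FixtureStudy(
        variants=variants,
        annotations=annotations,
        pedigrees=pedigrees,
        gene_list=load_known_gene_list(),
        regions=regions,
        region_lods=region_lods,
    )
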