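"""Readers and writers for every external representation the pipeline touches.

VCF is read through cyvcf2 and normalized into :class:`VariantRecord`
(multi-allelic sites split, indels parsimony-trimmed and, when a reference
sequence is supplied, left-aligned).  PED, BED, annotation tables,
haplotype-label tables and gene lists are small line-oriented text formats.
All internal coordinates are 1-based; BED input is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from cyvcf2 import VCF

from .pedigree import Affection, Individual, Pedigree, PedigreeError, Sex
from .variants import (
    Consequence,
    GenotypeCall,
    VariantAnnotation,
    VariantKey,
    VariantRecord,
    normalize_record,
)


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_variants(
    path: str, reference: Optional[dict[str, str]] = None
) -> list[VariantRecord]:
    """Read a VCF into normalized biallelic :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alt allele; in a
    split record, sample alleles matching a *different* alt are recoded as
    ref.  ``reference`` optionally maps chromosome name to its sequence for
    full left-alignment of indels; without it alleles are parsimony-trimmed
    only.  Site quality is taken from the VQSLOD INFO field when present.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"{path}: cannot open VCF ({exc})")
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    n_rec = 0
    try:
        for rec in vcf:
            n_rec += 1
            alts = rec.ALT or []
            depths = _format_ints(rec, "DP", len(samples))
            gqs = _format_ints(rec, "GQ", len(samples))
            vqslod = rec.INFO.get("VQSLOD")
            gts = rec.genotypes  # [a1, a2, phased]
            for alt_index, alt in enumerate(alts, start=1):
                if set(alt) - set("ACGTacgt"):
                    continue  # symbolic / spanning-deletion alleles dropped
                calls: dict[str, GenotypeCall] = {}
                for si, sample in enumerate(samples):
                    a1, a2 = gts[si][0], gts[si][1]
                    calls[sample] = GenotypeCall(
                        _recode(a1, alt_index),
                        _recode(a2, alt_index),
                        depth=depths[si],
                        gq=gqs[si],
                    )
                v = VariantRecord(
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                    ref=str(rec.REF).upper(),
                    alt=str(alt).upper(),
                    site_quality=float(vqslod) if vqslod is not None else None,
                    calls=calls,
                )
                chrom_seq = reference.get(v.chrom) if reference else None
                out.append(normalize_record(v, chrom_seq))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF near record {n_rec} ({exc})")
    return out


def _recode(allele: int, alt_index: int) -> Optional[int]:
    if allele is None or allele < 0:
        return None
    return 1 if allele == alt_index else 0


def _format_ints(rec, tag: str, n: int) -> list[int]:
    arr = rec.format(tag)
    if arr is None:
        return [0] * n
    vals = []
    for row in arr:
        try:
            x = int(row[0])
        except (TypeError, ValueError):
            x = 0
        vals.append(max(x, 0))
    return vals


def write_vcf(path: str, variants: list[VariantRecord], samples: list[str]) -> None:
    """Write records as a minimal VCF 4.2 with GT/DP/GQ and VQSLOD."""
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="Recalibration score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda r: (chroms.index(r.chrom), r.pos, r.ref, r.alt)):
            info = f"VQSLOD={v.site_quality:g}" if v.site_quality is not None else "."
            cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", info, "GT:DP:GQ"]
            for s in samples:
                call = v.calls.get(s)
                if call is None or call.is_missing:
                    gt = "./."
                    dp = call.depth if call else 0
                    gq = call.gq if call else 0
                else:
                    gt = f"{call.a1}/{call.a2}"
                    dp, gq = call.depth, call.gq
                cols.append(f"{gt}:{dp}:{gq}")
            fh.write("\t".join(cols) + "\n")


# ----------------------------------------------------------------------
# PED
# ----------------------------------------------------------------------
def read_pedigree(path: str) -> list[Pedigree]:
    """Parse a whitespace-delimited PED file into one Pedigree per family.

    Columns: family, id, father, mother, sex, phenotype, and an optional
    seventh 0/1 column flagging sequenced individuals.  Parent code ``0``
    means unknown (founder).
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected >= 6 columns, got {len(parts)}")
            fam, iid, fid, mid, sex, pheno = parts[:6]
            sequenced = len(parts) >= 7 and parts[6] == "1"
            ind = Individual(
                id=iid,
                family_id=fam,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=Sex.from_ped_code(sex),
                affection=Affection.from_ped_code(pheno),
                sequenced=sequenced,
            )
            if ind.father_id == iid or ind.mother_id == iid:
                raise ParseError(f"{path}:{ln}: individual {iid} listed as its own parent")
            rows.setdefault(fam, []).append(ind)
    pedigrees = []
    for fam, members in rows.items():
        try:
            ped = Pedigree(fam, members)
        except PedigreeError as exc:
            raise ParseError(f"{path}: {exc}")
        ids = {m.id for m in members}
        for m in members:
            for role, pid in (("father", m.father_id), ("mother", m.mother_id)):
                if pid is not None and pid not in ids:
                    raise ParseError(
                        f"{path}: family {fam}: {m.id} references absent {role} {pid!r}"
                    )
        pedigrees.append(ped)
    return pedigrees


def write_pedigree(path: str, pedigrees: list[Pedigree]) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            m.sex.to_ped_code(),
                            m.affection.to_ped_code(),
                            "1" if m.sequenced else "0",
                        ]
                    )
                    + "\n"
                )


# ----------------------------------------------------------------------
# Annotation table
# ----------------------------------------------------------------------
_ANN_REQUIRED = ("chrom", "pos", "ref", "alt", "gene")


def read_annotations(path: str) -> dict[VariantKey, VariantAnnotation]:
    """Read a tab-separated annotation table keyed by (chrom, pos, ref, alt).

    Empty maf/cadd/dbsnp cells are stored as absent (``None``), never 0.
    A duplicated key is an error unless the rows agree on every field.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _ANN_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out: dict[VariantKey, VariantAnnotation] = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]).upper(), str(row["alt"]).upper())
        ann = VariantAnnotation(
            gene=str(row["gene"]),
            consequence=Consequence.parse(_cell(row, "consequence") or "other"),
            maf=_float_cell(row, "maf"),
            cadd=_float_cell(row, "cadd"),
            dbsnp=_cell(row, "dbsnp"),
            map35=_float_cell(row, "map35", default=1.0),
            map20=_float_cell(row, "map20", default=1.0),
            aa_change=_cell(row, "aa_change") or "",
        )
        if key in out and out[key] != ann:
            raise ParseError(f"{path}: duplicate key {key} with conflicting annotations")
        out[key] = ann
    return out


def _cell(row, col) -> Optional[str]:
    if col not in row.index:
        return None
    val = row[col]
    if pd.isna(val) or str(val).strip() in ("", "-", "."):
        return None
    return str(val).strip()


def _float_cell(row, col, default=None) -> Optional[float]:
    text = _cell(row, col)
    return default if text is None else float(text)


def write_annotations(path: str, anns: dict[VariantKey, VariantAnnotation]) -> None:
    cols = ["chrom", "pos", "ref", "alt", "gene", "consequence", "maf", "cadd",
            "dbsnp", "map35", "map20", "aa_change"]
    rows = []
    for (chrom, pos, ref, alt), a in anns.items():
        rows.append(
            [chrom, pos, ref, alt, a.gene, a.consequence.value,
             "" if a.maf is None else repr(a.maf),
             "" if a.cadd is None else repr(a.cadd),
             a.dbsnp or "", repr(a.map35), repr(a.map20), a.aa_change]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Regions (BED-like)
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Region:
    """Genomic interval in internal 1-based inclusive coordinates."""

    chrom: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    label: str = ""

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def read_regions(path: str) -> list[Region]:
    """Read BED3+label (0-based half-open) and convert to 1-based inclusive."""
    regions: list[Region] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{path}:{ln}: start {start} >= end {end}")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(Region(chrom, start + 1, end, label))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def write_regions(path: str, regions: list[Region], extra: Optional[list[str]] = None) -> None:
    """Write regions as BED (0-based half-open); ``extra`` appends columns."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            cols = [r.chrom, str(r.start - 1), str(r.end), r.label]
            if extra is not None:
                cols.append(extra[i])
            fh.write("\t".join(cols) + "\n")


# ----------------------------------------------------------------------
# Marker map, marker genotypes, LOD-region tables
# ----------------------------------------------------------------------
def read_marker_map(path: str) -> list[tuple[str, str, int, tuple[float, ...]]]:
    """Read a marker map: columns marker, chrom, pos, freqs (comma-joined)."""
    out = []
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for _, row in df.iterrows():
        freqs = tuple(float(x) for x in str(row["freqs"]).split(","))
        out.append((str(row["marker"]), str(row["chrom"]), int(row["pos"]), freqs))
    return out


def read_marker_genotypes(
    path: str,
) -> dict[str, dict[str, dict[str, tuple[int, int]]]]:
    """Read per-family marker genotypes: {marker: {family: {individual: (a1, a2)}}}."""
    out: dict[str, dict[str, dict[str, tuple[int, int]]]] = {}
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "individual": str, "marker": str})
    for _, row in df.iterrows():
        out.setdefault(str(row["marker"]), {}).setdefault(str(row["family"]), {})[
            str(row["individual"])
        ] = (int(row["a1"]), int(row["a2"]))
    return out


def read_lod_region_table(path: str) -> tuple[dict[str, list["Region"]], dict[str, float]]:
    """Read a family LOD-region table (family, chrom, start, end, lod;
    1-based inclusive coordinates) into ({family: regions}, {family: lod})."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"family": str, "chrom": str})
    regions: dict[str, list[Region]] = {}
    lods: dict[str, float] = {}
    for _, row in df.iterrows():
        fam = str(row["family"])
        regions.setdefault(fam, []).append(
            Region(str(row["chrom"]), int(row["start"]), int(row["end"]), "LOD>2")
        )
        lods[fam] = float(row["lod"]) if "lod" in row.index else float("nan")
    return regions, lods


# ----------------------------------------------------------------------
# Gene lists and haplotype labels
# ----------------------------------------------------------------------
def read_gene_list(path: str) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#") and g not in genes:
                genes.append(g)
    return genes


def read_haplotype_labels(path: str) -> dict[tuple[str, str], dict[str, list[tuple[int, int]]]]:
    """Read founder-haplotype labels.

    Columns: family, individual, chrom, marker_index (0-based), label1,
    label2.  Returns ``{(family, chrom): {individual: [(label1, label2), ...]}}``
    with labels ordered by marker index.
    """
    raw: dict[tuple[str, str], dict[str, dict[int, tuple[int, int]]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{ln}: expected 6 columns")
            fam, ind, chrom, idx, l1, l2 = parts
            raw.setdefault((fam, chrom), {}).setdefault(ind, {})[int(idx)] = (int(l1), int(l2))
    out: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for key, inds in raw.items():
        out[key] = {}
        for ind, by_idx in inds.items():
            out[key][ind] = [by_idx[i] for i in sorted(by_idx)]
    return out


def write_haplotype_labels(
    path: str, labels: dict[tuple[str, str], dict[str, list[tuple[int, int]]]]
) -> None:
    with open(path, "w") as fh:
        for (fam, chrom), inds in labels.items():
            for ind, pairs in inds.items():
                for idx, (l1, l2) in enumerate(pairs):
                    fh.write(f"{fam}\t{ind}\t{chrom}\t{idx}\t{l1}\t{l2}\n")
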