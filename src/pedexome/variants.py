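"""Variant-level domain types: genotype calls, variant records, annotations.

A variant is always stored biallelic (one alt per record; multi-allelic
sites are split on read) with 1-based coordinates and parsimony-trimmed,
left-aligned alleles.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

VALID_BASES = frozenset("ACGT")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: allele pair (0=ref, 1=alt, None=missing) plus DP/GQ.

    Half-calls (exactly one missing allele) are normalized to fully missing:
    they carry no usable information for segregation logic.
    """

    a1: Optional[int]
    a2: Optional[int]
    depth: int = 0
    gq: int = 0

    def __post_init__(self):
        if self.depth < 0 or self.gq < 0:
            raise ValueError("depth and gq must be non-negative")
        if (self.a1 is None) != (self.a2 is None):
            object.__setattr__(self, "a1", None)
            object.__setattr__(self, "a2", None)

    @property
    def is_missing(self) -> bool:
        return self.a1 is None

    @property
    def has_alt(self) -> bool:
        return not self.is_missing and (self.a1 == 1 or self.a2 == 1)

    @property
    def dosage(self) -> Optional[int]:
        if self.is_missing:
            return None
        return int(self.a1 == 1) + int(self.a2 == 1)

    def unordered(self) -> Optional[tuple[int, int]]:
        if self.is_missing:
            return None
        return (min(self.a1, self.a2), max(self.a1, self.a2))

    def as_missing(self) -> "GenotypeCall":
        return GenotypeCall(None, None, self.depth, self.gq)


MISSING_CALL = GenotypeCall(None, None)


@dataclass
class VariantRecord:
    """A single biallelic site with per-individual calls.

    ``site_quality`` holds a VQSLOD-style recalibration score when the
    source VCF provides one; ``None`` means unavailable (kept by the site
    filter but flagged).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_quality: Optional[float] = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= VALID_BASES:
                raise ValueError(f"{name} allele {allele!r} is not a non-empty ACGT string")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def with_calls(self, calls: dict[str, GenotypeCall]) -> "VariantRecord":
        return replace(self, calls=dict(calls))


class Consequence(enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "Consequence":
        t = text.strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "missense_variant": cls.MISSENSE,
            "nonsynonymous": cls.MISSENSE,
            "nonsynonymous_snv": cls.MISSENSE,
            "frameshift_variant": cls.FRAMESHIFT,
            "frameshift_deletion": cls.FRAMESHIFT,
            "frameshift_insertion": cls.FRAMESHIFT,
            "stop_gained": cls.STOP_GAIN,
            "stopgain": cls.STOP_GAIN,
            "nonsense": cls.STOP_GAIN,
            "splice_site": cls.SPLICE,
            "splicing": cls.SPLICE,
            "splice_donor_variant": cls.SPLICE,
            "splice_acceptor_variant": cls.SPLICE,
            "synonymous_variant": cls.SYNONYMOUS,
        }
        if t in cls._value2member_map_:
            return cls(t)
        if t in aliases:
            return aliases[t]
        return cls.OTHER


#: consequence classes counted as nonsynonymous / loss-of-function
NONSYN_LOF = frozenset(
    {Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.STOP_GAIN, Consequence.SPLICE}
)


@dataclass
class VariantAnnotation:
    """Functional annotation consumed (not computed) by the pipeline.

    ``maf`` is a Kaviar-style global population frequency; ``None`` means the
    variant is absent from the database, which rarity filters treat as
    passing (absence is evidence of rarity) while carrying a missing-MAF
    flag into reports. ``cadd`` is phred-scaled; ``map35``/``map20`` are
    Duke-uniqueness mappability scores for 35 bp / 20 bp tracks.
    """

    gene: str
    consequence: Consequence = Consequence.OTHER
    maf: Optional[float] = None
    cadd: Optional[float] = None
    dbsnp: Optional[str] = None
    map35: float = 1.0
    map20: float = 1.0
    aa_change: str = ""

    def __post_init__(self):
        for name in ("maf", "map35", "map20"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("cadd must be >= 0")

    @property
    def maf_missing(self) -> bool:
        return self.maf is None

    @property
    def is_nonsyn_lof(self) -> bool:
        return self.consequence in NONSYN_LOF


def normalize_alleles(
    pos: int, ref: str, alt: str, chrom_seq: Optional[str] = None
) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an allele pair.

    Implements the standard variant-normalization algorithm: repeatedly
    truncate a shared terminal base (extending leftward with the reference
    base when one allele would become empty), then strip shared leading
    bases.  ``chrom_seq`` is the full chromosome sequence (1-based access
    via ``chrom_seq[pos-2]`` for the base left of ``pos``); without it only
    parsimony trimming is possible and the position cannot shift left past
    the given alleles.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (
            ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and chrom_seq is not None
            and pos > 1
        ):
            left = chrom_seq[pos - 2].upper()
            ref, alt = left + ref[:-1], left + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_record(v: VariantRecord, chrom_seq: Optional[str] = None) -> VariantRecord:
    """Return ``v`` with normalized (pos, ref, alt); calls are untouched."""
    pos, ref, alt = normalize_alleles(v.pos, v.ref, v.alt, chrom_seq)
    return replace(v, pos=pos, ref=ref, alt=alt)
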