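"""Core in-memory containers shared across the toolkit.

Coordinates are stored internally as half-open, 0-based intervals for
segments/regions; point variants carry the conventional 1-based position
used by VCF/MAF. Copy numbers may be non-integer (allele-specific absolute
calls from array or exome data are real-valued).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

CALLERS = ("strelka", "mutect", "mutect2")


@dataclass(frozen=True)
class VariantCall:
    """A somatic small variant with read-level evidence and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str  # 'SNV' | 'indel'
    consequence: str  # 'nonsynonymous' | 'synonymous'
    gene: str
    alt_reads: int
    depth: int
    vaf: float
    alt_fwd: int = 0
    alt_rev: int = 0
    mean_base_quality: float | None = None
    mean_mapq: float | None = None
    callers: frozenset = frozenset()
    oncokb_driver: bool = False
    cosmic_count: int = 0
    hotspot: bool = False
    trinucleotide: str | None = None  # 3-mer centred on the site, reference strand
    sample_id: str = ""
    case_id: str = ""
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("variant position must be >= 1")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.alt_reads > self.depth:
            raise ValueError("alt reads exceed depth")
        if self.variant_class not in ("SNV", "indel"):
            raise ValueError(f"unknown variant class {self.variant_class!r}")

    @property
    def key(self) -> tuple:
        """Identity of the genomic change, independent of the sample."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def with_(self, **kw) -> "VariantCall":
        return replace(self, **kw)


@dataclass(frozen=True)
class CNSegment:
    """One genomic segment with allele-specific absolute copy number."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    major: float
    minor: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.minor < 0 or self.major < self.minor:
            raise ValueError("require major >= minor >= 0")

    @property
    def total(self) -> float:
        return self.major + self.minor

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNProfile:
    """Segmented allele-specific absolute copy-number profile of one sample."""

    sample_id: str
    segments: list[CNSegment]
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        by_chrom: dict[str, list[CNSegment]] = {}
        for s in self.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in by_chrom.items():
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping segments on chr{chrom}")

    def by_chromosome(self) -> dict[str, list[CNSegment]]:
        out: dict[str, list[CNSegment]] = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        return out

    @property
    def total_bases(self) -> int:
        return sum(s.length for s in self.segments)

    def total_cn_at(self, chrom: str, pos: int) -> float | None:
        """Total copy number of the segment overlapping 1-based ``pos``."""
        for s in self.segments:
            if s.chrom == chrom and s.start < pos <= s.end:
                return s.total
        return None


@dataclass(frozen=True)
class SampleMeta:
    """Clinical and technical covariates of one tumour sample."""

    sample_id: str
    case_id: str
    dataset: str
    histology: str  # 'seminoma' | 'nonseminoma'
    stage: str  # 'primary' | 'metastasis'
    site: str  # 'testis' | 'extragonadal'
    platinum_response: str  # 'sensitive' | 'resistant'
    purity: float
    ploidy: float
    material: str = "fresh"  # 'fresh' | 'FFPE'
    capture: str = "exome"  # 'exome' | 'panel'
    age: float | None = None
    months_since_diagnosis: float | None = None


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used wherever a real-valued copy number or ploidy is reduced to an
    integer state, so behaviour at .5 is deterministic and documented
    (Python's built-in round() is banker's rounding).
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
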