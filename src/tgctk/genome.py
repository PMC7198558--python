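"""Autosomal genome model (build 37) with chromosome-arm boundaries.

Analyses in this package score the 22 autosomes only; the X chromosome is
excluded throughout.  Arm-level statistics are computed on 39 arms: p and q
of the non-acrocentric autosomes, and the long (q) arm only of the five
acrocentric chromosomes 13, 14, 15, 21 and 22, whose short arms carry no
scoreable euchromatin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ACROCENTRIC = {"13", "14", "15", "21", "22"}

# (chromosome, length bp, centromere bp) -- GRCh37 coordinates.
_GRCH37 = [
    ("1", 249_250_621, 125_000_000),
    ("2", 243_199_373, 93_300_000),
    ("3", 198_022_430, 91_000_000),
    ("4", 191_154_276, 50_400_000),
    ("5", 180_915_260, 48_400_000),
    ("6", 171_115_067, 61_000_000),
    ("7", 159_138_663, 59_900_000),
    ("8", 146_364_022, 45_600_000),
    ("9", 141_213_431, 49_000_000),
    ("10", 135_534_747, 40_200_000),
    ("11", 135_006_516, 53_700_000),
    ("12", 133_851_895, 35_800_000),
    ("13", 115_169_878, 17_900_000),
    ("14", 107_349_540, 17_600_000),
    ("15", 102_531_392, 19_000_000),
    ("16", 90_354_753, 36_600_000),
    ("17", 81_195_210, 24_000_000),
    ("18", 78_077_248, 17_200_000),
    ("19", 59_128_983, 26_500_000),
    ("20", 63_025_520, 27_500_000),
    ("21", 48_129_895, 13_200_000),
    ("22", 51_304_566, 14_700_000),
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int
    acrocentric: bool

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"centromere of chr{self.name} must lie strictly inside the chromosome"
            )


@dataclass(frozen=True)
class Arm:
    """One chromosome arm as a half-open interval [start, end)."""

    chrom: str
    arm: str  # 'p' or 'q'
    start: int
    end: int
    scored: bool

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeModel:
    """Karyotype table: 22 autosomes with centromere positions.

    ``arms()`` yields one entry per arm used for tiling (p and q for every
    chromosome, so segments cover the genome), with ``scored=False`` for the
    short arms of acrocentric chromosomes.  ``scored_arms()`` yields the 39
    arms entering aneuploidy scores and breakpoint-per-arm features.
    """

    def __init__(self, chromosomes: list[Chromosome]):
        if len({c.name for c in chromosomes}) != len(chromosomes):
            raise ValueError("duplicate chromosome names")
        self.chromosomes = list(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}

    @classmethod
    def default(cls) -> "GenomeModel":
        return cls(
            [
                Chromosome(name, length, cen, name in ACROCENTRIC)
                for name, length, cen in _GRCH37
            ]
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeModel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            [
                Chromosome(r.chrom, int(r.length), int(r.centromere), bool(r.acrocentric))
                for r in df.itertuples()
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "chrom": c.name,
                    "length": c.length,
                    "centromere": c.centromere,
                    "acrocentric": c.acrocentric,
                }
                for c in self.chromosomes
            ]
        ).to_csv(path, sep="\t", index=False)

    def __getitem__(self, chrom: str) -> Chromosome:
        return self._by_name[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name

    def arms(self) -> list[Arm]:
        out: list[Arm] = []
        for c in self.chromosomes:
            out.append(Arm(c.name, "p", 0, c.centromere, scored=not c.acrocentric))
            out.append(Arm(c.name, "q", c.centromere, c.length, scored=True))
        return out

    def scored_arms(self) -> list[Arm]:
        return [a for a in self.arms() if a.scored]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


def default_genome() -> GenomeModel:
    return GenomeModel.default()
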