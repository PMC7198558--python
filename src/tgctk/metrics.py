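"""Mutation burden, clonality/multiplicity, pathway sets and driver triage."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import VariantCall, round_half_up

CLONAL_MULTIPLICITY = 0.8  # multiplicity above this is called clonal

# Mutually exclusive pathway gene sets (oncogenic-mutation pathway analysis).
PATHWAYS: dict[str, frozenset[str]] = {
    "RAS/RAF": frozenset({"KRAS", "NRAS", "BRAF", "NF1"}),
    "PI3K/MTOR": frozenset(
        {"PIK3CA", "PIK3CB", "PIK3R1", "PIK3R2", "MTOR", "RICTOR", "AKT1", "PTEN"}
    ),
    "WNT/CTNNB1": frozenset({"CTNNB1", "APC", "AXIN1", "GSK3B", "FAT1"}),
    "DNA repair": frozenset(
        {
            "BRCA1", "BRCA2", "ATM", "CHEK2", "PALB2", "POLE", "TOP1",
            "BARD1", "PMS2", "MUTYH", "BAP1", "CDK12",
        }
    ),
    "chromatin modification": frozenset(
        {
            "CREBBP", "DNMT3A", "NSD1", "EP300", "KMT2A", "SMARCB1", "SMARCA4",
            "SETD2", "KMT2C", "KDM6A", "ASXL1", "ARID1A", "ARID1B", "ARID2", "PBRM1",
        }
    ),
}


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    total_per_mb: float
    nonsynonymous_per_mb: float
    denominator_bases: int


def compute_tmb(sample_calls: list[VariantCall], intersect_bases: int) -> TmbResult:
    """Mutations per megabase over the capture-intersect denominator."""
    if intersect_bases <= 0:
        raise ValueError("capture intersect size must be positive")
    mb = intersect_bases / 1e6
    total = len(sample_calls)
    nonsyn = sum(1 for c in sample_calls if c.consequence == "nonsynonymous")
    sample_id = sample_calls[0].sample_id if sample_calls else ""
    return TmbResult(sample_id, total / mb, nonsyn / mb, intersect_bases)


@dataclass(frozen=True)
class MultiplicityResult:
    variant_id: str
    multiplicity: float
    clonal: bool


def multiplicity(
    vaf: float,
    purity: float,
    local_total_cn: float,
    variant_id: str = "",
) -> MultiplicityResult:
    """Mutated allele copies per tumour cell.

        m = VAF * (purity * CN_t + 2 * (1 - purity)) / purity

    i.e. the VAF rescaled by the effective local copy number of the admixed
    specimen (tumour cells contribute CN_t alleles at purity p, contaminating
    normal cells contribute 2 at 1-p). m > 0.8 is taken as clonal.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if local_total_cn <= 0:
        raise ValueError("local total copy number must be positive")
    if not (0.0 <= vaf <= 1.0):
        raise ValueError("VAF must lie in [0, 1]")
    m = vaf * (purity * local_total_cn + 2.0 * (1.0 - purity)) / purity
    return MultiplicityResult(variant_id, m, m > CLONAL_MULTIPLICITY)


def multiplicity_for_call(
    call: VariantCall, purity: float, profile=None, ploidy: float | None = None
) -> MultiplicityResult:
    """Multiplicity using the overlapping segment's total CN.

    Where no segment overlaps the variant, the sample ploidy rounded to the
    nearest integer is used instead (logged via a warning).
    """
    cn = profile.total_cn_at(call.chrom, call.pos) if profile is not None else None
    if cn is not None and round_half_up(cn) < 1:
        # a somatic variant cannot sit on zero copies: the segment call and
        # the variant are inconsistent, so fall back to the sample ploidy
        cn = None
    if cn is None:
        if ploidy is None:
            raise ValueError("no overlapping segment and no ploidy fallback given")
        cn = max(1, round_half_up(ploidy))
        warnings.warn(
            f"{call.variant_id}: no usable overlapping CN segment; "
            f"using rounded ploidy {cn}"
        )
    return multiplicity(call.vaf, purity, cn, call.variant_id)


def assign_pathway(gene: str) -> str | None:
    """Pathway label for a gene, or None; the gene sets are disjoint."""
    g = gene.upper()
    for pathway, genes in PATHWAYS.items():
        if g in genes:
            return pathway
    return None


@dataclass(frozen=True)
class DriverTriage:
    gene: str
    category: str  # 'Definitive' | 'Likely' | 'Putative' | 'None'


def driver_triage(
    gene: str,
    q_mutsig: float | None,
    q_oncodrive: float | None,
    p_mutsig: float | None = None,
    p_oncodrive: float | None = None,
    driver_variant_fraction: float | None = None,
    recurrent_driver_centile: float | None = None,
    putative_any_of: bool = False,
) -> DriverTriage:
    """Triage a gene's driver status from externally computed statistics.

    Definitive: exome-wide significant (q < 0.05) in both algorithms.
    Likely: q < 0.05 in exactly one.
    Putative: nominal p < 0.05 in >= 1 algorithm AND >= 95th centile for
    recurrent known-driver mutation count AND > 50% of the gene's variants
    are known drivers (all three jointly by default; ``putative_any_of``
    relaxes to any-of).
    """
    if q_mutsig is None or q_oncodrive is None:
        warnings.warn(f"{gene}: missing q-value(s); gene skipped")
        return DriverTriage(gene, "None")
    sig = (q_mutsig < 0.05, q_oncodrive < 0.05)
    if all(sig):
        return DriverTriage(gene, "Definitive")
    if any(sig):
        return DriverTriage(gene, "Likely")
    nominal = any(p is not None and p < 0.05 for p in (p_mutsig, p_oncodrive))
    centile_ok = recurrent_driver_centile is not None and recurrent_driver_centile >= 95.0
    fraction_ok = driver_variant_fraction is not None and driver_variant_fraction > 0.5
    criteria = (nominal, centile_ok, fraction_ok)
    if (any(criteria) if putative_any_of else all(criteria)):
        return DriverTriage(gene, "Putative")
    return DriverTriage(gene, "None")
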