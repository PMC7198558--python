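"""Multi-caller somatic variant harmonisation and hard filtering.

The filtering cascade applied to pooled exome call sets:

1. consensus: keep calls made by >= 2 of the three callers;
2. read-evidence (oxidation-artefact style) filter: >= 1 alternate read on
   each strand, mean base quality >= 26, mean mapping quality >= 50;
3. hard filter: SNVs need >= 5 supporting reads, indels >= 10, both need
   VAF >= 0.05 -- failures can be *rescued* by knowledge-base annotation
   (OncoKB driver, COSMIC count >= 50) or by the same variant passing the
   hard filter in a second tumour from the same case;
4. dataset-artifact removal: any gene or variant at >= 10% frequency in one
   dataset but < 1% in every other dataset is dropped;
5. capture intersect: calls restricted to the intersection of the capture
   BEDs, whose size is also the TMB denominator.

All thresholds are inclusive on the stated side. Every removal is recorded
in an audit log of (variant_id, sample_id, rule) tuples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .core import VariantCall

MIN_ALT_SNV = 5
MIN_ALT_INDEL = 10
MIN_VAF = 0.05
MIN_BASE_QUALITY = 26.0
MIN_MAPQ = 50.0
ARTIFACT_HIGH_FREQ = 0.10
ARTIFACT_LOW_FREQ = 0.01
RESCUE_COSMIC_COUNT = 50


@dataclass
class FilterAudit:
    """Per-rule removal log."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, call: VariantCall, rule: str) -> None:
        self.entries.append((call.variant_id, call.sample_id, rule))

    def removed_by(self, rule: str) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[2] == rule]


def consensus_filter(
    calls: list[VariantCall], audit: FilterAudit | None = None
) -> list[VariantCall]:
    """Retain calls supported by at least two calling algorithms."""
    kept = []
    for c in calls:
        if len(c.callers) >= 2:
            kept.append(c)
        elif audit is not None:
            audit.record(c, "consensus" if c.callers else "empty_caller_set")
    return kept


def strand_quality_filter(call: VariantCall) -> tuple[bool, str | None]:
    """Read-evidence filter; returns (pass, reason-code on failure)."""
    if call.mean_base_quality is None or call.mean_mapq is None:
        return False, "missing_quality_fields"
    if call.alt_fwd < 1 or call.alt_rev < 1:
        return False, "strand_bias"
    if call.mean_base_quality < MIN_BASE_QUALITY:
        return False, "low_base_quality"
    if call.mean_mapq < MIN_MAPQ:
        return False, "low_mapping_quality"
    return True, None


def hard_filter(call: VariantCall) -> bool:
    """Read support and VAF thresholds (inclusive)."""
    if call.variant_class == "SNV":
        min_alt = MIN_ALT_SNV
    elif call.variant_class == "indel":
        min_alt = MIN_ALT_INDEL
    else:  # pragma: no cover - guarded by VariantCall validation
        raise ValueError(f"unknown variant class {call.variant_class!r}")
    return call.alt_reads >= min_alt and call.vaf >= MIN_VAF


def rescue(call: VariantCall, sibling_calls: list[VariantCall]) -> bool:
    """Recover a hard-filter failure on external or within-case evidence.

    ``sibling_calls`` are calls from *other* tumours of the same case; the
    identical variant passing the hard filter in any of them rescues this
    one.
    """
    if call.oncokb_driver or call.cosmic_count >= RESCUE_COSMIC_COUNT:
        return True
    for sib in sibling_calls:
        if sib.key == call.key and sib.sample_id != call.sample_id and hard_filter(sib):
            return True
    return False


def hard_filter_with_rescue(
    calls: list[VariantCall], audit: FilterAudit | None = None
) -> list[VariantCall]:
    """Apply the hard filter case-wise, with rescue of failures."""
    by_case: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_case.setdefault(c.case_id, []).append(c)
    kept = []
    for c in calls:
        if hard_filter(c) or rescue(c, by_case.get(c.case_id, [])):
            kept.append(c)
        elif audit is not None:
            audit.record(c, "hard_filter")
    return kept


def _entity_frequencies(
    calls: list[VariantCall], entity: str
) -> dict[str, dict[object, float]]:
    """Per-dataset mutation frequency of each gene or variant.

    Frequency = fraction of the dataset's cases carrying >= 1 call in the
    entity.
    """
    cases_per_dataset: dict[str, set[str]] = {}
    hits: dict[str, dict[object, set[str]]] = {}
    for c in calls:
        cases_per_dataset.setdefault(c.dataset, set()).add(c.case_id)
        key = c.gene if entity == "gene" else c.key
        hits.setdefault(c.dataset, {}).setdefault(key, set()).add(c.case_id)
    freqs: dict[str, dict[object, float]] = {}
    for ds, ncases in ((ds, len(cs)) for ds, cs in cases_per_dataset.items()):
        freqs[ds] = {
            key: len(carriers) / ncases for key, carriers in hits.get(ds, {}).items()
        }
    return freqs


def dataset_artifact_filter(
    calls: list[VariantCall], audit: FilterAudit | None = None
) -> tuple[list[VariantCall], set]:
    """Remove genes/variants private to a single dataset at high frequency.

    An entity is an artefact iff some dataset shows frequency >= 10% while
    every other dataset shows < 1%. Applied at both gene and variant
    granularity; the union is removed. With a single dataset the rule
    cannot fire (no-op with a warning).
    """
    datasets = {c.dataset for c in calls}
    if len(datasets) < 2:
        warnings.warn("dataset artifact filter needs >= 2 datasets; skipping")
        return list(calls), set()

    removed_entities: set = set()
    for entity in ("gene", "variant"):
        freqs = _entity_frequencies(calls, entity)
        keys = {k for per_ds in freqs.values() for k in per_ds}
        for key in keys:
            per_ds = {ds: freqs[ds].get(key, 0.0) for ds in datasets}
            for ds, f in per_ds.items():
                others = [v for d, v in per_ds.items() if d != ds]
                if f >= ARTIFACT_HIGH_FREQ and all(v < ARTIFACT_LOW_FREQ for v in others):
                    removed_entities.add((entity, key))
                    break

    removed_genes = {k for e, k in removed_entities if e == "gene"}
    removed_variants = {k for e, k in removed_entities if e == "variant"}
    kept = []
    for c in calls:
        if c.gene in removed_genes or c.key in removed_variants:
            if audit is not None:
                audit.record(c, "dataset_artifact")
        else:
            kept.append(c)
    return kept, removed_entities


# ---------------------------------------------------------------------------
# Capture intervals


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file into 0-based half-open intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            if start >= end:
                raise ValueError(f"malformed BED line {lineno}: empty interval")
            intervals.append((chrom.removeprefix("chr"), start, end))
    return intervals


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def intersect_two(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Intersection of two merged interval sets (sorted sweep)."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        ca, sa, ea = a[i]
        cb, sb, eb = b[j]
        if ca < cb:
            i += 1
            continue
        if cb < ca:
            j += 1
            continue
        lo, hi = max(sa, sb), min(ea, eb)
        if lo < hi:
            out.append((ca, lo, hi))
        if ea <= eb:
            i += 1
        else:
            j += 1
    return out


@dataclass(frozen=True)
class CaptureIntersect:
    intervals: tuple

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        p0 = pos - 1
        return any(c == chrom and s <= p0 < e for c, s, e in self.intervals)


def capture_intersect(
    bed_sets: list[list[tuple[str, int, int]]],
) -> CaptureIntersect:
    """Intersect >= 1 capture interval sets (commutative, associative)."""
    if not bed_sets:
        raise ValueError("need at least one BED interval set")
    acc = merge_intervals(bed_sets[0])
    for other in bed_sets[1:]:
        acc = intersect_two(acc, other)
    return CaptureIntersect(tuple(acc))


def restrict_to_capture(
    calls: list[VariantCall],
    intersect: CaptureIntersect,
    audit: FilterAudit | None = None,
) -> list[VariantCall]:
    kept = []
    for c in calls:
        if intersect.contains(c.chrom, c.pos):
            kept.append(c)
        elif audit is not None:
            audit.record(c, "capture_intersect")
    return kept


def _is_oxog_candidate(call: VariantCall) -> bool:
    """C>A (or its G>T read-out) SNVs, the oxidative-damage substitution."""
    return call.variant_class == "SNV" and (call.ref, call.alt) in (
        ("C", "A"),
        ("G", "T"),
    )


def apply_filters(
    calls: list[VariantCall],
    bed_sets: list[list[tuple[str, int, int]]] | None = None,
    apply_strand_quality: bool = True,
    oxog_only_ca: bool = False,
) -> tuple[list[VariantCall], FilterAudit, CaptureIntersect | None]:
    """Full harmonisation cascade; returns retained calls, audit, intersect.

    ``oxog_only_ca`` restricts the strand/quality filter to C>A candidates,
    the substitution class produced by DNA oxidation; by default it is
    applied to every variant.
    """
    audit = FilterAudit()
    kept = consensus_filter(calls, audit)
    if apply_strand_quality:
        passed = []
        for c in kept:
            if oxog_only_ca and not _is_oxog_candidate(c):
                passed.append(c)
                continue
            ok, reason = strand_quality_filter(c)
            if ok:
                passed.append(c)
            else:
                audit.record(c, f"strand_quality:{reason}")
        kept = passed
    kept = hard_filter_with_rescue(kept, audit)
    kept, _ = dataset_artifact_filter(kept, audit) if len(
        {c.dataset for c in kept}
    ) >= 2 else (kept, set())
    intersect = None
    if bed_sets:
        intersect = capture_intersect(bed_sets)
        kept = restrict_to_capture(kept, intersect, audit)
    return kept, audit, intersect
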