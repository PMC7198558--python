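"""Genome-wide and arm-level aneuploidy from absolute copy-number profiles.

The baseline state of a tumour is its ploidy rounded to the nearest
integer. A segment "shows a copy-number change" when its rounded total CN
differs from that baseline; the aneuploid genome fraction is the changed
bases over all segmented bases. Arm events are called from the
length-weighted mean log2 ratio of total CN to baseline over each of the 39
scored autosomal arms, with |log2 ratio| > 0.1 called as gain/loss; the
aneuploidy score counts non-neutral arms (0-39).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core import CNProfile, round_half_up
from .genome import GenomeModel

ARM_EVENT_THRESHOLD = 0.1
N_SCORED_ARMS = 39
_LOG2_FLOOR_CN = 0.01  # total CN clipped here before log2 (homozygous loss)


def fraction_genome_aneuploid(profile: CNProfile) -> float:
    """Fraction of segmented bases whose rounded CN deviates from ploidy."""
    if not profile.segments:
        raise ValueError("empty profile")
    baseline = round_half_up(profile.ploidy)
    changed = sum(
        s.length for s in profile.segments if round_half_up(s.total) != baseline
    )
    return changed / profile.total_bases


@dataclass(frozen=True)
class ArmEvent:
    sample_id: str
    arm: str
    status: str  # 'gain' | 'loss' | 'neutral'
    log2_ratio: float


def call_arm_events(profile: CNProfile, genome: GenomeModel) -> list[ArmEvent]:
    """Length-weighted arm-level gain/loss calls at the +/-0.1 threshold."""
    baseline = max(1, round_half_up(profile.ploidy))
    by_chrom = profile.by_chromosome()
    events = []
    for arm in genome.scored_arms():
        segs = by_chrom.get(arm.chrom, [])
        num = 0.0
        denom = 0
        for s in segs:
            ov = min(s.end, arm.end) - max(s.start, arm.start)
            if ov > 0:
                num += ov * np.log2(max(s.total, _LOG2_FLOOR_CN) / baseline)
                denom += ov
        if denom == 0:
            warnings.warn(f"{profile.sample_id}: no segments on arm {arm.name}; neutral")
            ratio = 0.0
        else:
            ratio = num / denom
        if ratio > ARM_EVENT_THRESHOLD:
            status = "gain"
        elif ratio < -ARM_EVENT_THRESHOLD:
            status = "loss"
        else:
            status = "neutral"
        events.append(ArmEvent(profile.sample_id, arm.name, status, float(ratio)))
    return events


def aneuploidy_score(arm_events: list[ArmEvent]) -> int:
    """Number of non-neutral scored arms (0-39)."""
    if len(arm_events) != N_SCORED_ARMS:
        raise ValueError(f"expected {N_SCORED_ARMS} scored arms, got {len(arm_events)}")
    return sum(1 for e in arm_events if e.status != "neutral")


def read_focal_events(path) -> pd.DataFrame:
    """Load externally called focal events (peak-based caller output TSV).

    Focal-peak discovery is out of scope here; this imports a table with at
    least (sample, peak, status) columns for downstream frequency
    comparisons alongside the arm-level calls.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "peak", "status"}
    if not required <= set(df.columns):
        raise ValueError(f"focal event table needs columns {sorted(required)}")
    return df


def event_frequency_tests(
    arm_events: dict[str, list[ArmEvent]],
    group_labels: dict[str, str],
    event_type: str | None = None,
) -> pd.DataFrame:
    """Per-arm Fisher exact comparison of event frequencies between 2 groups.

    ``arm_events`` maps sample id to its arm-event list; ``group_labels``
    maps sample id to one of exactly two group names. ``event_type``
    restricts to 'gain' or 'loss' (default: any non-neutral event). Arms
    with p < 0.05 are flagged for follow-up covariate-adjusted modelling.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    members = {g: [s for s, gg in group_labels.items() if gg == g] for g in groups}
    if any(len(m) == 0 for m in members.values()):
        raise ValueError("empty group")

    def is_event(e: ArmEvent) -> bool:
        return e.status == event_type if event_type else e.status != "neutral"

    arms = [e.arm for e in next(iter(arm_events.values()))]
    rows = []
    for i, arm in enumerate(arms):
        counts = {}
        for g in groups:
            hit = sum(1 for s in members[g] if is_event(arm_events[s][i]))
            counts[g] = (hit, len(members[g]) - hit)
        table = [list(counts[groups[0]]), list(counts[groups[1]])]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "arm": arm,
                f"events_{groups[0]}": counts[groups[0]][0],
                f"n_{groups[0]}": len(members[groups[0]]),
                f"events_{groups[1]}": counts[groups[1]][0],
                f"n_{groups[1]}": len(members[groups[1]]),
                "fisher_p": p,
                "nominal": p < 0.05,
            }
        )
    return pd.DataFrame(rows)
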