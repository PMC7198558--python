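"""Serial-tumour analysis: force-calling, sharing classes, Jaccard
concordance and minimum-event copy-number phylogenies.

Force-calling interrogates, in every tumour of a case, sites discovered in
any one tumour: >= 2 supporting reads call the variant present; < 2
supporting reads at >= 50x depth call it absent; anything else is
indeterminate. Variants present in all tumours of a case are truncal;
variants confined to the primary (resp. metastases) are primary-only
(resp. metastasis-only).

Copy-number phylogenies use a minimum-event distance between allele-specific
profiles on a shared segment grid: the least number of segmental +/-1
copy-number events (each acting on a contiguous run of segments) turning one
profile into the other, summed over alleles and chromosomes, with copy
numbers capped at 4 and an infinite distance for any transition that would
regain an allele lost to copy number zero. Trees are built by neighbour
joining, rooted via an assumed pure diploid outgroup.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from skbio import DistanceMatrix
from skbio.tree import nj

PRESENT_MIN_ALT = 2
ABSENT_MIN_DEPTH = 50
CN_CAP = 4


@dataclass(frozen=True)
class ForceCallStatus:
    variant_id: str
    sample_id: str
    alt_reads: int
    depth: int
    status: str  # 'present' | 'absent' | 'indeterminate'


def force_call(variant_id: str, sample_id: str, alt: int, depth: int) -> ForceCallStatus:
    """Presence/absence decision from filtered read counts at one site."""
    if alt < 0 or depth < 0 or alt > depth:
        raise ValueError("invalid read counts")
    if alt >= PRESENT_MIN_ALT:
        status = "present"
    elif depth >= ABSENT_MIN_DEPTH:
        status = "absent"
    else:
        status = "indeterminate"
    return ForceCallStatus(variant_id, sample_id, alt, depth, status)


def classify_sharing(
    presence: pd.DataFrame,
    stages: dict[str, str],
    strict: bool = False,
) -> pd.Series:
    """Truncal / primary-only / metastasis-only classes per variant.

    ``presence`` is a variants x samples table of force-call statuses for
    one case; ``stages`` maps sample id to 'primary' or 'metastasis'. By
    default indeterminate sites are excluded from the denominator, but a
    variant is classifiable only if at least one determinate call exists in
    each compartment; ``strict`` treats any indeterminate as unclassifiable.
    Cases with a single tumour cannot be classified (error).
    """
    samples = list(presence.columns)
    if len(samples) < 2:
        raise ValueError("sharing classification needs >= 2 tumours per case")
    primaries = [s for s in samples if stages[s] == "primary"]
    mets = [s for s in samples if stages[s] == "metastasis"]
    out = {}
    for vid, row in presence.iterrows():
        if strict and (row == "indeterminate").any():
            out[vid] = "other"
            continue
        det_p = [s for s in primaries if row[s] != "indeterminate"]
        det_m = [s for s in mets if row[s] != "indeterminate"]
        if (primaries and not det_p) or (mets and not det_m):
            out[vid] = "other"
            continue
        det = det_p + det_m
        pres = [s for s in det if row[s] == "present"]
        if not pres:
            out[vid] = "other"
        elif len(pres) == len(det):
            out[vid] = "truncal"
        elif all(s in det_p for s in pres):
            out[vid] = "primary_only"
        elif all(s in det_m for s in pres):
            out[vid] = "metastasis_only"
        else:
            out[vid] = "other"
    return pd.Series(out, name="sharing_class")


def jaccard_index(variants_a: set, variants_b: set) -> float:
    """Set concordance as a percentage: 100 |A n B| / |A u B|."""
    union = variants_a | variants_b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return 100.0 * len(variants_a & variants_b) / len(union)


# ---------------------------------------------------------------------------
# Minimum-event copy-number distance


def _allele_events(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum segmental +/-1 events turning allele profile a into b.

    With d = b - a, positive and negative parts p, n, the count is
    sum_i max(0, p_i - p_{i-1}) + max(0, n_i - n_{i-1}) with p_0 = n_0 = 0
    (the classic contiguous-run decomposition). Any position with a_i = 0
    and b_i > 0 requires regaining a lost allele: infinite distance.
    """
    a = np.minimum(np.asarray(a, dtype=int), CN_CAP)
    b = np.minimum(np.asarray(b, dtype=int), CN_CAP)
    if a.shape != b.shape:
        raise ValueError("mismatched segment grids")
    if ((a == 0) & (b > 0)).any():
        return math.inf
    d = b - a
    p = np.concatenate([[0], np.maximum(d, 0)])
    n = np.concatenate([[0], np.maximum(-d, 0)])
    return float(np.maximum(np.diff(p), 0).sum() + np.maximum(np.diff(n), 0).sum())


def cn_event_distance(
    profile_a: dict[str, dict[str, np.ndarray]],
    profile_b: dict[str, dict[str, np.ndarray]],
) -> float:
    """Directed minimum-event distance A -> B over chromosomes and alleles.

    Profiles are {chromosome: {'major': array, 'minor': array}} on a shared
    per-case segment grid (see ``to_allele_arrays``); integer copy numbers
    capped at 4.
    """
    if set(profile_a) != set(profile_b):
        raise ValueError("profiles cover different chromosomes")
    total = 0.0
    for chrom in profile_a:
        for allele in ("major", "minor"):
            total += _allele_events(profile_a[chrom][allele], profile_b[chrom][allele])
            if math.isinf(total):
                return math.inf
    return total


def to_allele_arrays(profile) -> dict[str, dict[str, np.ndarray]]:
    """Integer allele arrays (capped at 4) from a CNProfile on a shared grid."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, segs in profile.by_chromosome().items():
        out[chrom] = {
            "major": np.array([min(int(round(s.major)), CN_CAP) for s in segs]),
            "minor": np.array([min(int(round(s.minor)), CN_CAP) for s in segs]),
        }
    return out


def split_to_union_breakpoints(profiles: list) -> list:
    """Re-segment CNProfiles of one case onto their union breakpoint set."""
    from .core import CNProfile, CNSegment

    grid: dict[str, set[int]] = {}
    for p in profiles:
        for s in p.segments:
            grid.setdefault(s.chrom, set()).update((s.start, s.end))
    out = []
    for p in profiles:
        segs = []
        for chrom, chrom_segs in p.by_chromosome().items():
            cuts = sorted(grid[chrom])
            for s in chrom_segs:
                inner = [c for c in cuts if s.start < c < s.end]
                bounds = [s.start] + inner + [s.end]
                for lo, hi in zip(bounds, bounds[1:]):
                    segs.append(CNSegment(chrom, lo, hi, s.major, s.minor))
        out.append(CNProfile(p.sample_id, segs, p.purity, p.ploidy))
    return out


def event_distance_matrix(
    profiles: dict[str, dict[str, dict[str, np.ndarray]]],
    add_diploid_root: bool = True,
) -> pd.DataFrame:
    """Symmetric distance matrix, max(d(A,B), d(B,A)), optionally with a
    pure-diploid pseudo-sample (major=minor=1 everywhere) as outgroup.

    Distances involving the diploid root are directed root -> sample (the
    direction evolution ran); a tumour with lost alleles cannot reach the
    diploid state, but the reverse transition is what the root models.
    """
    profiles = dict(profiles)
    if add_diploid_root:
        template = next(iter(profiles.values()))
        profiles["diploid"] = {
            chrom: {al: np.ones_like(arr) for al, arr in alleles.items()}
            for chrom, alleles in template.items()
        }
    ids = sorted(profiles)
    D = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if add_diploid_root and "diploid" in (a, b):
                src, dst = (a, b) if a == "diploid" else (b, a)
                d = cn_event_distance(profiles[src], profiles[dst])
            else:
                d = max(
                    cn_event_distance(profiles[a], profiles[b]),
                    cn_event_distance(profiles[b], profiles[a]),
                )
            D.loc[a, b] = D.loc[b, a] = d
    return D


def build_tree(distances: pd.DataFrame, root: str = "diploid") -> str:
    """Neighbour-joining Newick tree rooted at the diploid outgroup.

    Ties are broken deterministically by processing samples in sorted-id
    order. Infinite distances (allele regain) are replaced by 1.5x the
    largest finite distance, with a warning. With < 3 taxa a trivial tree
    is emitted with a warning.
    """
    ids = sorted(distances.index)
    D = distances.loc[ids, ids].to_numpy(dtype=float)
    if np.isinf(D).any():
        finite_max = D[np.isfinite(D)].max()
        warnings.warn("infinite CN distances capped at 1.5x max finite distance")
        D = np.where(np.isinf(D), 1.5 * finite_max, D)
    if len(ids) < 3:
        warnings.warn("fewer than 3 taxa; emitting trivial tree")
        if len(ids) == 1:
            return f"({ids[0]}:0);"
        d = D[0, 1] / 2
        return f"({ids[0]}:{d},{ids[1]}:{d});"
    tree = nj(DistanceMatrix(D, ids))
    if root in ids:
        tree = tree.root_at(tree.find(root).parent)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def events_vs_time(
    event_counts: np.ndarray, months: np.ndarray
) -> tuple[float, float, float]:
    """Linear fit of CN event counts on months since diagnosis.

    Returns (slope, r_squared, p). Requires >= 3 samples.
    """
    x = np.asarray(months, dtype=float)
    y = np.asarray(event_counts, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples")
    res = linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
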