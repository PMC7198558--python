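"""Seed-reproducible synthetic TGCT-like cohorts with ground truth.

The generator emulates the statistical structure the analysis stages
assume: hyperploid segmented copy-number profiles composed from planted
copy-number signature mixtures; 96-channel SNV spectra drawn from planted
reference-signature mixtures; multi-sample cases with truncal and private
variants whose VAFs follow the multiplicity model
VAF = m*p / (p*CN_t + 2(1-p)) plus binomial read sampling; clinical
covariates with planted gene-covariate log-odds and a planted TMB shift in
platinum-resistant cases; and three-caller detection with configurable
per-caller sensitivity and false-positive rates.

Every observable links back to a TruthRecord entry (per-sample signature
exposures, per-variant sharing class and multiplicity, per-gene effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import CALLERS, CNProfile, CNSegment, SampleMeta, VariantCall
from .genome import GenomeModel
from .snv_signatures import SPECTRUM_CHANNELS

CAPTURE_START = 10_000_000
CAPTURE_WIDTH = 1_363_636  # per autosome; 22 windows ~ 30 Mb total
MIN_SEGMENT_BP = 50_000


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Generative copy-number signatures


@dataclass(frozen=True)
class CNSignatureDef:
    """One generative copy-number process.

    Arms assigned to the process receive ``Poisson(breakpoint_rate)``
    breakpoints; segment spacings follow a Dirichlet with concentration
    ``size_alpha`` (small values give one dominant segment plus focal
    fragments); segment totals deviate from sample ploidy by
    N(cn_offset_mean, cn_offset_sd); ``oscillation_prob`` arms alternate
    between two adjacent integer states; ``loh_prob`` segments lose the
    minor allele. ``focal`` processes apply the CN offset only to segments
    shorter than a fifth of the arm (high-copy inserts on a near-ploidy
    background), the generative picture of focal amplification.
    """

    name: str
    breakpoint_rate: float
    size_alpha: float
    cn_offset_mean: float
    cn_offset_sd: float
    oscillation_prob: float
    loh_prob: float
    focal: bool = False


DEFAULT_CN_SIGNATURES: tuple[CNSignatureDef, ...] = (
    # arm-level gains/losses dominated by whole-arm exchange (few breaks)
    CNSignatureDef("broad-arm", 0.4, 2.0, 0.6, 0.8, 0.0, 0.05),
    # diploid-to-single-copy changes with loss of heterozygosity
    CNSignatureDef("loh", 2.0, 1.0, -1.4, 0.3, 0.0, 0.9),
    # dense breakpoints with large copy-number excursions
    CNSignatureDef("unstable", 10.0, 1.0, 0.0, 1.6, 0.0, 0.15),
    # focal amplification: high copy states on small segments
    CNSignatureDef("focal-amp", 3.0, 0.1, 3.0, 1.0, 0.0, 0.05, focal=True),
    # chains of segments alternating between two adjacent states
    CNSignatureDef("oscillating", 3.0, 1.0, 0.5, 0.5, 0.95, 0.05),
)


def generate_cn_profile(
    exposures: np.ndarray,
    genome: GenomeModel,
    ploidy: float,
    rng: np.random.Generator,
    signatures: tuple[CNSignatureDef, ...] = DEFAULT_CN_SIGNATURES,
    noise_sd: float = 0.08,
    total_breakpoints: int | None = None,
    sample_id: str = "",
    purity: float = 1.0,
) -> CNProfile:
    """Sample one segmented profile from a signature-exposure mixture.

    Each chromosome arm is assigned to one generative signature with
    probability proportional to the exposures; segments tile every
    chromosome without gaps or overlaps. ``total_breakpoints=0`` forces a
    flat profile at exactly the given ploidy (merged to whole-chromosome
    segments).
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (len(signatures),):
        raise ValueError(
            f"exposure vector length {exposures.shape} != {len(signatures)} signatures"
        )
    if (exposures < 0).any() or abs(exposures.sum() - 1.0) > 1e-6:
        raise ValueError("exposures must be non-negative and sum to 1")

    arms = genome.arms()
    # proportional (largest-remainder) allocation of arms to signatures, so
    # per-sample event counts track the exposures; placement is random
    quotas = exposures * len(arms)
    counts = np.floor(quotas).astype(int)
    remainder = len(arms) - counts.sum()
    if remainder > 0:
        frac_order = np.argsort(-(quotas - counts))
        counts[frac_order[:remainder]] += 1
    assignment = np.repeat(np.arange(len(signatures)), counts)
    rng.shuffle(assignment)

    # per-signature breakpoint budgets proportional to exposures, placed
    # multinomially over the signature's arms: per-arm counts keep the
    # Poisson-like shape the mixture model expects, while each sample's
    # event total is set by its exposures rather than an extra noise draw
    arm_breakpoints = np.zeros(len(arms), dtype=int)
    if total_breakpoints != 0:
        for k, sig in enumerate(signatures):
            arm_idx = np.flatnonzero(assignment == k)
            if len(arm_idx) == 0:
                continue
            budget = int(round(len(arm_idx) * sig.breakpoint_rate))
            if budget > 0:
                alloc = rng.multinomial(budget, np.full(len(arm_idx), 1 / len(arm_idx)))
                arm_breakpoints[arm_idx] = np.minimum(alloc, 12)

    segments: list[CNSegment] = []
    for arm, k, b in zip(arms, assignment, arm_breakpoints):
        sig = signatures[int(k)]
        b = int(b)
        n_seg = b + 1
        spacings = rng.dirichlet(np.full(n_seg, sig.size_alpha)) * arm.length
        spacings = np.maximum(spacings, MIN_SEGMENT_BP)
        spacings *= arm.length / spacings.sum()
        bounds = arm.start + np.concatenate([[0], np.cumsum(spacings)])
        bounds = np.rint(bounds).astype(int)
        bounds[-1] = arm.end

        if total_breakpoints == 0:
            totals = np.full(n_seg, float(ploidy))
        elif n_seg >= 3 and rng.random() < sig.oscillation_prob:
            s1 = max(0, round(ploidy + rng.normal(sig.cn_offset_mean, sig.cn_offset_sd)))
            step = int(rng.choice([-1, 1]))
            s2 = s1 + step if s1 + step >= 0 else s1 + 1
            states = np.where(np.arange(n_seg) % 2 == 0, s1, s2).astype(float)
            totals = states + rng.normal(0.0, noise_sd, n_seg)
        elif sig.focal:
            offsets = rng.normal(sig.cn_offset_mean, sig.cn_offset_sd, n_seg)
            background = rng.normal(0.0, 0.3, n_seg)
            is_focal = spacings < 0.2 * arm.length
            totals = (
                ploidy
                + np.where(is_focal, offsets, background)
                + rng.normal(0.0, noise_sd, n_seg)
            )
        else:
            totals = (
                ploidy
                + rng.normal(sig.cn_offset_mean, sig.cn_offset_sd, n_seg)
                + rng.normal(0.0, noise_sd, n_seg)
            )
        totals = np.maximum(totals, 0.0)

        for i in range(n_seg):
            total = float(totals[i])
            if total_breakpoints == 0:
                minor = min(float(int(round(total)) // 2), total / 2)
            elif rng.random() < sig.loh_prob:
                minor = 0.0
            else:
                minor = float(int(round(total)) // 2)
                if minor > 0 and rng.random() < 0.25:
                    minor -= 1.0
                minor = min(minor, total / 2)
            if bounds[i] < bounds[i + 1]:
                segments.append(
                    CNSegment(arm.chrom, int(bounds[i]), int(bounds[i + 1]),
                              total - minor, minor)
                )

    # merge adjacent equal segments (only occurs for noiseless flat profiles)
    merged: list[CNSegment] = []
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if (
            merged
            and merged[-1].chrom == s.chrom
            and merged[-1].end == s.start
            and merged[-1].major == s.major
            and merged[-1].minor == s.minor
        ):
            merged[-1] = CNSegment(s.chrom, merged[-1].start, s.end, s.major, s.minor)
        else:
            merged.append(s)
    return CNProfile(sample_id, merged, purity, ploidy)


def evolve_profile(
    profile: CNProfile, n_events: int, rng: np.random.Generator, sample_id: str = ""
) -> CNProfile:
    """Derive a descendant profile by adding segmental +/-1 CN events.

    Each event adds or removes one copy of one allele over a contiguous run
    of existing segments on one chromosome; events that would drop an allele
    to zero are re-drawn, so minimum-event distances between relatives stay
    finite. The segment grid is unchanged (shared per-case breakpoints).
    """
    by_chrom = {c: list(segs) for c, segs in profile.by_chromosome().items()}
    chroms = sorted(by_chrom)
    applied = 0
    attempts = 0
    while applied < n_events and attempts < n_events * 20 + 20:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        segs = by_chrom[chrom]
        i = int(rng.integers(len(segs)))
        j = min(len(segs), i + 1 + int(rng.integers(3)))
        allele = "major" if rng.random() < 0.6 else "minor"
        delta = float(rng.choice([-1.0, 1.0]))
        new = []
        ok = True
        for s in segs[i:j]:
            major, minor = s.major, s.minor
            # an allele at integer state 0 is lost and untouchable, and no
            # event may take an allele to 0 (keeps event distances finite)
            changed = major if allele == "major" else minor
            if round(changed) < 1 or round(changed + delta) < 1 or changed + delta < 0:
                ok = False
                break
            if allele == "major":
                major += delta
            else:
                minor += delta
            if major < minor:
                ok = False
                break
            new.append(CNSegment(s.chrom, s.start, s.end, major, minor))
        if not ok:
            continue
        segs[i:j] = new
        applied += 1
    all_segs = [s for segs in by_chrom.values() for s in segs]
    return CNProfile(sample_id or profile.sample_id, all_segs, profile.purity, profile.ploidy)


# ---------------------------------------------------------------------------
# Reference SNV signatures (synthetic stand-in) and spectra


def synthetic_reference_signatures(
    n_signatures: int = 30, seed: int = 20200504
) -> pd.DataFrame:
    """Synthetic 30x96 reference-signature matrix in the COSMIC-30 layout.

    A stand-in for the COSMIC catalogue, for testing and simulation only:
    rows are sparse Dirichlet draws over the 96 channels, so distinct
    signatures are near-orthogonal. Deterministic for a given seed (the
    default is fixed so every caller sees the same matrix). Real analyses
    should load the genuine catalogue with
    :func:`tgctk.snv_signatures.read_signature_matrix`.
    """
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.full(96, 0.08), size=n_signatures)
    return pd.DataFrame(
        rows,
        index=[f"Signature {i + 1}" for i in range(n_signatures)],
        columns=list(SPECTRUM_CHANNELS),
    )


def generate_spectrum(
    mix: np.ndarray,
    n_mutations: int,
    reference: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial 96-channel draw from a signature mixture."""
    mix = np.asarray(mix, dtype=float)
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if mix.shape != (len(reference),) or abs(mix.sum() - 1.0) > 1e-6 or (mix < 0).any():
        raise ValueError("mix must be a probability vector over the reference rows")
    S = reference.to_numpy(dtype=float)
    S = S / S.sum(axis=1, keepdims=True)
    p = mix @ S
    return rng.multinomial(n_mutations, p / p.sum()).astype(float)


# ---------------------------------------------------------------------------
# Cohort configuration


@dataclass
class GeneEffect:
    gene: str
    baseline_prob: float
    log_odds: dict[str, float] = field(default_factory=dict)  # covariate -> beta


@dataclass
class CohortConfig:
    n_cases: int = 100
    seed: int = 0
    samples_per_case: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    seminoma_prev: float = 0.45
    resistant_prev: float = 0.30
    extragonadal_prev: float = 0.08
    dataset_prev: dict[str, float] = field(
        default_factory=lambda: {"ICR1": 0.2, "ICR2": 0.25, "DFCI": 0.25, "TCGA": 0.3}
    )
    purity_range: tuple[float, float] = (0.45, 0.95)
    # hypertriploid karyotypes: tight spread keeps the planted signature
    # mixture the dominant low-rank structure of the encodings
    ploidy_mean: float = 3.2
    ploidy_sd: float = 0.1
    exposure_alpha: float = 0.4  # Dirichlet concentration of CN-sig exposures
    cn_signatures: tuple[CNSignatureDef, ...] = DEFAULT_CN_SIGNATURES
    cn_noise_sd: float = 0.08
    # mutation burden (per Mb over the ~30 Mb capture intersect)
    nonsyn_tmb: float = 0.33
    resistant_tmb_shift: float = 0.35
    syn_tmb: float = 0.10
    indel_fraction: float = 0.015
    clonal_fraction: float = 0.8
    truncal_fraction: float = 0.6
    mean_depth: float = 130.0
    # SNV-signature mixtures per histology (indices into the reference rows)
    cosmic_mix: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "seminoma": {2: 0.55, 18: 0.25, 4: 0.20},
            "nonseminoma": {0: 0.35, 2: 0.40, 18: 0.25},
        }
    )
    planted_gene_effects: list[GeneEffect] = field(
        default_factory=lambda: [
            GeneEffect("KIT", 0.10, {"seminoma": 1.8, "resistant": -1.2}),
            GeneEffect("KRAS", 0.12, {"seminoma": 1.2}),
            GeneEffect("TP53", 0.05, {"resistant": 0.9}),
            GeneEffect("CTNNB1", 0.04, {"resistant": 0.7}),
        ]
    )
    caller_sensitivity: dict[str, float] = field(
        default_factory=lambda: {c: 0.95 for c in CALLERS}
    )
    caller_fpr: float = 0.05  # expected false calls per caller / true variant

    def validate(self) -> None:
        probs = [
            self.seminoma_prev,
            self.resistant_prev,
            self.extragonadal_prev,
            self.indel_fraction,
            self.clonal_fraction,
            self.truncal_fraction,
            self.caller_fpr,
            *self.samples_per_case.values(),
            *self.dataset_prev.values(),
            *self.caller_sensitivity.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("prevalence/probability outside [0, 1]")
        for dist, name in (
            (self.samples_per_case, "samples_per_case"),
            (self.dataset_prev, "dataset_prev"),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} probabilities must sum to 1")
        for eff in self.planted_gene_effects:
            if not (0.0 < eff.baseline_prob < 1.0):
                raise ConfigurationError(f"baseline prob of {eff.gene} outside (0, 1)")


@dataclass
class TruthRecord:
    exposures: pd.DataFrame  # sample_id x signature name
    variant_truth: pd.DataFrame  # variant/sample-level truth
    gene_effects: pd.DataFrame


# gene universe ------------------------------------------------------------

_NAMED_GENES = [
    "KIT", "KRAS", "NRAS", "TP53", "PTEN", "BRAF", "NF1", "PIK3CA", "PIK3CB",
    "PIK3R1", "PIK3R2", "MTOR", "RICTOR", "AKT1", "CTNNB1", "APC", "AXIN1",
    "GSK3B", "FAT1", "BRCA1", "BRCA2", "ATM", "CHEK2", "PALB2", "POLE", "TOP1",
    "BARD1", "PMS2", "MUTYH", "BAP1", "CDK12", "CREBBP", "DNMT3A", "NSD1",
    "EP300", "KMT2A", "SMARCB1", "SMARCA4", "SETD2", "KMT2C", "KDM6A", "ASXL1",
    "ARID1A", "ARID1B", "ARID2", "PBRM1", "RAC1", "CBL", "BCOR", "MDM2",
]
GENE_UNIVERSE = _NAMED_GENES + [f"G{i:03d}" for i in range(1, 151)]


def gene_loci(genome: GenomeModel) -> dict[str, tuple[str, int]]:
    """Deterministic synthetic loci inside the capture windows."""
    chroms = [c.name for c in genome.chromosomes]
    loci = {}
    for i, gene in enumerate(GENE_UNIVERSE):
        chrom = chroms[i % len(chroms)]
        start = CAPTURE_START + (i // len(chroms)) * 120_000 + 5_000
        loci[gene] = (chrom, start)
    return loci


def capture_intervals(
    genome: GenomeModel, pad: int = 0
) -> list[tuple[str, int, int]]:
    """One ~1.36 Mb capture window per autosome (~30 Mb in total)."""
    return [
        (c.name, CAPTURE_START - pad, CAPTURE_START + CAPTURE_WIDTH + pad)
        for c in genome.chromosomes
    ]


def simulate_caller_calls(
    variants: list[VariantCall],
    sensitivities: dict[str, float],
    fpr: float,
    rng: np.random.Generator,
    genome: GenomeModel | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Assign caller sets to true variants and inject false positives.

    Each true variant is detected independently by each of the three named
    callers at its sensitivity. Per caller, Poisson(fpr x n_true) false
    positives are injected as low-evidence single-caller SNV calls.
    Returns (true variants with caller sets, false-positive calls).
    """
    if set(sensitivities) != set(CALLERS):
        raise ValueError(f"sensitivities required for callers {CALLERS}")
    genome = genome or GenomeModel.default()
    with_callers = []
    for v in variants:
        callers = frozenset(c for c in CALLERS if rng.random() < sensitivities[c])
        with_callers.append(v.with_(callers=callers))

    fps: list[VariantCall] = []
    by_sample: dict[str, VariantCall] = {v.sample_id: v for v in variants}
    for caller in CALLERS:
        n_fp = rng.poisson(fpr * len(variants))
        for _ in range(n_fp):
            if not by_sample:
                break
            template = by_sample[
                sorted(by_sample)[int(rng.integers(len(by_sample)))]
            ]
            chrom = genome.chromosomes[int(rng.integers(22))].name
            pos = CAPTURE_START + int(rng.integers(CAPTURE_WIDTH))
            depth = max(10, int(rng.poisson(80)))
            alt = min(depth, 3)
            fps.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref="C",
                    alt="A",
                    variant_class="SNV",
                    consequence="synonymous",
                    gene=f"G{int(rng.integers(1, 151)):03d}",
                    alt_reads=alt,
                    depth=depth,
                    vaf=alt / depth,
                    alt_fwd=alt,
                    alt_rev=0,
                    mean_base_quality=24.0,
                    mean_mapq=55.0,
                    callers=frozenset({caller}),
                    trinucleotide="ACA",
                    sample_id=template.sample_id,
                    case_id=template.case_id,
                    dataset=template.dataset,
                )
            )
    return with_callers, fps


# ---------------------------------------------------------------------------
# Full cohort generation


def _draw_category(rng, dist: dict):
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _channel_to_variant_fields(channel: str) -> tuple[str, str, str]:
    five, rest = channel.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return ref, alt, f"{five}{ref}{three}"


def generate_cohort(
    config: CohortConfig,
    genome: GenomeModel | None = None,
    reference_signatures: pd.DataFrame | None = None,
) -> tuple[list[SampleMeta], list[VariantCall], dict[str, CNProfile], TruthRecord]:
    """Generate a full synthetic cohort with ground-truth labels.

    Deterministic for a fixed config and seed. Metastatic samples of a case
    inherit the primary's truncal variants and descend from it (two or more
    metastases share a common metastatic precursor profile).
    """
    config.validate()
    genome = genome or GenomeModel.default()
    reference = (
        reference_signatures
        if reference_signatures is not None
        else synthetic_reference_signatures()
    )
    rng = np.random.default_rng(config.seed)
    loci = gene_loci(genome)
    sig_names = [s.name for s in config.cn_signatures]
    n_sigs = len(sig_names)
    capture_mb = len(genome.chromosomes) * CAPTURE_WIDTH / 1e6
    planted_genes = {e.gene for e in config.planted_gene_effects}
    background_genes = [g for g in GENE_UNIVERSE if g not in planted_genes]

    # per-histology channel distributions
    S = reference.to_numpy(dtype=float)
    S = S / S.sum(axis=1, keepdims=True)
    channel_p = {}
    for hist, mixdict in config.cosmic_mix.items():
        mix = np.zeros(len(reference))
        for idx, w in mixdict.items():
            mix[idx] = w
        mix /= mix.sum()
        channel_p[hist] = mix @ S

    samples: list[SampleMeta] = []
    variants: list[VariantCall] = []
    profiles: dict[str, CNProfile] = {}
    exposure_rows = {}
    truth_rows = []

    def draw_alleles(histology: str, is_indel: bool) -> tuple[str, str, str | None]:
        if is_indel:
            return "A", "AT", None
        channel = SPECTRUM_CHANNELS[int(rng.choice(96, p=channel_p[histology]))]
        return _channel_to_variant_fields(channel)

    def make_variant(
        meta: SampleMeta, profile: CNProfile, gene: str, pos: int,
        is_indel: bool, is_nonsyn: bool, clonal: bool, driver: bool,
        sharing: str, vid_suffix: str,
        alleles: tuple[str, str, str | None] | None = None,
    ) -> VariantCall | None:
        chrom = loci[gene][0]
        cn = profile.total_cn_at(chrom, pos)
        if cn is None or round(cn) < 1:
            # a variant cannot sit on zero copies: place it at ploidy instead
            cn = max(1.0, round(profile.ploidy))
        if clonal:
            m = 2.0 if (cn >= 3 and rng.random() < 0.3) else 1.0
        else:
            m = float(rng.uniform(0.2, 0.6))
        p = meta.purity
        vaf_true = float(np.clip(m * p / (p * cn + 2 * (1 - p)), 0.005, 0.95))
        depth = max(10, int(rng.poisson(config.mean_depth)))
        alt = int(rng.binomial(depth, vaf_true))
        # shared (truncal/planted) variants carry identical alleles everywhere
        ref, alt_allele, tri = alleles or draw_alleles(meta.histology, is_indel)
        alt_fwd = int(rng.binomial(alt, 0.5)) if alt else 0
        call = VariantCall(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt_allele,
            variant_class="indel" if is_indel else "SNV",
            consequence="nonsynonymous" if is_nonsyn else "synonymous",
            gene=gene,
            alt_reads=alt,
            depth=depth,
            vaf=alt / depth,
            alt_fwd=alt_fwd,
            alt_rev=alt - alt_fwd,
            mean_base_quality=float(np.clip(rng.normal(32, 2), 20, 40)),
            mean_mapq=float(np.clip(rng.normal(58, 4), 30, 60)),
            oncokb_driver=driver,
            cosmic_count=int(rng.geometric(0.3)) * (5 if driver else 1),
            trinucleotide=tri,
            sample_id=meta.sample_id,
            case_id=meta.case_id,
            dataset=meta.dataset,
        )
        truth_rows.append(
            {
                "variant_id": call.variant_id,
                "case_id": meta.case_id,
                "sample_id": meta.sample_id,
                "sharing_class": sharing,
                "multiplicity": m,
                "clonal": clonal,
                "vaf_true": vaf_true,
                "suffix": vid_suffix,
            }
        )
        return call

    for i in range(config.n_cases):
        case_id = f"C{i:04d}"
        histology = "seminoma" if rng.random() < config.seminoma_prev else "nonseminoma"
        resistant = rng.random() < config.resistant_prev
        site = "extragonadal" if rng.random() < config.extragonadal_prev else "testis"
        dataset = _draw_category(rng, config.dataset_prev)
        n_samples = _draw_category(rng, config.samples_per_case)
        ploidy = float(np.clip(rng.normal(config.ploidy_mean, config.ploidy_sd), 2.6, 4.0))
        exposures = rng.dirichlet(np.full(n_sigs, config.exposure_alpha))
        age = float(np.clip(rng.normal(32, 6), 18, 60))
        covariate_values = {
            "seminoma": float(histology == "seminoma"),
            "resistant": float(resistant),
            "extragonadal": float(site == "extragonadal"),
        }

        metas: list[SampleMeta] = []
        for j in range(n_samples):
            stage = "primary" if j == 0 else "metastasis"
            months = None if j == 0 else float(rng.uniform(6, 48))
            metas.append(
                SampleMeta(
                    sample_id=f"{case_id}_T{j}",
                    case_id=case_id,
                    dataset=dataset,
                    histology=histology,
                    stage=stage,
                    site=site,
                    platinum_response="resistant" if resistant else "sensitive",
                    purity=float(rng.uniform(*config.purity_range)),
                    ploidy=ploidy,
                    material="FFPE" if dataset in ("ICR2", "DFCI") else "fresh",
                    capture="exome",
                    age=age,
                    months_since_diagnosis=months,
                )
            )
        samples.extend(metas)

        # copy-number profiles: primary, then descendants via added events
        primary_profile = generate_cn_profile(
            exposures, genome, ploidy, rng,
            signatures=config.cn_signatures, noise_sd=config.cn_noise_sd,
            sample_id=metas[0].sample_id, purity=metas[0].purity,
        )
        profiles[metas[0].sample_id] = primary_profile
        exposure_rows[metas[0].sample_id] = exposures
        met_parent = primary_profile
        if n_samples >= 3:  # shared metastatic precursor
            met_parent = evolve_profile(primary_profile, int(rng.poisson(6)), rng)
        for meta in metas[1:]:
            n_ev = max(1, int(rng.poisson(0.4 * (meta.months_since_diagnosis or 12))))
            child = evolve_profile(met_parent, n_ev, rng, sample_id=meta.sample_id)
            child.purity = meta.purity
            profiles[meta.sample_id] = child
            exposure_rows[meta.sample_id] = exposures

        # small-variant burden
        nonsyn_rate = config.nonsyn_tmb + (config.resistant_tmb_shift if resistant else 0)
        per_sample_total = (nonsyn_rate + config.syn_tmb) * capture_mb
        nonsyn_frac = nonsyn_rate / (nonsyn_rate + config.syn_tmb)

        used_pos: set[tuple[str, int]] = set()

        def draw_site() -> tuple[str, int]:
            for _ in range(50):
                gene = background_genes[int(rng.integers(len(background_genes)))]
                pos = loci[gene][1] + int(rng.integers(10_000)) + 1
                if (gene, pos) not in used_pos:
                    used_pos.add((gene, pos))
                    return gene, pos
            raise RuntimeError("could not find a free site")

        n_truncal = rng.poisson(config.truncal_fraction * per_sample_total)
        truncal_sites = [draw_site() for _ in range(n_truncal)]
        truncal_kinds = []
        for _ in range(n_truncal):
            is_indel = rng.random() < config.indel_fraction
            truncal_kinds.append(
                (
                    is_indel,
                    rng.random() < nonsyn_frac,
                    rng.random() < config.clonal_fraction,
                    draw_alleles(histology, is_indel),
                )
            )
        for meta in metas:
            profile = profiles[meta.sample_id]
            for (gene, pos), (is_indel, is_nonsyn, clonal, alleles) in zip(
                truncal_sites, truncal_kinds
            ):
                v = make_variant(
                    meta, profile, gene, pos, is_indel, is_nonsyn, clonal,
                    driver=False,
                    sharing="truncal" if n_samples > 1 else "single_sample",
                    vid_suffix="truncal", alleles=alleles,
                )
                variants.append(v)
            n_private = rng.poisson((1 - config.truncal_fraction) * per_sample_total)
            for _ in range(n_private):
                gene, pos = draw_site()
                sharing = (
                    "single_sample"
                    if n_samples == 1
                    else ("primary_only" if meta.stage == "primary" else "metastasis_only")
                )
                variants.append(
                    make_variant(
                        meta, profile, gene, pos,
                        rng.random() < config.indel_fraction,
                        rng.random() < nonsyn_frac,
                        rng.random() < config.clonal_fraction,
                        driver=False, sharing=sharing, vid_suffix="private",
                    )
                )

        # planted driver-gene mutations (case-level, truncal, clonal)
        for eff in config.planted_gene_effects:
            eta = logit(eff.baseline_prob) + sum(
                beta * covariate_values[cov] for cov, beta in eff.log_odds.items()
            )
            if rng.random() < expit(eta):
                pos = loci[eff.gene][1] + int(rng.integers(10_000)) + 1
                alleles = draw_alleles(histology, False)
                driver = rng.random() < 0.7
                for meta in metas:
                    variants.append(
                        make_variant(
                            meta, profiles[meta.sample_id], eff.gene, pos,
                            is_indel=False, is_nonsyn=True, clonal=True,
                            driver=driver,
                            sharing="truncal" if n_samples > 1 else "single_sample",
                            vid_suffix="planted", alleles=alleles,
                        )
                    )

    truth = TruthRecord(
        exposures=pd.DataFrame.from_dict(
            exposure_rows, orient="index", columns=sig_names
        ),
        variant_truth=pd.DataFrame(truth_rows),
        gene_effects=pd.DataFrame(
            [
                {"gene": e.gene, "baseline_prob": e.baseline_prob,
                 "covariate": cov, "log_odds": beta}
                for e in config.planted_gene_effects
                for cov, beta in e.log_odds.items()
            ]
        ),
    )
    return samples, variants, profiles, truth


def signature_reference_profiles(
    model,
    genome: GenomeModel,
    signatures: tuple[CNSignatureDef, ...] = DEFAULT_CN_SIGNATURES,
    n_samples: int = 40,
    seed: int = 0,
    ploidy_mean: float = 3.2,
    ploidy_sd: float = 0.1,
    noise_sd: float = 0.08,
) -> np.ndarray:
    """Empirical 36-component profile of each pure generative signature.

    Generates ``n_samples`` single-signature profiles per signature, encodes
    them under ``model`` and returns the mean encoding per signature,
    normalised to sum one -- the ground-truth signature-by-component matrix
    in encoding space, used to match NMF factors back to the planted
    processes.
    """
    from .cn_features import encode_sample, extract_features

    rng = np.random.default_rng(seed)
    rows = []
    for k in range(len(signatures)):
        e = np.zeros(len(signatures))
        e[k] = 1.0
        encs = []
        for _ in range(n_samples):
            ploidy = float(np.clip(rng.normal(ploidy_mean, ploidy_sd), 2.6, 4.0))
            prof = generate_cn_profile(
                e, genome, ploidy, rng, signatures=signatures, noise_sd=noise_sd
            )
            encs.append(encode_sample(extract_features(prof, genome), model).vector)
        mean = np.mean(encs, axis=0)
        rows.append(mean / mean.sum())
    return np.array(rows)
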