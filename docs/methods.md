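# Methods

`tgctk` reimplements, as a tested library, the desk-scale computational
stages of a multi-cohort testicular germ-cell tumour (TGCT) genomics
analysis: somatic variant harmonisation and hard filtering, mutation burden
and clonality metrics, reference SNV-signature fitting, copy-number (CN)
feature extraction and signature deconvolution, aneuploidy scoring,
covariate-adjusted association testing, and longitudinal force-calling and
CN phylogenetics. Because the real cohorts are controlled-access, every
stage is exercised against a synthetic cohort generator that plants known
signal and records the ground truth, so the pipeline's ability to recover
parameters is itself under test.

## Genome model

Build-37 autosomes only; the X chromosome is excluded from every analysis.
Arm-level statistics score 39 arms: p and q of the non-acrocentric
autosomes plus the q arms of the five acrocentric chromosomes (13, 14, 15,
21, 22), whose short arms carry no scoreable sequence. The karyotype table
(lengths, centromeres) ships with the package and can be replaced by a TSV.
Real-valued copy numbers are reduced to integer states by round-half-away
(documented because Python's built-in rounds half to even).

## Variant harmonisation and filtering

The cascade applied to pooled multi-caller exome call sets, all thresholds
inclusive on the stated side:

1. **Consensus** — keep calls made by ≥ 2 of {strelka, mutect, mutect2}.
2. **Read evidence** (oxidation-artefact style) — ≥ 1 alternate read per
   strand, mean base quality ≥ 26, mean mapping quality ≥ 50. Applied to
   all variants by default; a flag restricts it to C>A candidates, since
   the oxidative artefact is strand-specific C>A.
3. **Hard filter with rescue** — SNVs need ≥ 5 alternate reads, indels
   ≥ 10, both need VAF ≥ 0.05. A failure is rescued by knowledge-base
   evidence (curated driver annotation, or a somatic-catalogue count ≥ 50)
   or by the identical variant passing the hard filter in another tumour of
   the same case; a rescued variant re-enters every tumour's call set.
   Rescue is evaluated only after hard-filter failure; consensus failures
   are not rescuable.
4. **Dataset-artifact removal** — any gene *or* exact variant at ≥ 10%
   frequency in one dataset while < 1% in every other dataset is removed
   (union of both granularities). The rule presumes datasets large enough
   that one carrier stays below 10%; with fewer than ~10 cases per dataset
   it degenerates and removes everything, so it no-ops (with a warning)
   when fewer than two datasets are present and should be interpreted with
   care on small cohorts.
5. **Capture intersect** — calls restricted to the intersection of the
   capture BEDs; the intersect size (bases) is the TMB denominator.
   Intervals are half-open and 0-based internally; BED I/O is native BED,
   variant positions 1-based.

Every removal is written to an audit log `(variant, sample, rule)`.

## Mutation metrics

**TMB** = mutations / intersect megabases, total and nonsynonymous-only.

**Multiplicity** (mutated allele copies per tumour cell):
`m = VAF · (p·CN_t + 2(1−p)) / p` with purity `p` and local total copy
number `CN_t` from the overlapping segment; `m > 0.8` is called clonal.
Where no segment overlaps — or the overlapping segment rounds to zero
copies, which is inconsistent with a somatic variant at that locus — the
sample ploidy rounded to the nearest integer is substituted and a warning
logged. The formula is a strategy hook (`multiplicity()` is pure), so an
alternative clonality model can be swapped in.

**Pathways**: mutually exclusive gene sets (RAS/RAF, PI3K/MTOR,
WNT/CTNNB1, DNA repair, chromatin modification) assigned by exact gene
match.

**Driver triage** consumes externally computed per-gene statistics (the
significance algorithms themselves are out of scope): *Definitive* = q <
0.05 in both algorithms; *Likely* = q < 0.05 in exactly one; *Putative* =
nominal p < 0.05 in ≥ 1 algorithm AND ≥ 95th centile of recurrent
known-driver mutation count AND > 50% known-driver variants — all three
jointly by default (a flag relaxes to any-of).

## SNV signatures

Spectra are 96-channel trinucleotide counts in the pyrimidine-reference
convention, channel order `C>A, C>G, C>T, T>A, T>C, T>G` × 16 contexts
(5' base, then 3' base, alphabetical). Purine-reference substitutions are
reverse-complemented before binning; contexts containing N are skipped and
counted.

Fitting decomposes a normalised spectrum into a non-negative combination of
reference signatures by iterative forward selection: at each step the
signature whose addition most reduces the sum-of-squares error is added and
all selected weights are refit by non-negative least squares; selection
stops when the relative improvement falls below 1e-4. Weights below 0.06
(the minimum-weight convention of the standard fitting tool) are zeroed and
the survivors refit; weights plus the unexplained residual are normalised
to sum to one. Exposures are invariant to scaling the input spectrum.
Exome/genome trinucleotide renormalisation is off by default.

Group-level analysis sums spectra within groups before fitting; individual
samples are fit only at ≥ 50 SNVs, below which single-sample fits are
unstable.

The package does not bundle the COSMIC catalogue. `read_signature_matrix`
loads a real catalogue TSV in either orientation;
`synthetic_reference_signatures` generates a clearly-labelled synthetic
stand-in (sparse Dirichlet rows, fixed seed) used by the tests, the
examples and the acceptance script, where only format and recovery
behaviour matter, not the biological identity of the signatures.

## Copy-number features and encoding

Six per-sample feature distributions from the segmented absolute CN
profile: (i) segment size (Mb); (ii) breakpoint count per 10 Mb window —
non-overlapping tiles from the chromosome start (a deterministic special
case of sliding windows; the stride is configurable); (iii) change-point =
|ΔCN| between adjacent segments (non-integer CN used throughout); (iv)
segment total CN; (v) breakpoint count per chromosome arm; (vi) lengths (in
segments, ≥ 3) of maximal chains alternating between two integer-rounded CN
states, where overlapping chains may share boundary segments.

A *breakpoint* is a junction whose integer-rounded total CN differs across
it. Junctions exactly at the centromere are excluded from features
(ii), (iii), (v) and chain scanning: no array probes span the centromere,
so a junction placed exactly there is a segmentation artifact rather than a
CN event. Feature (v) bins over all 44 tiled arms so that the per-arm and
per-window breakpoint totals agree exactly; the 39-arm restriction applies
only to the aneuploidy score.

Features i/iii/iv are modelled by Gaussian mixtures (EM via scikit-learn),
ii/v/vi by Poisson mixtures (EM implemented here). Component counts default
to 10+3+7+8+5+3 = 36 and are configurable; a BIC selector is provided for
the Gaussian features. Each sample becomes a 36-vector by summing, over its
observations of each feature, the posterior probability of each observation
under that feature's components; each feature block therefore sums to its
observation count (invariant, enforced to 1e-6). Observations with zero
density under every component receive a uniform posterior with a warning.
Samples with purity < 0.40 are excluded before encoding.

## Copy-number signatures (NMF)

The patients × 36 matrix is factorised V ≈ E·W by NMF with
Kullback–Leibler multiplicative updates (best of `n_restarts` random
starts, deterministic given the seed); exposures are row-normalised after
fitting. A Frobenius objective is available and uses coordinate descent
(first restart SVD-initialised), because multiplicative updates converge
too slowly to certify exact factorisations.

**Rank selection** computes four measures per candidate rank — cophenetic
correlation and dispersion of the consensus matrix (consensus over NMF
restarts, samples clustered by dominant exposure), mean silhouette of the
consensus clusters, and residual sum of squares — and calibrates them
against two nulls:

* consensus measures against column-permuted copies of the matrix (which
  destroy between-sample structure);
* the RSS improvement of rank r over r−1 against a **Poisson parametric
  bootstrap**: data resampled as Poisson noise around the rank-(r−1)
  reconstruction. The encoding entries are sums of posterior probabilities
  of counted events, so Poisson is the natural noise model, and this puts
  the "is one more signature justified?" test at the correct residual
  scale. A fully permuted null cannot do this: it destroys *all* structure,
  leaving so much residual variance that fitting noise improves its RSS
  more than the smallest real component improves the observed fit.

The observed RSS improvement is computed with exactly the restart budget
used on the bootstrap replicates — exchangeability between observed and
null statistics; computing the observed statistic from more deeply
optimised fits biases the test toward accepting spurious components.

The chosen rank is the largest r such that the bootstrap supports the RSS
improvement at every rank ≤ r (sequential forward stopping). The consensus
measures and their permutation nulls are reported as diagnostics but do not
gate the choice: column-permuted data can cluster *more* stably than real
mixed-membership cohorts, so consensus stability discriminates unreliably
in both directions. All raw measures and both nulls are returned so users
can apply their own rule. If no rank qualifies the survey reports
"no structure". As a sequential 95th-percentile test the procedure retains
a ~5–10% chance per survey of accepting one spurious extra component on
marginal data; recovery claims are therefore stated over seed ensembles.

**Matching**: recovered signature weight rows are matched one-to-one to a
reference weight matrix by Hungarian assignment maximising total Pearson
correlation (greedy matching can mis-pair correlated signatures);
zero-variance rows are skipped. **Presence** = fraction of samples with
row-normalised exposure strictly above 0.05 (normalisation before
thresholding).

## Aneuploidy

Baseline = ploidy rounded to the nearest integer. Fraction of genome
aneuploid = bases in segments whose rounded total CN differs from baseline,
over all segmented bases. Arm events come from the length-weighted mean of
log2(total CN / baseline) per scored arm (total CN floored at 0.01 before
the log), called gain/loss at strictly > |0.1|, neutral otherwise; arms
without segments are neutral with a warning. The aneuploidy score counts
non-neutral arms (0–39). This documented arm-caller replaces an external
peak-calling tool whose arm outputs used the same ±0.1 presence threshold;
it is validated on synthetic whole-arm events. The ploidy-corrected (rather
than relative) log2 scale is chosen to match the baseline convention of the
genome-fraction metric. Per-arm group comparisons use two-sided Fisher
exact tests, with nominal hits (p < 0.05) forwarded to covariate-adjusted
logistic modelling.

## Association machinery

Logistic (binomial/logit, IRLS) and linear models via statsmodels, with:
complete-case handling (dropped rows counted); separation flagging at
|log-odds| > 15 rather than silent reporting; backward stepwise elimination
dropping the least-significant Wald term until all remaining terms pass
alpha, with protected terms (the exposure of interest) never removed —
protection is on by default in the examples because an unprotected exposure
could eliminate itself; likelihood-ratio tests (chi-squared on 2·ΔlogLik)
for nested models; permutation linear models with
p = (1 + #{perm ≥ obs}) / (1 + n_perm); unpaired two-sided Wilcoxon
rank-sum tests with Benjamini–Hochberg adjustment (the groups compared are
independent samples, so the rank-sum rather than the signed-rank variant is
correct); and Pearson correlations with t-transform p-values.

## Longitudinal analysis

**Force-calling**: a site discovered in any tumour of a case is
interrogated in all of them using reads passing unique-pair, base quality
≥ 20, read quality ≥ 5 filters. Present = ≥ 2 supporting reads; absent =
< 2 supporting reads at ≥ 50× depth; otherwise indeterminate. **Sharing**:
truncal = present in all tumours; primary-only / metastasis-only = confined
to that compartment. Indeterminate calls are excluded from the denominator
by default, but a variant is classifiable only with at least one
determinate call per compartment; strict mode treats any indeterminate as
unclassifiable. **Jaccard** concordance is reported as a percentage,
100·|A∩B|/|A∪B|, defined as 0 for two empty sets.

**Minimum-event CN distance**: profiles of one case are placed on their
union breakpoint grid (`split_to_union_breakpoints`); per chromosome and
allele (major/minor, integer, capped at 4), the distance is the minimum
number of segmental ±1 events (each acting on a contiguous run) turning one
profile into the other — computed in closed form as the total variation of
the positive and negative parts of the difference profile, which equals
breadth-first search over the event graph (verified exhaustively for all
profiles of length ≤ 5). An allele lost to copy 0 cannot be regained:
such transitions get infinite distance. This is a documented simplification
of the full finite-state-transducer distance, preserving its zero-loss
irreversibility. Sample-pair distances are symmetrised as
max(d(A,B), d(B,A)); distances to the pure-diploid root are directed
root → sample, the direction evolution ran. Any residual infinite entry is
capped at 1.5× the largest finite distance with a warning before tree
building. Trees are neighbour joining (scikit-bio) over sorted sample ids
(deterministic ties), rooted at the diploid outgroup; < 3 taxa produce a
trivial tree with a warning. CN event counts regressed on months since
diagnosis use ordinary least squares.

## Synthetic cohort generator

The generator produces seed-reproducible cohorts carrying the statistical
structure each stage assumes, with a `TruthRecord` linking every observable
to its generating parameters.

*Clinical covariates*: configurable prevalences (defaults: 45% seminoma,
30% platinum-resistant, 8% extragonadal, four datasets); 1–3 tumours per
case (70/20/10%); purity uniform on [0.45, 0.95]; ploidy normal(3.2, 0.1)
clipped to [2.6, 4.0] — the hypertriploid-to-subtetraploid karyotype range
characteristic of TGCT. The tight ploidy spread is deliberate: the CN
features are *absolute*, so broad ploidy dispersion is itself a real
low-rank direction in encoding space that competes with the planted
signatures; cohorts with strongly bimodal ploidy would need the rank survey
interpreted accordingly (limitation).

*Copy-number profiles*: five generative processes emulate distinct CN
signatures — broad arm-level gains/losses (few breakpoints), LOH
(diploid-to-single-copy with minor-allele loss), dense unstable breakage,
focal amplification (high-copy segments shorter than a fifth of the arm on
a near-ploidy background), and two-state oscillation. Arms are allocated to
processes by largest-remainder quotas proportional to the sample's exposure
vector (Dirichlet(0.4) by default, giving per-signature >5% presence in
roughly three quarters of samples); each process's breakpoint budget
(arms × rate) is placed multinomially over its arms, so per-arm counts keep
the Poisson-like shape the mixture model expects while the sample's event
total is set by its exposures. Segments tile every chromosome exactly;
totals carry Gaussian measurement jitter (sd 0.08). Ground-truth
signature-by-component profiles in encoding space are obtained empirically
(`signature_reference_profiles`: mean encoding of pure-signature samples),
since emergent features (change-points, windows) make the analytic profile
intractable.

*Small variants*: nonsynonymous burden 0.33/Mb over the ~30 Mb synthetic
capture, +0.35/Mb in resistant cases (the planted resistance effect);
synonymous 0.10/Mb; 1.5% indels; per-histology SNV channel mixtures drawn
from the synthetic reference matrix. VAFs follow the multiplicity model
(clonal fraction 0.8; m ∈ {1, 2} clonal, uniform(0.2, 0.6) subclonal) with
binomial read sampling at Poisson(130) depth. Per-case truncal pools
(fraction 0.6) are shared — with identical alleles — across a case's
tumours; the remainder is private per sample. Planted gene–covariate
effects (e.g. KIT: baseline 10%, log-OR +1.8 for seminoma, −1.2 for
resistance) are injected at the case level as clonal truncal mutations.
Caller detection is independent per caller (default sensitivity 0.95);
false positives are injected per caller as low-evidence, strand-biased,
single-caller calls at rate fpr × n_true.

*Serial tumours*: metastases descend from the primary (via a shared
precursor when a case has ≥ 2 metastases) by adding segmental ±1 events on
the existing grid at ~0.4 events/month since diagnosis; events never touch
an allele whose integer state is 0, so within-case minimum-event distances
stay finite, as they must along a real evolutionary path.

**What the generator does not emulate** — and hence what green tests do not
certify about real data: FFPE damage chemistry beyond the threshold
filters, mappability and capture-efficiency variation, subclonal CN states,
germline contamination, inter-gene mutation-rate covariates, segmentation
error correlated with purity, and joint covariate distributions beyond
independent prevalences. Recovery results certify the *pipeline's
correctness*, not field performance on any particular real cohort.

## Numerical choices and conventions

- Thresholds inclusive on their stated side everywhere ("≥", "at least"),
  except strictly ">" for clonality (0.8), arm events (|0.1|) and presence
  (0.05), matching each rule's definition.
- All randomness flows through explicit `numpy.random.Generator` seeds; no
  hidden global state. Identical config + seed reproduces cohorts
  byte-identically.
- Mixture EM: Poisson EM stops at relative log-likelihood change < 1e-6;
  rates floored at 1e-6; quantile-spread initialisation. Gaussian mixtures
  use three EM initialisations and a 1e-6 covariance floor. Requested
  component counts are reduced when a feature has fewer distinct values.
- Problem sizes in the test-suite recovery checks (cohorts of 150–200
  cases, 10 seeds for rank recovery, 10–100 k mutations for spectrum
  recovery, 1000 null GLM simulations) were chosen as the smallest sizes at
  which the planted effects are statistically decisive.

## Known limitations

- The arm-caller replaces the external peak-based tool; focal-peak
  discovery is out of scope (focal events can be imported from external
  output for downstream comparisons).
- The rank survey's decision rule is one deterministic codification of the
  four-measure-plus-null idea; the survey object exposes every raw and null
  measure so a different rule can be applied without recomputation.
- The minimum-event distance is the segmental-event count, not the full
  transducer algebra; for profiles without allele regain the two agree on
  all exhaustively enumerable instances we test.
- Dataset-artifact filtering assumes datasets of ≳ 100 cases; on small
  synthetic cohorts the variant-level rule is degenerate (documented in the
  filtering module).
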