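"""Copy-number feature distributions and 36-component posterior encoding.

Six genome-wide feature distributions are computed per sample from its
segmented absolute copy-number profile:

  i.   segment size (Mb) -- one value per segment;
  ii.  breakpoint count per 10 Mb window -- non-overlapping tiles from the
       chromosome start;
  iii. change-point -- absolute difference in (non-integer) total copy
       number between adjacent segments;
  iv.  segment copy number -- total CN of each segment;
  v.   breakpoint count per chromosome arm (39 scored arms);
  vi.  lengths (in segments) of maximal chains of segments oscillating
       between two integer-rounded CN states (chains of >= 3 segments).

A *breakpoint* is a junction between adjacent segments whose rounded total
CN differs. Features i, iii and iv are modelled with Gaussian mixtures;
ii, v and vi with Poisson mixtures. The fitted components (36 in total by
default: 10+3+7+8+5+3) turn each sample into a 36-vector by summing, over
the sample's observations of each feature, the posterior probability of
each observation under each of that feature's components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm, poisson
from sklearn.mixture import GaussianMixture

from .core import CNProfile, round_half_up
from .genome import GenomeModel

FEATURE_NAMES = ("segsize", "bp10mb", "changepoint", "copynumber", "bpchrarm", "osccn")
GAUSSIAN_FEATURES = frozenset({"segsize", "changepoint", "copynumber"})
DEFAULT_COMPONENT_COUNTS = {
    "segsize": 10,
    "bp10mb": 3,
    "changepoint": 7,
    "copynumber": 8,
    "bpchrarm": 5,
    "osccn": 3,
}
WINDOW_BP = 10_000_000
MIN_ENCODING_PURITY = 0.4


@dataclass
class CNFeatureSet:
    """Per-sample observation lists for the six features."""

    sample_id: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        self.values = {f: np.asarray(self.values[f], dtype=float) for f in FEATURE_NAMES}
        for f, v in self.values.items():
            if (v < 0).any():
                raise ValueError(f"negative value in feature {f}")


def oscillation_chain_lengths(states: list[int]) -> list[int]:
    """Lengths of maximal >= 3-segment chains alternating between 2 states.

    A chain covers positions i..j (j >= i+2) where every element equals the
    element two before it and differs from its neighbour. Chains may share
    their boundary segments with neighbouring chains.
    """
    n = len(states)
    if n < 3:
        return []
    alt = [
        states[t] == states[t - 2] and states[t] != states[t - 1] for t in range(2, n)
    ]
    out = []
    t = 0
    while t < len(alt):
        if alt[t]:
            start = t
            while t < len(alt) and alt[t]:
                t += 1
            out.append(t - start + 2)  # run of flags [start, t) -> segments start..t+1
        else:
            t += 1
    return out


def extract_features(
    profile: CNProfile, genome: GenomeModel, window_stride: int | None = None
) -> CNFeatureSet:
    """Compute the six feature distributions from a segmented profile.

    ``window_stride`` controls the 10 Mb breakpoint windows: the default
    (None) uses non-overlapping tiles from the chromosome start, the
    deterministic special case of sliding windows; a smaller stride gives
    overlapping windows (each breakpoint then contributes to several).
    """
    by_chrom = profile.by_chromosome()
    sizes: list[float] = []
    changepoints: list[float] = []
    copynumbers: list[float] = []
    osc: list[int] = []
    breakpoints: dict[str, list[int]] = {}  # chrom -> junction positions (bp)

    for chrom, segs in by_chrom.items():
        if chrom not in genome:
            raise ValueError(f"profile contains unknown chromosome {chrom!r}")
        for a, b in zip(segs, segs[1:]):
            if b.start != a.end:
                raise ValueError(f"gap between segments on chr{chrom}")
        sizes.extend(s.length / 1e6 for s in segs)
        copynumbers.extend(s.total for s in segs)
        rounded = [round_half_up(s.total) for s in segs]
        centromere = genome[chrom].centromere
        bp_pos = []
        for i, (a, b) in enumerate(zip(segs, segs[1:])):
            if a.end == centromere:
                # junctions exactly at the centromere are segmentation
                # artifacts (no probes span it), not copy-number events
                continue
            changepoints.append(abs(b.total - a.total))
            if rounded[i + 1] != rounded[i]:
                bp_pos.append(a.end)
        breakpoints[chrom] = bp_pos
        cen_idx = [i for i, s in enumerate(segs) if s.end == centromere]
        if cen_idx:  # oscillation chains do not span the centromere
            cut = cen_idx[0] + 1
            osc.extend(oscillation_chain_lengths(rounded[:cut]))
            osc.extend(oscillation_chain_lengths(rounded[cut:]))
        else:
            osc.extend(oscillation_chain_lengths(rounded))

    stride = WINDOW_BP if window_stride is None else int(window_stride)
    if stride <= 0:
        raise ValueError("window stride must be positive")
    bp10: list[int] = []
    for c in genome.chromosomes:
        if c.name not in by_chrom:
            continue
        pos = np.asarray(breakpoints.get(c.name, []))
        starts = np.arange(0, max(c.length - WINDOW_BP, 0) + 1, stride)
        if stride == WINDOW_BP and len(starts) * WINDOW_BP < c.length:
            starts = np.append(starts, len(starts) * WINDOW_BP)  # tail tile
        for w0 in starts:
            w1 = min(w0 + WINDOW_BP, c.length)
            bp10.append(int(((pos >= w0) & (pos < w1)).sum()) if len(pos) else 0)

    # binned over all tiled arms (junctions at the centromere fall in q), so
    # the per-arm totals equal the per-window totals exactly
    bparm: list[int] = []
    for arm in genome.arms():
        if arm.chrom not in by_chrom:
            continue
        bparm.append(
            sum(1 for p in breakpoints.get(arm.chrom, []) if arm.start <= p < arm.end)
        )

    return CNFeatureSet(
        profile.sample_id,
        {
            "segsize": np.array(sizes),
            "bp10mb": np.array(bp10),
            "changepoint": np.array(changepoints),
            "copynumber": np.array(copynumbers),
            "bpchrarm": np.array(bparm),
            "osccn": np.array(osc),
        },
    )


# ---------------------------------------------------------------------------
# Mixture component model


@dataclass(frozen=True)
class Component:
    feature: str
    family: str  # 'gaussian' | 'poisson'
    weight: float
    mean: float
    sd: float | None = None  # gaussian only

    def log_density(self, x: np.ndarray) -> np.ndarray:
        if self.family == "gaussian":
            return norm.logpdf(x, self.mean, max(self.sd, 1e-6))
        return poisson.logpmf(np.rint(x).astype(int), max(self.mean, 1e-9))


@dataclass
class ComponentModel:
    """Ordered list of mixture components across the six features."""

    components: list[Component]

    def __post_init__(self) -> None:
        for f in FEATURE_NAMES:
            w = sum(c.weight for c in self.components if c.feature == f)
            if abs(w - 1.0) > 1e-6:
                raise ValueError(f"weights of feature {f} sum to {w}, not 1")
            fam = "gaussian" if f in GAUSSIAN_FEATURES else "poisson"
            if any(c.family != fam for c in self.components if c.feature == f):
                raise ValueError(f"feature {f} must use {fam} components")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def feature_components(self, feature: str) -> list[tuple[int, Component]]:
        return [(i, c) for i, c in enumerate(self.components) if c.feature == feature]

    def component_means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "feature": c.feature,
                "family": c.family,
                "weight": c.weight,
                "mean": c.mean,
                "sd": c.sd,
            }
            for c in self.components
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ComponentModel":
        payload = json.loads(Path(path).read_text())
        return cls([Component(**c) for c in payload])


def _fit_poisson_mixture(
    x: np.ndarray, k: int, max_iter: int = 300, tol: float = 1e-6, seed: int = 0
) -> list[tuple[float, float]]:
    """EM for a k-component Poisson mixture; returns [(weight, rate)]."""
    x = np.rint(np.asarray(x, dtype=float))
    n = len(x)
    if n < k:
        raise ValueError("fewer observations than components")
    # quantile-spread initialisation
    qs = np.quantile(x, np.linspace(0.1, 0.9, k))
    rates = np.maximum(qs + np.linspace(0, 1e-3, k), 1e-3)
    weights = np.full(k, 1.0 / k)
    ll_old = -np.inf
    for _ in range(max_iter):
        logp = poisson.logpmf(x[:, None], rates[None, :]) + np.log(weights)[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot).ravel() + m.ravel()).sum())
        nk = resp.sum(axis=0)
        weights = nk / n
        rates = np.maximum((resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12), 1e-6)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    order = np.argsort(rates)
    return [(float(weights[i]), float(rates[i])) for i in order]


def fit_component_model(
    feature_sets: list[CNFeatureSet],
    component_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> ComponentModel:
    """Fit per-feature mixtures to the pooled cohort feature values.

    Gaussian mixtures (EM via scikit-learn) for segment size, change-point
    and copy number; Poisson mixtures (EM) for the count features. Component
    counts default to 10+3+7+8+5+3 = 36 and are fully configurable.
    """
    counts = dict(DEFAULT_COMPONENT_COUNTS if component_counts is None else component_counts)
    components: list[Component] = []
    for f in FEATURE_NAMES:
        pooled = np.concatenate([fs.values[f] for fs in feature_sets])
        k = counts[f]
        if len(pooled) < k:
            raise ValueError(f"feature {f}: {len(pooled)} observations < {k} components")
        if f in GAUSSIAN_FEATURES:
            k_eff = min(k, max(1, len(np.unique(np.round(pooled, 9)))))
            gm = GaussianMixture(
                n_components=k_eff,
                covariance_type="diag",
                random_state=seed,
                n_init=3,
                reg_covar=1e-6,
            ).fit(pooled[:, None])
            order = np.argsort(gm.means_.ravel())
            for i in order:
                components.append(
                    Component(
                        f,
                        "gaussian",
                        float(gm.weights_[i]),
                        float(gm.means_[i, 0]),
                        float(np.sqrt(gm.covariances_[i, 0])),
                    )
                )
        else:
            k_eff = min(k, max(1, len(np.unique(np.rint(pooled)))))
            for w, rate in _fit_poisson_mixture(pooled, k_eff, seed=seed):
                components.append(Component(f, "poisson", w, rate))
    return ComponentModel(components)


def select_component_count_bic(
    values: np.ndarray, feature: str, k_range: range, seed: int = 0
) -> int:
    """Pick the per-feature component count by lowest BIC (Gaussian features)."""
    if feature not in GAUSSIAN_FEATURES:
        raise ValueError("BIC selection implemented for Gaussian features")
    best_k, best_bic = None, np.inf
    for k in k_range:
        if len(values) <= k:
            continue
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", random_state=seed, reg_covar=1e-6
        ).fit(values[:, None])
        bic = gm.bic(values[:, None])
        if bic < best_bic:
            best_k, best_bic = k, bic
    if best_k is None:
        raise ValueError("no feasible component count in range")
    return best_k


@dataclass
class SampleEncoding:
    sample_id: str
    vector: np.ndarray  # summed posteriors, one entry per component
    event_counts: dict[str, int]


def encode_sample(features: CNFeatureSet, model: ComponentModel) -> SampleEncoding:
    """Sum-of-posterior-probabilities encoding of one sample.

    For each observation of each feature the posterior over that feature's
    components (weight x density, normalised) is computed and accumulated;
    each feature's block therefore sums to its observation count.
    """
    vec = np.zeros(model.n_components)
    counts: dict[str, int] = {}
    for f in FEATURE_NAMES:
        idx_comp = model.feature_components(f)
        if not idx_comp:
            raise ValueError(f"model lacks components for feature {f}")
        x = features.values[f]
        counts[f] = len(x)
        if len(x) == 0:
            continue
        idx = [i for i, _ in idx_comp]
        logp = np.stack(
            [np.log(max(c.weight, 1e-300)) + c.log_density(x) for _, c in idx_comp],
            axis=1,
        )
        m = logp.max(axis=1, keepdims=True)
        bad = ~np.isfinite(m.ravel())
        p = np.exp(logp - np.where(np.isfinite(m), m, 0.0))
        if bad.any():
            warnings.warn(
                f"{features.sample_id}: {bad.sum()} observation(s) of {f} have zero "
                "density under all components; uniform posterior used"
            )
            p[bad] = 1.0
        p /= p.sum(axis=1, keepdims=True)
        vec[idx] += p.sum(axis=0)
    return SampleEncoding(features.sample_id, vec, counts)


def encode_cohort(
    profiles: list[CNProfile],
    genome: GenomeModel,
    model: ComponentModel | None = None,
    component_counts: dict[str, int] | None = None,
    min_purity: float = MIN_ENCODING_PURITY,
    seed: int = 0,
):
    """Feature-extract and encode a cohort; optionally fit the model first.

    Samples below the purity floor (default 0.4) are excluded before
    encoding. Returns (samples x components matrix, sample ids, model).
    """
    usable = [p for p in profiles if p.purity >= min_purity]
    if not usable:
        raise ValueError("no profiles at or above the purity floor")
    feats = [extract_features(p, genome) for p in usable]
    if model is None:
        model = fit_component_model(feats, component_counts, seed=seed)
    encodings = [encode_sample(fs, model) for fs in feats]
    matrix = np.stack([e.vector for e in encodings])
    return matrix, [e.sample_id for e in encodings], model
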