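"""96-channel trinucleotide spectra and reference-signature fitting.

Spectra use the standard pyrimidine-reference convention: six substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G), each in 16 flanking contexts ordered
alphabetically by 5' then 3' base, giving the fixed 96-channel order in
``SPECTRUM_CHANNELS``. Substitutions recorded on the purine strand are
reverse-complemented before binning.

Fitting decomposes an observed spectrum into a non-negative combination of
reference signatures (e.g. the 30-signature COSMIC catalogue) by iterative
forward selection with a non-negative least-squares refit at each step;
signatures contributing less than a minimum weight are zeroed, and weights
plus the unexplained residual sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import VariantCall

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
SPECTRUM_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(SPECTRUM_CHANNELS)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MIN_SIGNATURE_WEIGHT = 0.06  # weights below this are zeroed after fitting
MIN_SAMPLE_SNVS = 50  # sample-level fits only at >= 50 SNVs


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, trinucleotide: str) -> str:
    """96-channel label for a substitution in its trinucleotide context."""
    ref, alt, tri = ref.upper(), alt.upper(), trinucleotide.upper()
    if len(tri) != 3 or tri[1] != ref:
        raise ValueError(f"context {tri!r} does not centre on ref {ref!r}")
    if any(b not in _COMPLEMENT for b in tri + alt):
        raise ValueError(f"non-ACGT base in {tri!r}>{alt!r}")
    if ref in ("A", "G"):  # purine reference: flip to pyrimidine strand
        tri, ref, alt = _revcomp(tri), _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


@dataclass
class TrinucleotideSpectrum:
    counts: np.ndarray  # length 96, channel order SPECTRUM_CHANNELS
    label: str = ""
    skipped: int = 0  # variants dropped (ambiguous context)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "TrinucleotideSpectrum") -> "TrinucleotideSpectrum":
        return TrinucleotideSpectrum(self.counts + other.counts, self.label)


def build_spectrum(variants: list[VariantCall], label: str = "") -> TrinucleotideSpectrum:
    """Bin SNVs with trinucleotide context into the 96 channels.

    Variants whose context contains N (or is missing) are skipped and
    counted in ``spectrum.skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in variants:
        if v.variant_class != "SNV":
            continue
        if v.trinucleotide is None or "N" in v.trinucleotide.upper():
            skipped += 1
            continue
        counts[_CHANNEL_INDEX[channel_of(v.ref, v.alt, v.trinucleotide)]] += 1
    return TrinucleotideSpectrum(counts, label, skipped)


@dataclass
class SignatureExposure:
    weights: pd.Series  # indexed by signature name, >= 0
    residual: float
    n_snvs: float
    label: str = ""
    selection_errors: tuple = ()  # SSE after each forward-selection step

    def __post_init__(self) -> None:
        total = float(self.weights.sum()) + self.residual
        if abs(total - 1.0) > 1e-6:
            raise ValueError("weights + residual must sum to 1")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a signatures-by-96-channel reference TSV (COSMIC layout).

    Accepts either orientation (signatures in rows or columns); rows are
    returned as signatures, columns ordered per ``SPECTRUM_CHANNELS``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(SPECTRUM_CHANNELS) <= set(df.index):
        df = df.T
    if not set(SPECTRUM_CHANNELS) <= set(df.columns):
        raise ValueError("reference matrix lacks the 96 trinucleotide channels")
    return df.loc[:, list(SPECTRUM_CHANNELS)].astype(float)


def fit_signatures(
    spectrum: TrinucleotideSpectrum,
    reference: pd.DataFrame,
    min_weight: float = MIN_SIGNATURE_WEIGHT,
    tol: float = 1e-4,
    context_weights: np.ndarray | None = None,
) -> SignatureExposure:
    """Forward-selection non-negative fit of reference signatures.

    Starting from the empty set, the signature whose addition most reduces
    the sum-of-squares reconstruction error of the normalised spectrum is
    added (with all selected weights refit by NNLS) until the relative error
    improvement falls below ``tol``. Weights below ``min_weight`` are then
    zeroed and the remaining signatures refit; weights and the unexplained
    residual are normalised to sum to one.

    ``context_weights`` (length 96) optionally rescales the spectrum by the
    relative trinucleotide frequency of the sequenced territory (e.g.
    genome/exome ratios) before fitting; off by default.
    """
    if spectrum.total <= 0:
        raise ValueError("cannot fit an all-zero spectrum")
    counts = spectrum.counts
    if context_weights is not None:
        w = np.asarray(context_weights, dtype=float)
        if w.shape != (96,) or (w <= 0).any():
            raise ValueError("context weights must be 96 positive values")
        counts = counts * w
    v = counts / counts.sum()
    S = reference.to_numpy(dtype=float)
    S = S / S.sum(axis=1, keepdims=True)
    names = list(reference.index)
    n_sig = len(names)

    def refit(sel: list[int]) -> tuple[np.ndarray, float]:
        w, rnorm = nnls(S[sel].T, v)
        return w, rnorm**2

    selected: list[int] = []
    err = float(v @ v)
    errors = [err]
    while len(selected) < n_sig:
        best = None
        for j in range(n_sig):
            if j in selected:
                continue
            _, e = refit(selected + [j])
            if best is None or e < best[1]:
                best = (j, e)
        assert best is not None
        if err - best[1] < tol * err:
            break
        selected.append(best[0])
        err = best[1]
        errors.append(err)

    weights = np.zeros(n_sig)
    if selected:
        w, _ = refit(selected)
        weights[selected] = w
        # drop negligible contributions and refit the survivors
        keep = [j for j, wj in zip(selected, w) if wj >= min_weight]
        weights[:] = 0.0
        if keep:
            w, _ = refit(keep)
            weights[keep] = w

    total = weights.sum()
    if total > 1.0:
        weights = weights / total
        residual = 0.0
    else:
        residual = 1.0 - total
    return SignatureExposure(
        pd.Series(weights, index=names),
        float(residual),
        spectrum.total,
        spectrum.label,
        tuple(errors),
    )


def pool_and_fit(
    spectra: list[TrinucleotideSpectrum],
    groups: list[str],
    reference: pd.DataFrame,
    min_sample_snvs: int = MIN_SAMPLE_SNVS,
    **fit_kw,
) -> tuple[dict[str, SignatureExposure], dict[str, SignatureExposure]]:
    """Group-pooled fits plus sample-level fits for mutation-rich samples.

    Spectra are summed within each group before fitting; individual samples
    are fit only where their SNV total meets ``min_sample_snvs``.
    Returns (per-group exposures, per-sample exposures).
    """
    if len(spectra) != len(groups):
        raise ValueError("one group label per spectrum required")
    pooled: dict[str, np.ndarray] = {}
    for spec, g in zip(spectra, groups):
        pooled[g] = pooled.get(g, np.zeros(96)) + spec.counts

    group_fits: dict[str, SignatureExposure] = {}
    for g, counts in pooled.items():
        if counts.sum() == 0:
            warnings.warn(f"group {g!r} has no SNVs; skipped")
            continue
        group_fits[g] = fit_signatures(
            TrinucleotideSpectrum(counts, label=g), reference, **fit_kw
        )

    sample_fits: dict[str, SignatureExposure] = {}
    for spec in spectra:
        if spec.total >= min_sample_snvs:
            sample_fits[spec.label] = fit_signatures(spec, reference, **fit_kw)
    return group_fits, sample_fits


def exposures_to_frame(fits: dict[str, SignatureExposure]) -> pd.DataFrame:
    """Stack exposures into a labels-by-signature table (+residual column)."""
    rows = {}
    for label, fit in fits.items():
        row = fit.weights.copy()
        row["residual"] = fit.residual
        rows[label] = row
    return pd.DataFrame(rows).T
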