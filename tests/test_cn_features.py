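"""Copy-number feature extraction and mixture-model encoding."""

import itertools

import numpy as np
import pytest

from tgctk.core import CNProfile, CNSegment
from tgctk.cn_features import (
    DEFAULT_COMPONENT_COUNTS,
    Component,
    ComponentModel,
    _fit_poisson_mixture,
    encode_sample,
    extract_features,
    fit_component_model,
    oscillation_chain_lengths,
)


def flat_profile(genome, cn=2.0, sample_id="S"):
    segs = [CNSegment(c.name, 0, c.length, cn / 2, cn / 2) for c in genome.chromosomes]
    return CNProfile(sample_id, segs, 1.0, cn)


def chrom1_profile(genome, totals, minor=None):
    """Equal-length segments tiling chromosome 1 with the given total CNs."""
    c = genome["1"]
    n = len(totals)
    bounds = np.linspace(0, c.length, n + 1).astype(int)
    segs = [
        CNSegment("1", int(bounds[i]), int(bounds[i + 1]),
                  totals[i] - (minor[i] if minor else 0.0),
                  (minor[i] if minor else 0.0))
        for i in range(n)
    ]
    return CNProfile("S", segs, 1.0, 2.0)


class TestExtractFeatures:
    def test_flat_profile_has_no_events(self, genome):
        fs = extract_features(flat_profile(genome), genome)
        assert (fs.values["bp10mb"] == 0).all()
        assert (fs.values["bpchrarm"] == 0).all()
        assert len(fs.values["changepoint"]) == 0
        assert len(fs.values["osccn"]) == 0
        assert len(fs.values["segsize"]) == 22
        assert len(fs.values["bpchrarm"]) == 44

    def test_changepoint_arithmetic(self, genome):
        fs = extract_features(chrom1_profile(genome, [2.0, 4.5]), genome)
        changes = fs.values["changepoint"]
        # one within-chromosome junction on chr1
        assert changes.tolist() == [2.5]

    def test_oscillating_sequence(self, genome):
        fs = extract_features(chrom1_profile(genome, [2, 3, 2, 3, 2]), genome)
        assert fs.values["osccn"].tolist() == [5.0]

    def test_breakpoint_totals_match_across_binnings(self, genome, small_cohort):
        _, (_, _, profiles, _) = small_cohort
        for p in list(profiles.values())[:10]:
            fs = extract_features(p, genome)
            assert fs.values["bp10mb"].sum() == fs.values["bpchrarm"].sum()

    def test_equal_cn_junction_is_not_breakpoint(self, genome):
        fs = extract_features(chrom1_profile(genome, [2.0, 2.2]), genome)
        assert fs.values["bp10mb"].sum() == 0
        assert len(fs.values["changepoint"]) == 1  # junction still a change-point obs

    def test_gap_rejected(self, genome):
        segs = [CNSegment("1", 0, 100, 1, 1), CNSegment("1", 200, 300, 1, 1)]
        profile = CNProfile("S", segs, 1.0, 2.0)
        with pytest.raises(ValueError, match="gap"):
            extract_features(profile, genome)

    def test_segment_split_invariance_of_breakpoints(self, genome):
        one = chrom1_profile(genome, [2.0, 2.0, 4.0, 4.0])
        two = chrom1_profile(genome, [2.0, 4.0])
        f1 = extract_features(one, genome)
        f2 = extract_features(two, genome)
        assert f1.values["bpchrarm"].sum() == f2.values["bpchrarm"].sum() == 1


class TestOscillationOracle:
    @staticmethod
    def oracle(states):
        """Exhaustive scan: all maximal two-state alternating windows >= 3."""
        n = len(states)
        found = []
        for i in range(n):
            for j in range(i + 2, n):
                window = states[i : j + 1]
                alternating = all(
                    window[t] == window[t - 2] and window[t] != window[t - 1]
                    for t in range(2, len(window))
                )
                if not alternating:
                    continue
                left_ext = i > 0 and states[i - 1] == window[1] and states[i - 1] != window[0]
                right_ext = (
                    j < n - 1 and states[j + 1] == window[-2] and states[j + 1] != window[-1]
                )
                if not left_ext and not right_ext:
                    found.append(j - i + 1)
        return sorted(found)

    def test_matches_exhaustive_scan_up_to_length_8(self):
        for length in range(1, 9):
            for states in itertools.product([1, 2, 3, 4], repeat=length):
                assert sorted(oscillation_chain_lengths(list(states))) == self.oracle(
                    list(states)
                ), states

    def test_example_chain(self):
        assert oscillation_chain_lengths([2, 3, 2, 3, 2]) == [5]

    def test_overlapping_chains(self):
        assert sorted(oscillation_chain_lengths([2, 3, 2, 4, 2, 4])) == [3, 4]


class TestComponentModel:
    def test_default_counts_sum_to_36(self):
        assert sum(DEFAULT_COMPONENT_COUNTS.values()) == 36

    def test_requested_counts_reported(self, genome, small_cohort):
        _, (_, _, profiles, _) = small_cohort
        feats = [extract_features(p, genome) for p in list(profiles.values())[:15]]
        counts = {"segsize": 10, "bp10mb": 3, "changepoint": 7,
                  "copynumber": 8, "bpchrarm": 5, "osccn": 3}
        model = fit_component_model(feats, counts, seed=0)
        assert model.n_components == 36

    def test_weight_normalisation_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            ComponentModel(
                [Component("segsize", "gaussian", 0.5, 1.0, 1.0)]
                + [
                    Component(f, "poisson" if f in ("bp10mb", "bpchrarm", "osccn") else "gaussian",
                              1.0, 1.0, 1.0)
                    for f in ("bp10mb", "changepoint", "copynumber", "bpchrarm", "osccn")
                ]
            )

    def test_family_mapping_enforced(self):
        comps = [
            Component("segsize", "poisson", 1.0, 1.0),  # wrong family
            *[
                Component(f, "poisson" if f in ("bp10mb", "bpchrarm", "osccn") else "gaussian",
                          1.0, 1.0, 1.0)
                for f in ("bp10mb", "changepoint", "copynumber", "bpchrarm", "osccn")
            ],
        ]
        with pytest.raises(ValueError, match="gaussian"):
            ComponentModel(comps)

    def test_json_round_trip(self, genome, small_cohort, tmp_path):
        _, (_, _, profiles, _) = small_cohort
        feats = [extract_features(p, genome) for p in list(profiles.values())[:15]]
        model = fit_component_model(feats, seed=0)
        model.to_json(tmp_path / "model.json")
        back = ComponentModel.from_json(tmp_path / "model.json")
        assert np.allclose(model.component_means(), back.component_means())

    def test_gaussian_em_recovery(self, rng):
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        feats = _FakeFeatures(x)
        model = fit_component_model([feats], {**DEFAULT_COMPONENT_COUNTS, "segsize": 2},
                                    seed=0)
        means = sorted(c.mean for c in model.components if c.feature == "segsize")
        se = 1 / np.sqrt(2000)
        assert abs(means[0] - 0) < 3 * se and abs(means[1] - 10) < 3 * se

    def test_poisson_em_recovery(self, rng):
        x = np.concatenate([rng.poisson(1, 3000), rng.poisson(12, 3000)])
        comps = _fit_poisson_mixture(x, 2, seed=0)
        rates = sorted(r for _, r in comps)
        assert rates[0] == pytest.approx(1.0, abs=0.15)
        assert rates[1] == pytest.approx(12.0, abs=0.5)

    def test_single_valued_poisson_component(self):
        comps = _fit_poisson_mixture(np.full(100, 4.0), 1)
        assert comps[0][1] == pytest.approx(4.0)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            _fit_poisson_mixture(np.array([1.0]), 3)


class _FakeFeatures:
    """Feature set with controlled values in one feature, tiny filler elsewhere."""

    def __init__(self, segsize_values):
        filler = np.arange(1, 40, dtype=float)
        self.sample_id = "F"
        self.values = {
            "segsize": np.asarray(segsize_values, dtype=float),
            "bp10mb": filler % 5,
            "changepoint": filler / 4,
            "copynumber": filler / 10 + 1,
            "bpchrarm": filler % 6,
            "osccn": np.array([3.0, 4.0, 5.0] * 13),
        }


@pytest.fixture(scope="module")
def fitted(genome, small_cohort):
    _, (_, _, profiles, _) = small_cohort
    feats = [extract_features(p, genome) for p in list(profiles.values())[:20]]
    model = fit_component_model(feats, seed=0)
    return feats, model


class TestEncoding:
    def test_block_sums_equal_observation_counts(self, fitted):
        feats, model = fitted
        for fs in feats[:5]:
            enc = encode_sample(fs, model)
            for f, count in enc.event_counts.items():
                idx = [i for i, _ in model.feature_components(f)]
                assert enc.vector[idx].sum() == pytest.approx(count, abs=1e-6)

    def test_encoding_length_36(self, fitted):
        feats, model = fitted
        assert encode_sample(feats[0], model).vector.shape == (36,)

    def test_lone_component_gets_unit_mass(self):
        comps = []
        for f in ("segsize", "changepoint", "copynumber"):
            comps.append(Component(f, "gaussian", 1.0, 5.0, 1.0))
        for f in ("bp10mb", "bpchrarm", "osccn"):
            comps.append(Component(f, "poisson", 1.0, 2.0))
        model = ComponentModel(comps)
        fs = _FakeFeatures([5.0])
        fs.values = {f: np.array([]) for f in fs.values}
        fs.values["segsize"] = np.array([5.0])
        enc = encode_sample(fs, model)
        assert enc.vector[0] == pytest.approx(1.0)


def test_sliding_window_stride(genome):
    profile = chrom1_profile(genome, [2.0, 4.0])
    tiled = extract_features(profile, genome)
    slid = extract_features(profile, genome, window_stride=5_000_000)
    # one breakpoint: overlapping 10 Mb windows at 5 Mb stride see it twice
    assert tiled.values["bp10mb"].sum() == 1
    assert slid.values["bp10mb"].sum() == 2
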