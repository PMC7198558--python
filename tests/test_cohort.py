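"""Synthetic cohort generator: determinism, planted structure, writers."""

import numpy as np
import pandas as pd
import pytest

from tgctk import io
from tgctk.cohort import (
    CohortConfig,
    ConfigurationError,
    DEFAULT_CN_SIGNATURES,
    GeneEffect,
    capture_intervals,
    generate_cn_profile,
    generate_cohort,
    simulate_caller_calls,
)
from tgctk.core import round_half_up
from tgctk.filtering import capture_intersect, consensus_filter
from tgctk.longitudinal import jaccard_index
from tgctk.metrics import multiplicity
from tgctk.stats import ModelSpec, fit_glm


class TestDeterminism:
    def test_identical_config_and_seed(self, small_cohort):
        cfg, (samples, variants, profiles, truth) = small_cohort
        s2, v2, p2, t2 = generate_cohort(CohortConfig(n_cases=30, seed=7))
        assert samples == s2
        assert variants == v2
        assert all(
            profiles[k].segments == p2[k].segments for k in profiles
        )
        pd.testing.assert_frame_equal(truth.exposures, t2.exposures)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_cases=5, seed=1))[1]
        b = generate_cohort(CohortConfig(n_cases=5, seed=2))[1]
        assert a != b


class TestConfigValidation:
    def test_prevalence_outside_unit_interval(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(n_cases=2, seminoma_prev=1.4))

    def test_sample_distribution_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(n_cases=2, samples_per_case={1: 0.5, 2: 0.2}))


class TestProfiles:
    def test_segments_tile_every_chromosome(self, genome, small_cohort):
        _, (_, _, profiles, _) = small_cohort
        for p in profiles.values():
            for chrom, segs in p.by_chromosome().items():
                assert segs[0].start == 0
                assert segs[-1].end == genome[chrom].length
                for a, b in zip(segs, segs[1:]):
                    assert b.start == a.end

    def test_flat_profile_at_ploidy_two(self, genome, rng):
        e = np.full(5, 0.2)
        p = generate_cn_profile(e, genome, 2.0, rng, total_breakpoints=0)
        assert len(p.segments) == 22  # merged to whole chromosomes
        assert all(s.total == 2.0 for s in p.segments)

    def test_wrong_exposure_length_rejected(self, genome, rng):
        with pytest.raises(ValueError, match="length"):
            generate_cn_profile(np.array([1.0]), genome, 2.0, rng)

    def test_exposures_sum_to_one(self, small_cohort):
        _, (_, _, _, truth) = small_cohort
        assert np.allclose(truth.exposures.sum(axis=1), 1.0)

    def test_pure_signature_round_trip(self, genome):
        """Profiles from pure signature k re-encode closest to k's profile."""
        from tgctk.cn_features import encode_cohort
        from tgctk.cohort import signature_reference_profiles

        rng = np.random.default_rng(5)
        profiles = []
        labels = []
        for k in range(5):
            e = np.eye(5)[k]
            for i in range(25):
                prof = generate_cn_profile(e, genome, 3.2, rng, sample_id=f"k{k}_{i}")
                prof.purity = 0.8
                profiles.append(prof)
                labels.append(k)
        V, ids, model = encode_cohort(profiles, genome, seed=0)
        ref = signature_reference_profiles(model, genome, n_samples=25, seed=99)
        refn = ref / np.linalg.norm(ref, axis=1, keepdims=True)
        correct = 0
        for row, k in zip(V, labels):
            v = row / np.linalg.norm(row)
            cos = refn @ v
            correct += int(np.argmax(cos) == k) and cos[k] > 0.9
        assert correct / len(labels) > 0.9


class TestVariants:
    def test_vaf_follows_multiplicity_model(self, small_cohort):
        _, (samples, variants, profiles, truth) = small_cohort
        meta = {s.sample_id: s for s in samples}
        vt = truth.variant_truth.set_index(
            ["variant_id", "sample_id"], drop=False
        )
        checked = 0
        for v in variants[:400]:
            row = vt.loc[(v.variant_id, v.sample_id)]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            p = meta[v.sample_id].purity
            if v.depth < 100:
                continue
            cn = profiles[v.sample_id].total_cn_at(v.chrom, v.pos)
            if cn is None or round(cn) < 1:
                cn = max(1.0, round(profiles[v.sample_id].ploidy))
            expected = row.multiplicity * p / (p * cn + 2 * (1 - p))
            expected = float(np.clip(expected, 0.005, 0.95))
            # binomial sampling error at the observed depth
            se = np.sqrt(expected * (1 - expected) / v.depth)
            assert abs(v.vaf - expected) < 5 * se + 1e-9
            checked += 1
        assert checked > 100

    def test_truncal_fraction_one_gives_full_jaccard(self):
        cfg = CohortConfig(
            n_cases=12, seed=3, truncal_fraction=1.0,
            samples_per_case={2: 0.5, 3: 0.5},
            planted_gene_effects=[],
        )
        samples, variants, _, _ = generate_cohort(cfg)
        by_sample: dict[str, set] = {}
        for v in variants:
            by_sample.setdefault(v.sample_id, set()).add(v.variant_id)
        by_case: dict[str, list] = {}
        for s in samples:
            by_case.setdefault(s.case_id, []).append(s.sample_id)
        for case, sids in by_case.items():
            sets = [by_sample.get(sid, set()) for sid in sids]
            if len(sets) > 1 and any(sets):
                for other in sets[1:]:
                    assert jaccard_index(sets[0], other) == 100.0

    def test_every_variant_links_to_truth(self, small_cohort):
        _, (_, variants, _, truth) = small_cohort
        truth_keys = set(
            zip(truth.variant_truth.variant_id, truth.variant_truth.sample_id)
        )
        for v in variants:
            assert (v.variant_id, v.sample_id) in truth_keys

    def test_variants_inside_capture(self, genome, small_cohort):
        _, (_, variants, _, _) = small_cohort
        ci = capture_intersect([capture_intervals(genome)])
        assert all(ci.contains(v.chrom, v.pos) for v in variants)

    def test_resistant_tmb_shift_present(self):
        cfg = CohortConfig(n_cases=150, seed=21, planted_gene_effects=[])
        samples, variants, _, _ = generate_cohort(cfg)
        counts = {}
        for v in variants:
            if v.consequence == "nonsynonymous":
                counts[v.sample_id] = counts.get(v.sample_id, 0) + 1
        res, sen = [], []
        for s in samples:
            n = counts.get(s.sample_id, 0)
            (res if s.platinum_response == "resistant" else sen).append(n)
        shift_per_mb = (np.mean(res) - np.mean(sen)) / 30.0
        assert shift_per_mb == pytest.approx(0.35, abs=0.12)


class TestCallerSimulation:
    def test_full_sensitivity_gives_three_callers(self, small_cohort, rng):
        _, (_, variants, _, _) = small_cohort
        sens = {c: 1.0 for c in ("strelka", "mutect", "mutect2")}
        called, fps = simulate_caller_calls(variants[:50], sens, 0.0, rng)
        assert all(len(v.callers) == 3 for v in called)
        assert not fps

    def test_zero_sensitivity_retains_nothing(self, small_cohort, rng):
        _, (_, variants, _, _) = small_cohort
        sens = {c: 0.0 for c in ("strelka", "mutect", "mutect2")}
        called, _ = simulate_caller_calls(variants[:50], sens, 0.0, rng)
        assert consensus_filter(called) == []

    def test_consensus_retention_matches_binomial(self, rng):
        """P(>= 2 of 3 callers) at sensitivity 0.9 each = 0.972."""
        cfg = CohortConfig(n_cases=60, seed=9, planted_gene_effects=[])
        _, variants, _, _ = generate_cohort(cfg)
        sens = {c: 0.9 for c in ("strelka", "mutect", "mutect2")}
        called, _ = simulate_caller_calls(variants, sens, 0.0, rng)
        kept = len(consensus_filter(called)) / len(called)
        expected = 3 * 0.9**2 * 0.1 + 0.9**3
        se = np.sqrt(expected * (1 - expected) / len(called))
        assert abs(kept - expected) < 4 * se


class TestPlantedAssociations:
    def test_logistic_recovery_coverage(self):
        """Planted odds ratio lands inside the 95% Wald CI in most cohorts."""
        effect = GeneEffect("KIT", 0.15, {"resistant": np.log(3.0)})
        inside = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = CohortConfig(
                n_cases=150, seed=500 + rep, planted_gene_effects=[effect],
                samples_per_case={1: 1.0},
            )
            samples, variants, _, _ = generate_cohort(cfg)
            mutated = {v.case_id for v in variants if v.gene == "KIT"}
            rows = [
                {
                    "mut": int(s.case_id in mutated),
                    "resistant": int(s.platinum_response == "resistant"),
                }
                for s in samples
            ]
            fit = fit_glm(ModelSpec("mut", "binary", ["resistant"]), pd.DataFrame(rows))
            beta = fit.coefficients["resistant"]
            se = fit.std_errors["resistant"]
            if beta - 1.96 * se <= np.log(3.0) <= beta + 1.96 * se:
                inside += 1
        assert inside >= int(0.8 * n_rep)


class TestWriters:
    def test_round_trips(self, tmp_path, small_cohort):
        _, (samples, variants, profiles, truth) = small_cohort
        io.write_maf(variants, tmp_path / "v.maf.tsv")
        back = io.read_maf(tmp_path / "v.maf.tsv")
        assert back == variants

        some = list(profiles.values())[:3]
        io.write_seg(some, tmp_path / "p.seg.tsv")
        seg_back = io.read_seg(tmp_path / "p.seg.tsv")
        assert {p.sample_id for p in seg_back} == {p.sample_id for p in some}
        by_id = {p.sample_id: p for p in seg_back}
        for p in some:
            q = by_id[p.sample_id]
            assert len(q.segments) == len(p.segments)
            assert q.segments[0].start == p.segments[0].start

        io.write_covariates(samples, tmp_path / "cov.tsv")
        cov = io.read_covariates(tmp_path / "cov.tsv")
        assert len(cov) == len(samples)

        io.write_vcf(variants[:10], tmp_path / "v.vcf")
        text = (tmp_path / "v.vcf").read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert len([l for l in text.splitlines() if not l.startswith("#")]) == 10
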