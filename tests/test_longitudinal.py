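"""Force-calling, sharing classes, Jaccard and CN phylogenies."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tgctk.core import CNProfile, CNSegment
from tgctk.longitudinal import (
    _allele_events,
    build_tree,
    classify_sharing,
    cn_event_distance,
    event_distance_matrix,
    events_vs_time,
    force_call,
    jaccard_index,
    split_to_union_breakpoints,
    to_allele_arrays,
)


class TestForceCall:
    @pytest.mark.parametrize(
        "alt,depth,status",
        [
            (3, 60, "present"),
            (1, 100, "absent"),
            (0, 30, "indeterminate"),
            (2, 10, "present"),  # presence needs no depth floor
            (1, 50, "absent"),  # inclusive depth boundary
            (1, 49, "indeterminate"),
        ],
    )
    def test_rules(self, alt, depth, status):
        assert force_call("v", "s", alt, depth).status == status

    def test_exhaustive_truth_table(self):
        for alt in (0, 1, 2):
            for depth in (30, 49, 50, 51):
                got = force_call("v", "s", alt, depth).status
                if alt >= 2:
                    expected = "present"
                elif depth >= 50:
                    expected = "absent"
                else:
                    expected = "indeterminate"
                assert got == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            force_call("v", "s", -1, 10)
        with pytest.raises(ValueError):
            force_call("v", "s", 5, 3)


class TestSharing:
    @staticmethod
    def table(rows, samples=("P", "M1", "M2")):
        return pd.DataFrame(rows, columns=list(samples))

    STAGES = {"P": "primary", "M1": "metastasis", "M2": "metastasis"}

    def test_truncal(self):
        t = self.table({"v1": ["present", "present", "present"]}.values())
        t.index = ["v1"]
        out = classify_sharing(t, self.STAGES)
        assert out["v1"] == "truncal"

    def test_primary_only(self):
        t = pd.DataFrame(
            {"P": ["present"], "M1": ["absent"], "M2": ["absent"]}, index=["v"]
        )
        assert classify_sharing(t, self.STAGES)["v"] == "primary_only"

    def test_metastasis_only(self):
        t = pd.DataFrame(
            {"P": ["absent"], "M1": ["present"], "M2": ["present"]}, index=["v"]
        )
        assert classify_sharing(t, self.STAGES)["v"] == "metastasis_only"

    def test_indeterminate_primary_blocks_classification(self):
        t = pd.DataFrame(
            {"P": ["indeterminate"], "M1": ["present"], "M2": ["absent"]}, index=["v"]
        )
        assert classify_sharing(t, self.STAGES)["v"] == "other"

    def test_indeterminate_met_excluded_from_denominator(self):
        t = pd.DataFrame(
            {"P": ["present"], "M1": ["present"], "M2": ["indeterminate"]}, index=["v"]
        )
        assert classify_sharing(t, self.STAGES)["v"] == "truncal"

    def test_strict_mode(self):
        t = pd.DataFrame(
            {"P": ["present"], "M1": ["present"], "M2": ["indeterminate"]}, index=["v"]
        )
        assert classify_sharing(t, self.STAGES, strict=True)["v"] == "other"

    def test_single_tumour_rejected(self):
        t = pd.DataFrame({"P": ["present"]}, index=["v"])
        with pytest.raises(ValueError):
            classify_sharing(t, {"P": "primary"})


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 100.0

    def test_disjoint(self):
        assert jaccard_index({"a"}, {"b"}) == 0.0

    def test_half_shared(self):
        assert jaccard_index({"a", "b", "c"}, {"b", "c", "d"}) == 50.0

    def test_empty_sets_defined_zero(self):
        with pytest.warns(UserWarning):
            assert jaccard_index(set(), set()) == 0.0

    def test_monotone_under_shared_additions(self):
        a, b = {"a", "x"}, {"b", "x"}
        before = jaccard_index(a, b)
        after = jaccard_index(a | {"s"}, b | {"s"})
        assert after >= before


def bfs_min_events(a, b, cap=4):
    """Breadth-first search over +/-1 contiguous-run operations.

    A decrement cannot act on a segment at 0 and an increment cannot act on
    a segment at 0 (an allele lost to zero cannot be regained); copy numbers
    stay within [0, cap].
    """
    a, b = tuple(a), tuple(b)
    if a == b:
        return 0
    L = len(a)
    frontier = {a}
    seen = {a}
    dist = 0
    while frontier:
        dist += 1
        nxt = set()
        for state in frontier:
            for i in range(L):
                for j in range(i, L):
                    for delta in (1, -1):
                        seg = state[i : j + 1]
                        if any(s == 0 for s in seg):
                            continue
                        new_seg = tuple(s + delta for s in seg)
                        if any(s < 0 or s > cap for s in new_seg):
                            continue
                        cand = state[:i] + new_seg + state[j + 1 :]
                        if cand == b:
                            return dist
                        if cand not in seen:
                            seen.add(cand)
                            nxt.add(cand)
        frontier = nxt
    return math.inf


class TestEventDistance:
    def test_identical_zero(self):
        assert _allele_events([2, 2, 2], [2, 2, 2]) == 0

    def test_single_gain_run(self):
        assert _allele_events([2, 2, 2], [3, 3, 2]) == 1

    def test_gain_and_loss(self):
        assert _allele_events([2, 2, 2], [3, 1, 3]) == 3

    def test_regain_after_loss_is_infinite(self):
        assert _allele_events([0, 2], [1, 2]) == math.inf

    def test_loss_to_zero_is_finite(self):
        assert _allele_events([1, 1], [0, 0]) == 1

    def test_matches_bfs_oracle_exhaustive_short(self):
        # all profile pairs of length <= 2 over copy numbers 0..4
        for L in (1, 2):
            for a in itertools.product(range(5), repeat=L):
                for b in itertools.product(range(5), repeat=L):
                    assert _allele_events(list(a), list(b)) == bfs_min_events(a, b), (a, b)

    def test_matches_bfs_oracle_sampled_length4(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            a = rng.integers(0, 5, size=4)
            b = rng.integers(0, 5, size=4)
            assert _allele_events(a, b) == bfs_min_events(tuple(a), tuple(b)), (a, b)

    def test_profile_distance_sums_alleles_and_chromosomes(self):
        pa = {"1": {"major": np.array([2, 2]), "minor": np.array([1, 1])}}
        pb = {"1": {"major": np.array([3, 3]), "minor": np.array([1, 0])}}
        assert cn_event_distance(pa, pb) == 2

    def test_mismatched_grid_rejected(self):
        pa = {"1": {"major": np.array([2, 2]), "minor": np.array([1, 1])}}
        pb = {"1": {"major": np.array([3]), "minor": np.array([1])}}
        with pytest.raises(ValueError):
            cn_event_distance(pa, pb)

    def test_symmetrised_matrix(self):
        profiles = {
            "A": {"1": {"major": np.array([2, 2]), "minor": np.array([1, 1])}},
            "B": {"1": {"major": np.array([3, 2]), "minor": np.array([1, 1])}},
        }
        D = event_distance_matrix(profiles)
        assert (D.values.diagonal() == 0).all()
        assert np.allclose(D.values, D.values.T)
        # major 1,1 -> 2,2 is a single contiguous +1 event; minor unchanged
        assert D.loc["A", "diploid"] == 1


class TestSegmentGrid:
    def test_split_to_union_breakpoints(self):
        p1 = CNProfile("A", [CNSegment("1", 0, 100, 2, 1)], 1.0, 3.0)
        p2 = CNProfile(
            "B",
            [CNSegment("1", 0, 40, 2, 1), CNSegment("1", 40, 100, 3, 1)],
            1.0,
            3.0,
        )
        out = split_to_union_breakpoints([p1, p2])
        assert [s.end for s in out[0].segments] == [40, 100]
        a1, a2 = to_allele_arrays(out[0]), to_allele_arrays(out[1])
        assert cn_event_distance(a1, a2) == 1


class TestTree:
    def test_three_taxon_branch_lengths(self):
        # additive distances: d(AB)=3, d(AC)=5, d(BC)=6 -> a=1, b=2, c=4
        import skbio

        D = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        newick = build_tree(D, root="C")
        tree = skbio.TreeNode.read([newick])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)

    def test_identical_samples_zero_cherry(self):
        profiles = {
            "A": {"1": {"major": np.array([3, 3]), "minor": np.array([1, 1])}},
            "B": {"1": {"major": np.array([3, 3]), "minor": np.array([1, 1])}},
            "C": {"1": {"major": np.array([4, 2]), "minor": np.array([0, 1])}},
        }
        D = event_distance_matrix(profiles, add_diploid_root=False)
        assert D.loc["A", "B"] == 0

    def test_trivial_tree_warning(self):
        D = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.warns(UserWarning):
            newick = build_tree(D, root="A")
        assert "A" in newick and "B" in newick

    def test_metastatic_clade_recovered(self, genome):
        """Metastases seeded from one precursor form a clade vs the primary."""
        import skbio

        from tgctk.cohort import evolve_profile, generate_cn_profile

        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            e = np.array([0.4, 0.1, 0.2, 0.1, 0.2])
            primary = generate_cn_profile(e, genome, 3.2, rng, sample_id="P")
            precursor = evolve_profile(primary, 12, rng)
            m1 = evolve_profile(precursor, 5, rng, sample_id="M1")
            m2 = evolve_profile(precursor, 5, rng, sample_id="M2")
            arrays = {
                "P": to_allele_arrays(primary),
                "M1": to_allele_arrays(m1),
                "M2": to_allele_arrays(m2),
            }
            D = event_distance_matrix(arrays)
            tree = skbio.TreeNode.read([build_tree(D)])
            lca = tree.lca(["M1", "M2"])
            mets_clade = {t.name for t in lca.tips()} == {"M1", "M2"}
            hits += mets_clade
        assert hits >= int(0.95 * n_rep)


class TestEventsVsTime:
    def test_perfect_line(self):
        slope, r2, p = events_vs_time([2, 4, 6, 8], [1, 2, 3, 4])
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_zero_slope(self, rng):
        months = np.arange(10, dtype=float)
        counts = np.full(10, 5.0) + rng.normal(0, 0.01, 10)
        slope, _, _ = events_vs_time(counts, months)
        assert abs(slope) < 0.01

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(2)
        months = np.linspace(1, 40, 30)
        counts = 2.0 * months + rng.normal(0, 4, 30)
        slope, r2, p = events_vs_time(counts, months)
        assert slope == pytest.approx(2.0, abs=0.3)
        assert p < 0.001

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            events_vs_time([1, 2], [1, 2])
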