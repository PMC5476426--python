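"""Proximity statistics: comparison sets, profile, bootstrap, locus ranking."""

import itertools

import numpy as np
import pytest

from hybridhic.contacts import NormalizedContactMatrix, normalize_matrix
from hybridhic.genome import build_bin_index, call_homologous_bins
from hybridhic.proximity import (
    ControlLevel,
    ExclusionPolicy,
    PolicyViolationError,
    admissible_bins,
    bootstrap_genomic_proximity,
    build_comparison_set,
    locus_pairing_strength,
    proximity_profile,
)
from hybridhic.synth import ConditionEffects, SyntheticWorldConfig, simulate_condition


@pytest.fixture(scope="module")
def cond():
    return simulate_condition(SyntheticWorldConfig(), ConditionEffects(), seed=77)


@pytest.fixture(scope="module")
def norm(cond):
    return normalize_matrix(cond.matrix)


def _brute_force_set(anchor, level, policy, index, hmap):
    """Independent enumeration over all intergenome bin pairs."""
    b1, b2 = anchor
    ok = admissible_bins(index, policy)
    out = set()
    for i, j in itertools.product(range(index.n_bins), repeat=2):
        if index.parent[i] != 1 or index.parent[j] != 2:
            continue
        shared = (i == b1) ^ (j == b2)
        if not shared:
            continue
        kept, replaced, cand = (b1, b2, j) if i == b1 else (b2, b1, i)
        if not ok[cand] or hmap.exclusion[kept, cand]:
            continue
        if level in (ControlLevel.DCEN, ControlLevel.DCEN_ARM):
            if index.d_cen[cand] != index.d_cen[replaced]:
                continue
        if level is ControlLevel.DCEN_ARM:
            a_len = int(index.arm_length[cand])
            r_len = int(index.arm_length[replaced])
            if max(a_len, r_len) > 0 and min(a_len, r_len) / max(a_len, r_len) < policy.arm_ratio_min:
                continue
        out.add((i, j))
    return out


class TestComparisonSets:
    @pytest.mark.parametrize("level", list(ControlLevel))
    def test_matches_brute_force_enumeration(self, cond, level):
        index, hmap = cond.index, cond.hmap
        policy = ExclusionPolicy(exclude_centromere_bins=True, telomere_margin=1)
        for k in (3, 20, 50, 70):
            anchor = tuple(int(x) for x in hmap.pairs[k])
            cset = build_comparison_set(anchor, level, policy, index, hmap)
            got = {tuple(p) for p in cset.pairs}
            assert got == _brute_force_set(anchor, level, policy, index, hmap)

    def test_nested_filtering(self, cond):
        index, hmap = cond.index, cond.hmap
        policy = ExclusionPolicy()
        for pair in hmap.pairs:
            anchor = tuple(int(x) for x in pair)
            sizes = {
                level: len(build_comparison_set(anchor, level, policy, index, hmap).pairs)
                for level in ControlLevel
            }
            assert (
                sizes[ControlLevel.DCEN_ARM]
                <= sizes[ControlLevel.DCEN]
                <= sizes[ControlLevel.ALL]
            )

    def test_dcen_filter_matches_exactly(self, cond):
        index, hmap = cond.index, cond.hmap
        anchor = tuple(int(x) for x in hmap.pairs[25])
        cset = build_comparison_set(anchor, ControlLevel.DCEN, ExclusionPolicy(), index, hmap)
        for i, j in cset.pairs:
            if i == anchor[0]:
                assert index.d_cen[j] == index.d_cen[anchor[1]]
            else:
                assert index.d_cen[i] == index.d_cen[anchor[0]]

    def test_arm_ratio_rule(self, cond):
        """Arm 8 vs 10 (0.8) admitted; arm 7 vs 10 (0.7) excluded."""
        index, hmap = cond.index, cond.hmap
        anchor = tuple(int(x) for x in hmap.pairs[40])
        policy = ExclusionPolicy(arm_ratio_min=0.75)
        cset = build_comparison_set(anchor, ControlLevel.DCEN_ARM, policy, index, hmap)
        for i, j in cset.pairs:
            cand, repl = (j, anchor[1]) if i == anchor[0] else (i, anchor[0])
            a, b = int(index.arm_length[cand]), int(index.arm_length[repl])
            assert min(a, b) / max(a, b) >= 0.75

    def test_members_share_exactly_one_anchor_bin(self, cond):
        index, hmap = cond.index, cond.hmap
        anchor = tuple(int(x) for x in hmap.pairs[10])
        cset = build_comparison_set(anchor, ControlLevel.ALL, ExclusionPolicy(), index, hmap)
        for i, j in cset.pairs:
            assert (i == anchor[0]) != (j == anchor[1])
            assert not hmap.exclusion[i, j] or (i, j) == anchor


class TestProfile:
    def test_ratio_arithmetic(self, cond, norm):
        prof = proximity_profile(norm, cond.hmap, ControlLevel.DCEN)
        ok = prof.sufficient
        assert len(ok) > 0
        row = ok.iloc[0]
        assert row["ratio"] == pytest.approx(row["homolog_value"] / row["median_comparable"])

    def test_identical_values_give_ratio_one(self, cond):
        index = cond.index
        values = np.full((index.n_bins, index.n_bins), 3.0)
        np.fill_diagonal(values, np.nan)
        flat = NormalizedContactMatrix(
            values=values, valid=np.ones(index.n_bins, dtype=bool), index=index
        )
        prof = proximity_profile(flat, cond.hmap, ControlLevel.ALL)
        assert np.allclose(prof.sufficient["ratio"], 1.0)

    def test_insufficient_comparables_flagged(self, cond, norm):
        policy = ExclusionPolicy(min_comparables=10_000)
        prof = proximity_profile(norm, cond.hmap, ControlLevel.DCEN_ARM, policy)
        assert not prof.frame["sufficient"].any()
        assert prof.frame["ratio"].isna().all()


class TestBootstrap:
    def test_degenerate_distribution_is_constant(self, cond):
        index = cond.index
        values = np.full((index.n_bins, index.n_bins), 1.0)
        for b1, b2 in cond.hmap.pairs:
            values[b1, b2] = values[b2, b1] = 2.0
        np.fill_diagonal(values, np.nan)
        m = NormalizedContactMatrix(
            values=values, valid=np.ones(index.n_bins, dtype=bool), index=index
        )
        dist = bootstrap_genomic_proximity(m, cond.hmap, ControlLevel.ALL, n_reps=200, seed=0)
        assert np.all(dist.ratios == pytest.approx(2.0))

    def test_seeded_reproducibility(self, cond, norm):
        a = bootstrap_genomic_proximity(norm, cond.hmap, n_reps=500, seed=3)
        b = bootstrap_genomic_proximity(norm, cond.hmap, n_reps=500, seed=3)
        c = bootstrap_genomic_proximity(norm, cond.hmap, n_reps=500, seed=4)
        assert np.array_equal(a.ratios, b.ratios)
        assert not np.array_equal(a.ratios, c.ratios)

    def test_scale_invariance(self, cond, norm):
        scaled = norm.scale_by(37.0)
        a = bootstrap_genomic_proximity(norm, cond.hmap, n_reps=300, seed=6)
        b = bootstrap_genomic_proximity(scaled, cond.hmap, n_reps=300, seed=6)
        assert np.allclose(a.ratios, b.ratios, rtol=1e-12)
        pa = proximity_profile(norm, cond.hmap)
        pb = proximity_profile(scaled, cond.hmap)
        assert np.allclose(
            pa.sufficient["ratio"], pb.sufficient["ratio"], rtol=1e-12
        )

    def test_enumeration_oracle_on_tiny_toy(self):
        """Bootstrap mean converges to the exhaustive single-draw mean."""
        world = SyntheticWorldConfig(
            chromosome_lengths=(256_000, 256_000),
            centromeres=(112_000, 144_000),
            spike_locus=5,  # tiny chromosomes: no bin reaches the auto rule
        )
        cond = simulate_condition(world, ConditionEffects(), seed=12)
        norm = normalize_matrix(cond.matrix)
        policy = ExclusionPolicy(exclude_centromere_bins=True)
        # restrict to <= 5 anchors by pruning the homology map
        hmap = cond.hmap
        hmap.pairs = hmap.pairs[:5]
        from hybridhic.proximity import _anchor_values

        anchors = [
            r
            for r in _anchor_values(norm, hmap, ControlLevel.DCEN, policy)
            if len(r["comparables"]) >= 2 and np.isfinite(r["homolog_value"])
        ]
        numer = sum(r["homolog_value"] for r in anchors)
        combos = itertools.product(*[r["comparables"] for r in anchors])
        exact = np.mean([numer / sum(draw) for draw in combos])
        dist = bootstrap_genomic_proximity(
            norm, hmap, ControlLevel.DCEN, policy, n_reps=200_000, seed=5
        )
        assert float(np.mean(dist.ratios)) == pytest.approx(float(exact), rel=0.01)

    def test_parameter_recovery_across_beta(self):
        """Bootstrap median recovers the injected pairing boost within 10%."""
        world = SyntheticWorldConfig()
        policy = ExclusionPolicy(exclude_centromere_bins=True, telomere_margin=1)
        for beta in (1.0, 1.5, 2.0):
            meds = []
            for s in range(5):
                c = simulate_condition(world, ConditionEffects(beta=beta), seed=800 + s)
                n = normalize_matrix(c.matrix)
                d = bootstrap_genomic_proximity(
                    n, c.hmap, ControlLevel.DCEN_ARM, policy, n_reps=2000, seed=s
                )
                meds.append(d.median)
            assert abs(float(np.mean(meds)) - beta) / beta < 0.10


class TestLocusPairing:
    def test_strongest_locus_ranks_first(self, cond):
        index = cond.index
        values = np.abs(np.random.default_rng(0).normal(1, 0.1, (index.n_bins, index.n_bins)))
        values = (values + values.T) / 2
        locus = cond.registry["spike_pair"]
        values[locus[0], locus[1]] = values[locus[1], locus[0]] = 50.0
        np.fill_diagonal(values, np.nan)
        m = NormalizedContactMatrix(
            values=values, valid=np.ones(index.n_bins, dtype=bool), index=index
        )
        res = locus_pairing_strength(m, locus, ExclusionPolicy.locus_background())
        assert res.rank == 1 and res.percentile == pytest.approx(100.0)

    def test_spike_detected_under_gamma(self):
        cond = simulate_condition(SyntheticWorldConfig(), ConditionEffects(gamma=5.0), seed=13)
        norm = normalize_matrix(cond.matrix)
        res = locus_pairing_strength(
            norm, cond.registry["spike_pair"], ExclusionPolicy.locus_background()
        )
        assert res.rank == 1

    def test_policy_violation_names_filter(self, cond, norm):
        # a pericentromeric pair fails the >= 15 bins from centromere filter
        index = cond.index
        cen_bin = int(np.flatnonzero(index.centromere_bin & (index.parent == 1))[0])
        partner = int(cond.hmap.partner_of(cen_bin))
        with pytest.raises(PolicyViolationError, match="d_cen|centromere"):
            locus_pairing_strength(norm, (cen_bin, partner), ExclusionPolicy.locus_background())

    def test_background_size_counts_policy_filtered_pairs(self, cond, norm):
        policy = ExclusionPolicy.locus_background()
        ok = admissible_bins(cond.index, policy)
        n1 = int((ok & (cond.index.parent == 1)).sum())
        n2 = int((ok & (cond.index.parent == 2)).sum())
        res = locus_pairing_strength(norm, cond.registry["spike_pair"], policy)
        assert res.n_background == n1 * n2
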