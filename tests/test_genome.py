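"""Genome model: bin tiling, centromere distances, homolog calling, mappability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridhic.genome import (
    ChromosomeSpec,
    GenomeConfigError,
    HomologyTable,
    HybridGenomeSpec,
    build_bin_index,
    call_homologous_bins,
    kmer_mappability,
    mappability_by_bin,
)


def _two_parent(chroms1):
    """Mirror parent-1 chromosomes into a parent-2 set."""
    mirrored = [
        ChromosomeSpec(c.name + "_2", 2, c.length, c.centromere, c.rdna) for c in chroms1
    ]
    return HybridGenomeSpec(chroms1 + mirrored)


class TestBinIndex:
    def test_tiling_and_short_last_bin(self):
        g = _two_parent([ChromosomeSpec("a", 1, 100_000, 40_000)])
        idx = build_bin_index(g, 32_000)
        sl = idx.chrom_slice("a")
        assert list(idx.start[sl]) == [0, 32_000, 64_000, 96_000]
        assert list(idx.end[sl]) == [32_000, 64_000, 96_000, 100_000]
        # tiling conservation
        assert int((idx.end[sl] - idx.start[sl]).sum()) == 100_000

    def test_d_cen_and_centromere_flag(self):
        g = _two_parent([ChromosomeSpec("a", 1, 100_000, 40_000)])
        idx = build_bin_index(g, 32_000)
        sl = idx.chrom_slice("a")
        assert list(idx.d_cen[sl]) == [1, 0, 1, 2]
        assert list(idx.centromere_bin[sl]) == [False, True, False, False]
        assert np.all((idx.d_cen == 0) == idx.centromere_bin)

    def test_arm_lengths_and_margins(self):
        g = _two_parent([ChromosomeSpec("a", 1, 8 * 32_000, 3 * 32_000 + 100)])
        idx = build_bin_index(g, 32_000)
        sl = idx.chrom_slice("a")
        # centromere in bin 3: left arm 3 bins, right arm 4 bins
        assert list(idx.arm_length[sl]) == [3, 3, 3, 4, 4, 4, 4, 4]
        assert list(idx.telomere_margin[sl]) == [True] + [False] * 6 + [True]
        assert np.all(idx.d_cen <= idx.arm_length)

    @given(
        n_bins=st.integers(2, 40),
        cen_bin=st.integers(0, 39),
        last=st.integers(1, 32_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_tiling_conservation_property(self, n_bins, cen_bin, last):
        cen_bin = min(cen_bin, n_bins - 1)
        length = (n_bins - 1) * 32_000 + last
        cen = min(cen_bin * 32_000 + 1, length - 1)
        g = _two_parent([ChromosomeSpec("a", 1, length, cen)])
        idx = build_bin_index(g, 32_000)
        sl = idx.chrom_slice("a")
        assert int((idx.end[sl] - idx.start[sl]).sum()) == length
        assert np.all(idx.start[sl][1:] == idx.end[sl][:-1])

    def test_d_cen_orientation_symmetry(self):
        """Mirroring a chromosome end-for-end mirrors d_cen exactly."""
        L, cen = 10 * 32_000, 3 * 32_000 + 5_000
        fwd = _two_parent([ChromosomeSpec("a", 1, L, cen)])
        rev = _two_parent([ChromosomeSpec("a", 1, L, L - cen)])
        i_f = build_bin_index(fwd, 32_000)
        i_r = build_bin_index(rev, 32_000)
        sl = i_f.chrom_slice("a")
        assert list(i_f.d_cen[sl]) == list(i_r.d_cen[sl])[::-1]

    def test_empty_genome_rejected(self):
        with pytest.raises(GenomeConfigError):
            HybridGenomeSpec([])

    def test_single_parent_rejected(self):
        with pytest.raises(GenomeConfigError, match="parent 2"):
            HybridGenomeSpec([ChromosomeSpec("a", 1, 64_000, 30_000)])

    def test_rdna_containing_centromere_rejected(self):
        with pytest.raises(GenomeConfigError, match="centromere"):
            ChromosomeSpec("a", 1, 100_000, 40_000, rdna=(30_000, 50_000))

    def test_rdna_split_arm_length(self):
        g = _two_parent(
            [ChromosomeSpec("a", 1, 12 * 32_000, 2 * 32_000 + 10, rdna=(6 * 32_000, 8 * 32_000))]
        )
        split = build_bin_index(g, 32_000, split_rdna_arms=True)
        plain = build_bin_index(g, 32_000, split_rdna_arms=False)
        sl = split.chrom_slice("a")
        # bins 3..5 sit between the centromere (bin 2) and the rDNA (bins 6-7)
        assert list(split.arm_length[sl])[3:6] == [3, 3, 3]
        assert list(plain.arm_length[sl])[3:6] == [9, 9, 9]
        # d_cen never changes
        assert list(split.d_cen[sl]) == list(plain.d_cen[sl])


def _gene_row(pid, c1, s1, e1, c2, s2, e2):
    return {
        "pair_id": pid,
        "chrom_1": c1,
        "start_1": s1,
        "end_1": e1,
        "chrom_2": c2,
        "start_2": s2,
        "end_2": e2,
    }


class TestHomologCalling:
    def _genome(self):
        return HybridGenomeSpec(
            [
                ChromosomeSpec("a", 1, 160_000, 70_000),
                ChromosomeSpec("a2", 2, 160_000, 70_000),
                ChromosomeSpec("b2", 2, 96_000, 40_000),
            ]
        )

    def test_single_gene_pair(self):
        idx = build_bin_index(self._genome(), 32_000)
        table = HomologyTable(
            pd.DataFrame([_gene_row("g1", "a", 10_000, 12_000, "a2", 40_000, 42_000)])
        )
        hmap = call_homologous_bins(table, idx, prune_isolated=False)
        assert hmap.n_pairs == 1
        b1, b2 = hmap.pairs[0]
        assert (idx.chrom_of(b1), b1 - idx.chrom_offsets["a"]) == ("a", 0)
        assert (idx.chrom_of(b2), b2 - idx.chrom_offsets["a2"]) == ("a2", 1)

    def test_vote_tie_breaks_to_lowest_bin(self):
        idx = build_bin_index(self._genome(), 32_000)
        rows = [
            # two votes for a2 bin 3 (both gene ends inside bin 3 of parent-1 too)
            _gene_row("g1", "a", 97_000, 99_000, "a2", 97_000, 99_000),
            # two votes for b2 bin 1 from the same parent-1 bin
            _gene_row("g2", "a", 100_000, 102_000, "b2", 33_000, 35_000),
        ]
        hmap = call_homologous_bins(HomologyTable(pd.DataFrame(rows)), idx, prune_isolated=False)
        assert hmap.n_pairs == 1
        b1, b2 = hmap.pairs[0]
        assert idx.chrom_of(b1) == "a"
        # tie (2 votes each) resolved to the lowest global parent-2 bin id
        assert b2 == min(
            idx.chrom_offsets["a2"] + 3, idx.chrom_offsets["b2"] + 1
        )

    def test_isolated_pair_pruned(self):
        idx = build_bin_index(self._genome(), 32_000)
        rows = [
            _gene_row("g0", "a", 1_000, 2_000, "a2", 1_000, 2_000),
            _gene_row("g1", "a", 33_000, 34_000, "a2", 33_000, 34_000),
            # isolated: Chebyshev distance 3 from the nearest other pair
            _gene_row("g2", "a", 130_000, 131_000, "a2", 130_000, 131_000),
        ]
        pruned = call_homologous_bins(HomologyTable(pd.DataFrame(rows)), idx, prune_isolated=True)
        kept = call_homologous_bins(HomologyTable(pd.DataFrame(rows)), idx, prune_isolated=False)
        assert kept.n_pairs == 3
        assert pruned.n_pairs == 2
        assert all(b1 - idx.chrom_offsets["a"] in (0, 1) for b1, _ in pruned.pairs)

    def test_identity_homology_yields_diagonal_and_no_pruning(self, polymer_world):
        hmap = polymer_world["hmap"]
        index = polymer_world["index"]
        n1 = index.n_bins // 2
        assert hmap.n_pairs == n1
        assert np.array_equal(hmap.pairs[:, 1] - hmap.pairs[:, 0], np.full(n1, n1))

    def test_exclusion_zone_buffer(self):
        idx = build_bin_index(self._genome(), 32_000)
        rows = [
            _gene_row("g0", "a", 1_000, 2_000, "a2", 1_000, 2_000),
            _gene_row("g1", "a", 33_000, 34_000, "a2", 33_000, 34_000),
        ]
        hmap = call_homologous_bins(HomologyTable(pd.DataFrame(rows)), idx, buffer=2)
        off1, off2 = idx.chrom_offsets["a"], idx.chrom_offsets["a2"]
        assert hmap.exclusion[off1 + 0, off2 + 0]  # the pair itself
        assert hmap.exclusion[off1 + 0, off2 + 2]  # within 2 bins
        assert hmap.exclusion[off1 + 3, off2 + 1]  # within 2 of pair (1,1)
        assert not hmap.exclusion[off1 + 4, off2 + 4]  # beyond the buffer
        # no spill onto the other parent-2 chromosome
        assert not hmap.exclusion[off1 + 0, idx.chrom_offsets["b2"] + 0]

    def test_brute_force_vote_oracle(self, rng):
        """Winner per parent-1 bin matches exhaustive vote counting."""
        idx = build_bin_index(self._genome(), 32_000)
        rows = []
        for k in range(40):
            s1 = int(rng.integers(0, 158_000))
            chrom2 = "a2" if rng.random() < 0.7 else "b2"
            lim = 158_000 if chrom2 == "a2" else 94_000
            s2 = int(rng.integers(0, lim))
            rows.append(_gene_row(f"g{k}", "a", s1, s1 + 1_000, chrom2, s2, s2 + 1_000))
        table = HomologyTable(pd.DataFrame(rows))
        hmap = call_homologous_bins(table, idx, prune_isolated=False)
        # independent oracle: count votes over every (bin1, bin2) pair
        votes: dict[tuple[int, int], int] = {}
        for _, r in table.frame.iterrows():
            for end in ("start", "end"):
                b1 = idx.bin_of(r["chrom_1"], r[f"{end}_1"])
                b2 = idx.bin_of(r["chrom_2"], r[f"{end}_2"])
                votes[(b1, b2)] = votes.get((b1, b2), 0) + 1
        expected = {}
        for b1 in {k[0] for k in votes}:
            cands = {b2: v for (a, b2), v in votes.items() if a == b1}
            best = max(cands.values())
            expected[b1] = min(b for b, v in cands.items() if v == best)
        assert {int(a): int(b) for a, b in hmap.pairs} == expected


class TestMappability:
    def test_all_unique_sequence(self, rng):
        # random 600-mer: all 80-mers unique with overwhelming probability
        seq = "".join(rng.choice(list("ACGT"), size=600))
        tracks = kmer_mappability({"a": seq}, read_length=80, step=10)
        starts, scores = tracks["a"]
        assert np.all(scores == 1.0)
        assert starts[1] - starts[0] == 10

    def test_duplicated_segment_scores_zero(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=200))
        seq = "".join(rng.choice(list("ACGT"), size=150)) + core + "".join(
            rng.choice(list("ACGT"), size=150)
        )
        tracks = kmer_mappability({"a": seq, "b": core}, read_length=80, step=10)
        starts, scores = tracks["a"]
        inside = (starts >= 150) & (starts + 80 <= 350)
        assert np.all(scores[inside] == 0.0)

    def test_reverse_complement_counts_as_occurrence(self):
        fwd = "ACGTTGCAACGGATCCTAGG" * 5
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        tracks = kmer_mappability({"a": fwd, "b": rc}, read_length=20, step=20)
        assert np.all(tracks["a"][1] == 0.0)

    def test_non_acgt_window_scored_zero(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:100] + "N" + seq[101:]
        tracks = kmer_mappability({"a": seq}, read_length=80, step=10)
        starts, scores = tracks["a"]
        covered = (starts <= 100) & (starts + 80 > 100)
        assert np.all(scores[covered] == 0.0)
        assert np.all(scores[~covered] == 1.0)

    def test_per_bin_aggregation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=64_000))
        g = HybridGenomeSpec(
            [ChromosomeSpec("a", 1, 64_000, 30_000), ChromosomeSpec("a2", 2, 64_000, 30_000)]
        )
        idx = build_bin_index(g, 32_000)
        tracks = kmer_mappability({"a": seq}, read_length=80, step=1000)
        by_bin = mappability_by_bin(tracks, idx)
        assert by_bin[idx.chrom_offsets["a"]] == 1.0
        assert np.isnan(by_bin[idx.chrom_offsets["a2"]])
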