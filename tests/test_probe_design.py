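"""Probe design rules: identity windows, exon boundaries, high-copy
masking, and uniform probe tiling."""

import itertools

import numpy as np
import pytest

from ahekit.probe_design import (LocusAlignment, TargetRegion,
                                 UndefinedIdentityError, find_exon_boundaries,
                                 mask_high_copy, pairwise_identity,
                                 probe_coverage, select_targets, tile_probes)
from conftest import random_seq


class TestPairwiseIdentity:
    def test_identical_rows(self):
        assert pairwise_identity(["ACGT" * 30] * 2) == 100.0

    def test_half_matching(self):
        assert pairwise_identity(["AAAA", "AATT"]) == 50.0

    def test_gap_columns_excluded(self):
        # pair comparison ignores the gapped column: 3 of 3 match
        assert pairwise_identity(["AC-T", "ACGT"]) == 100.0

    def test_single_row_rejected(self):
        with pytest.raises(UndefinedIdentityError):
            pairwise_identity(["ACGT"])

    def test_matches_brute_force_pair_loop(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), 60)) for _ in range(6)]
        vals = []
        for a, b in itertools.combinations(rows, 2):
            m = n = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                n += 1
                m += x == y
            if n:
                vals.append(100.0 * m / n)
        assert pairwise_identity(rows) == pytest.approx(np.mean(vals))


class TestExonBoundaries:
    def test_contiguous_substring_no_boundary(self, rng):
        genome = random_seq(rng, 2000)
        boundaries, unknown = find_exon_boundaries(genome[300:800], genome)
        assert boundaries == []
        assert unknown == []

    def test_spliced_transcript_single_boundary(self, rng):
        genome = random_seq(rng, 2000)
        transcript = genome[0:200] + genome[1000:1200]
        boundaries, _ = find_exon_boundaries(transcript, genome)
        assert boundaries == [200]

    def test_no_match_reports_unknown(self, rng):
        transcript = random_seq(rng, 100)
        genome = random_seq(rng, 500)
        boundaries, unknown = find_exon_boundaries(transcript, genome)
        assert boundaries == []
        assert unknown == [(0, 100)]

    def test_short_transcript_rejected(self):
        with pytest.raises(ValueError):
            find_exon_boundaries("ACGT", "ACGT" * 100)


class TestSelectTargets:
    def make_aln(self, rows, locus="L1"):
        return LocusAlignment(locus=locus,
                              taxa=[f"t{i}" for i in range(len(rows))],
                              rows=rows)

    def test_five_taxa_rejected(self):
        aln = self.make_aln(["A" * 200] * 5)
        assert select_targets(aln) == []

    def test_six_identical_taxa_one_target(self, rng):
        seq = random_seq(rng, 200)
        aln = self.make_aln([seq] * 6)
        targets = select_targets(aln)
        assert len(targets) == 1
        assert (targets[0].start, targets[0].end) == (0, 200)

    def test_gap_column_splits_region(self, rng):
        seq = random_seq(rng, 400)
        rows = [seq] * 5 + [seq[:200] + "-" + seq[201:]]
        targets = select_targets(self.make_aln(rows))
        assert [(t.start, t.end) for t in targets] == [(0, 200), (201, 400)]

    def test_exon_boundary_splits_region(self, rng):
        seq = random_seq(rng, 400)
        targets = select_targets(self.make_aln([seq] * 6),
                                 boundaries={"t0": [180]})
        assert [(t.start, t.end) for t in targets] == [(0, 180), (180, 400)]

    def test_identity_exactly_at_threshold_rejected(self):
        # every 120bp window of this 2-row-type alignment has exactly 50%
        # identity between differing rows -> mean pairwise identity must be
        # computed and the strict > rule applied
        a = "ACGT" * 50
        b = "".join(c if i % 2 == 0 else "ACGT"[("ACGT".index(c) + 1) % 4]
                    for i, c in enumerate(a))
        rows = [a] * 3 + [b] * 3
        # mean pairwise identity per window: pairs aa and bb are 100%, ab 50%
        # -> mean (3*100 + 3*100*0 ... ) compute directly:
        ident = pairwise_identity([r[:120] for r in rows])
        rows_all_b = [b] * 6
        assert select_targets(self.make_aln(rows_all_b),
                              min_ident=100.0) == []
        # boundary case: min_ident set to the exact achieved value -> reject
        assert select_targets(self.make_aln(rows), min_ident=ident) == []
        # just below -> accept
        assert len(select_targets(self.make_aln(rows),
                                  min_ident=ident - 0.01)) == 1

    def test_short_region_rejected(self, rng):
        seq = random_seq(rng, 140)
        assert select_targets(self.make_aln([seq] * 6)) == []

    def test_accepted_targets_satisfy_all_rules(self, rng):
        # independent re-check of every selection rule
        for _ in range(10):
            seq = random_seq(rng, 500)
            rows = []
            for _ in range(7):
                row = list(seq)
                for p in rng.integers(0, 500, 30):
                    row[p] = "ACGT"[rng.integers(0, 4)]
                if rng.random() < 0.5:
                    row[rng.integers(0, 500)] = "-"
                rows.append("".join(row))
            aln = self.make_aln(rows)
            bounds = {"t0": [int(rng.integers(0, 500))]}
            for t in select_targets(aln, boundaries=bounds):
                assert t.length >= 150
                assert len(aln.rows) >= 6
                sub = aln.slice(t.start, t.end)
                assert all("-" not in r for r in sub)
                assert not any(t.start < b < t.end for b in bounds["t0"])
                best = max(pairwise_identity(aln.slice(w, w + 120))
                           for w in range(t.start, t.end - 119))
                assert best > 50.0


class TestMaskHighCopy:
    def test_unique_genome_no_masking(self, rng):
        seq = random_seq(rng, 100)
        genome = random_seq(rng, 3000)
        assert mask_high_copy(seq, genome, count_threshold=2) == set()

    def test_tandem_repeat_masks_its_positions(self, rng):
        seq = random_seq(rng, 100)
        repeat = seq[40:55]                      # one 15-mer of the alignment
        genome = random_seq(rng, 500) + repeat * 60 + random_seq(rng, 500)
        masked = mask_high_copy(seq, genome, count_threshold=50)
        assert set(range(40, 55)) <= masked
        # positions far from the repeat stay unmasked
        assert not masked & set(range(0, 25))

    def test_hamming1_neighborhood_counts(self, rng):
        seq = random_seq(rng, 30)
        kmer = seq[5:20]
        mutant = ("A" if kmer[7] != "A" else "C").join([kmer[:7], kmer[8:]])
        genome = mutant * 80                     # only 1-off copies present
        masked = mask_high_copy(seq, genome, count_threshold=40)
        assert set(range(5, 20)) <= masked

    def test_threshold_monotonicity(self, rng):
        seq = random_seq(rng, 60)
        genome = random_seq(rng, 1000) + seq[10:25] * 30
        low = mask_high_copy(seq, genome, count_threshold=5)
        high = mask_high_copy(seq, genome, count_threshold=20)
        assert high <= low

    def test_short_sequence_no_masking(self, rng):
        assert mask_high_copy("ACGTACGT", random_seq(rng, 100),
                              count_threshold=1) == set()


def region(L, locus="L1"):
    return TargetRegion(locus=locus, start=0, end=L, taxa=["a"],
                       min_identity=100.0, mean_identity=100.0)


class TestTileProbes:
    def test_exact_probe_length_region(self, rng):
        seq = random_seq(rng, 120)
        ps = tile_probes(region(120), "t", seq)
        assert len(ps.probes) == 1
        assert ps.probes[0].sequence == seq

    def test_189bp_region_two_probes(self, rng):
        seq = random_seq(rng, 189)
        ps = tile_probes(region(189), "t", seq)
        assert [p.start for p in ps.probes] == [0, 69]

    def test_probes_stay_inside_region(self, rng):
        for L in (120, 200, 500, 1234):
            seq = random_seq(rng, L)
            ps = tile_probes(region(L), "t", seq)
            assert ps.probes[0].start == 0
            assert ps.probes[-1].start + 120 == L
            assert all(0 <= p.start <= L - 120 for p in ps.probes)

    def test_short_region_no_probes(self, rng):
        assert tile_probes(region(100), "t", random_seq(rng, 100)).probes == []

    def test_density_converges_for_long_regions(self, rng):
        covs = []
        for L in range(1200, 5200, 200):
            seq = random_seq(rng, L)
            covs.append(probe_coverage(tile_probes(region(L), "t", seq),
                                       region(L)))
        assert abs(np.mean(covs) - 1.72) / 1.72 < 0.05
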