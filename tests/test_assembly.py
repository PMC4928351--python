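"""Assembly: spaced-k-mer seeding, divergent mapping, 60-mer clustering,
offset refinement and binomial consensus calling."""

import math

import numpy as np
import pytest

from ahekit._seq import BASES, revcomp
from ahekit.assembly import (PATTERN, SPACED_SPAN, AssemblyCluster,
                             ClusterRead, ReferenceLibrary, build_library,
                             call_consensus, cluster_reads, map_read,
                             recruit_reads, refine_offsets, spaced_kmer_match)
from conftest import random_seq


def single_locus_library(seq, anchor_positions):
    chars = np.stack([np.array([BASES.index(seq[p + d]) for d in PATTERN],
                               dtype=np.int8) for p in anchor_positions])
    return ReferenceLibrary(loci=["LX"], refs={"LX": seq},
                            ref_start={"LX": 0}, kmer_chars=chars,
                            kmer_locus=np.zeros(len(anchor_positions), int),
                            kmer_offset=np.array(anchor_positions))


def mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = BASES[(BASES.index(out[p]) + 1) % 4]
    return "".join(out)


class TestSpacedKmerMatch:
    def test_exact_read_hits(self, rng):
        ref = random_seq(rng, 400)
        lib = single_locus_library(ref, [100])
        read = ref[80:230]
        hits = spaced_kmer_match(read, lib)
        assert ("LX", 80, 20) in hits

    def test_17_of_20_at_threshold(self, rng):
        ref = random_seq(rng, 400)
        lib = single_locus_library(ref, [100])
        read = mutate_at(ref[80:230], [20 + int(d) for d in PATTERN[:3]])
        hits = spaced_kmer_match(read, lib)
        assert any(h[2] == 17 for h in hits if h[1] == 80)

    def test_16_of_20_no_hit(self, rng):
        ref = random_seq(rng, 400)
        lib = single_locus_library(ref, [100])
        read = mutate_at(ref[80:230], [20 + int(d) for d in PATTERN[:4]])
        assert all(not (h[1] == 80 and h[2] >= 17)
                   for h in spaced_kmer_match(read, lib))
        assert spaced_kmer_match(read, lib, min_hits=16)

    def test_off_pattern_substitutions_ignored(self, rng):
        ref = random_seq(rng, 400)
        lib = single_locus_library(ref, [100])
        off_pattern = [20 + int(d) + 1 for d in PATTERN[:5]]
        read = mutate_at(ref[80:230], off_pattern)
        assert any(h[2] == 20 for h in spaced_kmer_match(read, lib))


def brute_force_map(read, reference, window=100):
    """Independent all-offset scorer in plain Python."""
    lr, lf = len(read), len(reference)
    best_score, best_off = -1, None
    for off in range(-(lr - 1), lf):
        matches = []
        for i in range(lr):
            p = off + i
            matches.append(1 if 0 <= p < lf and read[i] == reference[p] else 0)
        if lr <= window:
            score = sum(matches)
        else:
            score = max(sum(matches[s:s + window])
                        for s in range(lr - window + 1))
        if score > best_score:
            best_score, best_off = score, off
    return best_score, best_off


class TestMapRead:
    def test_identical_slice_maps_perfectly(self, rng):
        ref = random_seq(rng, 600)
        ok, off, score = map_read(ref[100:250], ref)
        assert ok and off == 100 and score == 100

    def test_54_matches_unmapped_55_mapped(self, rng):
        ref = random_seq(rng, 300)
        read = mutate_at(ref[50:200], range(0, 92, 2))  # 46 errors in 100bp
        _, _, score = map_read(read, ref)
        exp, _ = brute_force_map(read, ref)
        assert score == exp
        read54 = mutate_at(ref[50:200], range(46))      # 54/100 best window
        ok, _, sc = map_read(read54, ref)
        assert sc == brute_force_map(read54, ref)[0]
        if sc == 54:
            assert not ok

    def test_divergent_ortholog_maps_around_60(self, rng):
        ref = random_seq(rng, 400)
        read = "".join(c if rng.random() > 0.4 else "ACGT"[rng.integers(0, 4)]
                       for c in ref[100:250])
        ok, off, score = map_read(read, ref)
        exp_score, exp_off = brute_force_map(read, ref)
        assert score == exp_score
        assert 50 <= score <= 85

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            lf = int(rng.integers(150, 400))
            lr = int(rng.integers(60, 200))
            ref = random_seq(rng, lf)
            if rng.random() < 0.5:
                start = int(rng.integers(0, lf - min(lr, lf - 1)))
                read = ref[start:start + lr]
                read = mutate_at(read, rng.choice(len(read),
                                                  size=len(read) // 10,
                                                  replace=False))
            else:
                read = random_seq(rng, lr)
            exp_score, exp_off = brute_force_map(read, ref)
            ok, off, score = map_read(read, ref)
            assert score == exp_score
            assert off == exp_off
            assert ok == (score >= 55)


def make_reads_from(hap, rng, depth=20, read_len=150, frag=(150, 300),
                    prefix="r"):
    reads = []
    n = int(depth * len(hap) / np.mean(frag))
    for i in range(n):
        fl = min(int(rng.integers(*frag)), len(hap))
        s = int(rng.integers(0, len(hap) - fl + 1))
        seq = hap[s:s + fl]
        seq = seq if rng.random() < 0.5 else revcomp(seq)
        reads.append((f"{prefix}{i}", seq[:max(read_len, fl)]))
    return reads


class TestAssembleLocus:
    def test_single_locus_single_cluster(self, rng):
        ref = random_seq(rng, 500)
        lib = build_library({"LX": [ref]}, conserved_min=0.5)
        reads = make_reads_from(ref, rng, depth=20)
        assigned = recruit_reads(reads, lib)
        assert len(assigned) == len(reads)
        clusters = cluster_reads(reads, assigned, "ind1")
        big = [c for c in clusters if c.n_reads >= 2]
        assert len(big) == 1
        assert big[0].n_reads == len(reads)

    def test_duplicated_locus_two_clusters(self, rng):
        rng = np.random.default_rng(77)
        ref = random_seq(rng, 600)
        copy = mutate_at(ref, rng.choice(600, size=60, replace=False))
        lib = build_library({"LX": [ref]}, conserved_min=0.5)
        reads = (make_reads_from(ref, rng, depth=15, prefix="a")
                 + make_reads_from(copy, rng, depth=15, prefix="b"))
        assigned = recruit_reads(reads, lib)
        clusters = [c for c in cluster_reads(reads, assigned, "ind1")
                    if c.n_reads >= 10]
        assert len(clusters) == 2
        for c in clusters:
            sources = {r.id[0] for r in c.reads}
            assert len(sources) == 1           # no chimeric cluster

    def test_flanks_extend_past_reference(self, rng):
        locus = random_seq(rng, 700)
        anchor = locus[200:500]                # reference covers core only
        lib = build_library({"LX": [anchor]}, conserved_min=0.5)
        reads = make_reads_from(locus, rng, depth=25)
        assigned = recruit_reads(reads, lib)
        clusters = cluster_reads(reads, assigned, "ind1")
        big = max(clusters, key=lambda c: c.n_reads)
        lo, hi = big.span
        assert lo < 0 and hi > len(anchor)     # de novo walked into flanks
        assert big.n_reads > 0.9 * len(reads)

    def test_contaminants_stay_unrecruited(self, rng):
        ref = random_seq(rng, 500)
        lib = build_library({"LX": [ref]}, conserved_min=0.5)
        reads = make_reads_from(ref, rng, depth=10)
        n_target = len(reads)
        for i in range(20):
            reads.append((f"c{i}", random_seq(rng, 150)))
        assigned = recruit_reads(reads, lib)
        contam_recruited = [i for i in assigned if reads[i][0].startswith("c")]
        assert contam_recruited == []
        assert len(assigned) == n_target


class TestRefineOffsets:
    def cluster_from(self, hap, offsets, length=80):
        reads = [ClusterRead(f"r{i}", hap[o:o + length], o)
                 for i, o in enumerate(offsets)]
        return AssemblyCluster("LX", "ind", reads)

    def test_perfect_cluster_is_fixed_point(self, rng):
        hap = random_seq(rng, 300)
        cl = self.cluster_from(hap, range(0, 200, 10))
        before = [(r.offset, r.gap_pos) for r in cl.reads]
        refine_offsets(cl)
        assert [(r.offset, r.gap_pos) for r in cl.reads] == before

    def test_misplaced_read_shifted_back(self, rng):
        hap = random_seq(rng, 300)
        cl = self.cluster_from(hap, range(0, 200, 10))
        cl.reads[5].offset += 1                 # plant a 1bp misplacement
        refine_offsets(cl)
        assert cl.reads[5].offset == 50
        assert cl.reads[5].gap_pos is None

    def test_deletion_read_gets_one_gap(self, rng):
        hap = random_seq(rng, 300)
        cl = self.cluster_from(hap, range(0, 200, 10))
        # one read from a haplotype with a 1bp deletion at its position 40
        seq = cl.reads[5].seq
        cl.reads[5] = ClusterRead("del", seq[:40] + seq[41:] + hap[130:131], 50)
        refine_offsets(cl)
        assert cl.reads[5].gap_pos is not None


def oracle_consensus_base(counts, p_err=0.1, alpha=0.05, mask_cov=5):
    """Independent binomial-tail classifier via explicit pmf summation."""
    from ahekit._seq import IUPAC_FOR

    def tail(k, n):
        return sum(math.comb(n, i) * p_err**i * (1 - p_err) ** (n - i)
                   for i in range(k, n + 1)) if k > 0 else 1.0

    n = sum(counts.values())
    if n == 0:
        return "n"
    maj = max(sorted(counts), key=counts.get)
    m = counts[maj]
    if m == n or tail(n - m, n) >= alpha:
        call = maj
    else:
        members = {maj} | {b for b, k in counts.items()
                           if k > 0 and tail(k, n) < alpha}
        call = IUPAC_FOR[frozenset(members)]
    return call.lower() if n < mask_cov else call


def cluster_for_column(counts):
    """One-column cluster: each read contributes one base at offset 0."""
    reads = []
    i = 0
    for b, k in counts.items():
        for _ in range(k):
            reads.append(ClusterRead(f"r{i}", b, 0))
            i += 1
    return AssemblyCluster("LX", "ind", reads)


class TestCallConsensus:
    @pytest.mark.parametrize("counts,expected", [
        ({"A": 10}, "A"),
        ({"A": 9, "C": 1}, "A"),              # explainable as error
        ({"A": 5, "C": 5}, "M"),              # significant polymorphism
        ({"A": 4}, "a"),                      # below coverage-5 soft mask
        ({"A": 3, "C": 3}, "M"),              # coverage 6: no soft mask
        # coverage 4: P(X>=2|4,0.1)=0.052 >= alpha -> majority, soft-masked,
        # tie broken to the lexicographically smaller base
        ({"A": 2, "C": 2}, "a"),
        ({"A": 30, "C": 6, "G": 1}, "A"),
    ])
    def test_known_profiles(self, counts, expected):
        cons = call_consensus(cluster_for_column(counts))
        assert cons.seq == expected

    def test_matches_binomial_oracle_on_random_profiles(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 40))
            draws = rng.choice(list("ACGT"), size=n,
                               p=[0.55, 0.25, 0.15, 0.05])
            counts = {b: int((draws == b).sum()) for b in "ACGT"
                      if (draws == b).sum() > 0}
            got = call_consensus(cluster_for_column(counts)).seq
            assert got == oracle_consensus_base(counts)

    def test_end_to_end_error_free_consensus_equals_truth(self, rng):
        hap = random_seq(rng, 500)
        lib = build_library({"LX": [hap]}, conserved_min=0.5)
        reads = make_reads_from(hap, rng, depth=20)
        assigned = recruit_reads(reads, lib)
        clusters = cluster_reads(reads, assigned, "ind1")
        big = max(clusters, key=lambda c: c.n_reads)
        refine_offsets(big)
        cons = call_consensus(big)
        for i, c in enumerate(cons.seq):
            if c.isupper():
                assert c == hap[cons.start + i]

    def test_coverage_vector_matches_mask(self, rng):
        hap = random_seq(rng, 400)
        lib = build_library({"LX": [hap]}, conserved_min=0.5)
        reads = make_reads_from(hap, rng, depth=8)
        assigned = recruit_reads(reads, lib)
        big = max(cluster_reads(reads, assigned, "i"),
                  key=lambda c: c.n_reads)
        cons = call_consensus(refine_offsets(big))
        for c, cov in zip(cons.seq, cons.coverage):
            assert c.islower() == (cov < 5)
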