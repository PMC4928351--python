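"""Hybrid reference/de-novo assembly of enriched reads into locus consensus.

Two levels of read recruitment run together until a fixed point: (1) a
divergent-reference mapper seeds reads onto probe-region references — a
preliminary hit needs 17/20 positional matches against a spaced 20-mer
(every third base, 58 bp span) anchored at conserved design-alignment
sites, confirmed by >= 55 matches within the best 100 consecutive bases
over all gap-free offsets; (2) a de-novo extender recruits any read
sharing an exact 60-mer with an already-placed read, which is how the
assembly walks out of the probe region into the flanks.

Placed reads are clustered through their 60-mers (two 60-mers join when
they co-occur in at least two reads), offsets are refined by greedy
agreement maximization with at most one gap per read, and a consensus is
called per cluster under a binomial sequencing-error model (p_err = 0.1,
alpha = 0.05) with IUPAC ambiguity codes and lowercase soft-masking of
sites below 5x coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import binom

from ._seq import BASES, IUPAC_FOR, encode, revcomp

log = logging.getLogger(__name__)

SPACED_K = 20
SPACED_STEP = 3
SPACED_SPAN = (SPACED_K - 1) * SPACED_STEP + 1    # 58 bp
PATTERN = np.arange(SPACED_K) * SPACED_STEP
DENOVO_K = 60


@dataclass
class ReferenceLibrary:
    """Per-locus references plus a spaced 20-mer index at conserved sites."""

    loci: list                      # locus ids, index order
    refs: dict                      # locus -> reference string
    ref_start: dict                 # locus -> offset of reference within locus coords
    kmer_chars: np.ndarray          # (K, 20) int8
    kmer_locus: np.ndarray          # (K,) index into loci
    kmer_offset: np.ndarray         # (K,) reference offset of the k-mer start
    refs_enc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.refs_enc = {loc: encode(s) for loc, s in self.refs.items()}


def consensus_of_alignment(rows: list) -> str:
    """Plain majority consensus of equal-length rows (ties lexicographic)."""
    arrs = np.stack([encode(r) for r in rows])
    out = []
    for col in arrs.T:
        counts = np.bincount(col[col < 4], minlength=4)
        out.append(BASES[int(counts.argmax())] if counts.sum() else "N")
    return "".join(out)


def conserved_columns(rows: list, min_freq: float = 0.9) -> np.ndarray:
    """Boolean mask of columns whose modal base frequency >= min_freq."""
    arrs = np.stack([encode(r) for r in rows])
    n = len(rows)
    out = np.zeros(arrs.shape[1], dtype=bool)
    for j in range(arrs.shape[1]):
        col = arrs[:, j]
        counts = np.bincount(col[col < 4], minlength=4)
        out[j] = counts.max() >= min_freq * n
    return out


def build_library(design_alignments: dict, conserved_min: float = 0.9,
                  anchor_spacing: int = 10, min_anchors: int = 3,
                  region: dict | None = None) -> ReferenceLibrary:
    """Build the mapping reference library from design alignments.

    design_alignments: locus -> list of aligned sequences (the alignments
    used for probe design). The reference is their majority consensus;
    spaced 20-mers are anchored at positions where all 20 sampled columns
    are conserved (modal base frequency >= conserved_min), thinned to one
    anchor per ``anchor_spacing`` bp. When a locus yields fewer than
    ``min_anchors`` anchors at that threshold, the threshold is relaxed
    in 0.1 steps (floor 0.5) for that locus — every locus must be
    mappable, and real probe regions are conserved by construction.
    ``region`` optionally restricts each locus to a column interval
    (locus -> (start, end)), mimicking a probe-region reference whose
    flanks must be assembled de novo.
    """
    loci = sorted(design_alignments)
    refs, ref_start = {}, {}
    chars, klocus, koffset = [], [], []
    for li, locus in enumerate(loci):
        rows = design_alignments[locus]
        if hasattr(rows, "rows"):           # LocusAlignment duck-typing
            rows = rows.rows
        start, end = (region or {}).get(locus, (0, len(rows[0])))
        rows = [r[start:end] for r in rows]
        ref = consensus_of_alignment(rows)
        refs[locus] = ref
        ref_start[locus] = start
        enc = encode(ref)
        threshold = conserved_min
        anchors = []
        while True:
            cons = conserved_columns(rows, threshold)
            anchors = []
            last = -(10**9)
            for p in range(0, len(ref) - SPACED_SPAN + 1):
                cols = p + PATTERN
                if cons[cols].all() and p - last >= anchor_spacing:
                    anchors.append(p)
                    last = p
            if len(anchors) >= min_anchors or threshold <= 0.5:
                break
            threshold = round(threshold - 0.1, 10)
        if len(anchors) < min_anchors:
            log.warning("locus %s: only %d spaced-kmer anchors even at "
                        "threshold %.1f", locus, len(anchors), threshold)
        for p in anchors:
            chars.append(enc[p + PATTERN])
            klocus.append(li)
            koffset.append(p)
    if not chars:
        raise ValueError("no conserved anchors found; lower conserved_min")
    return ReferenceLibrary(
        loci=loci, refs=refs, ref_start=ref_start,
        kmer_chars=np.stack(chars), kmer_locus=np.array(klocus),
        kmer_offset=np.array(koffset))


def spaced_kmer_match(read: str, library: ReferenceLibrary,
                      min_hits: int = 17) -> list:
    """Preliminary locus hits of a read against the spaced 20-mer index.

    Returns [(locus, estimated_ref_offset, n_matching_positions), ...] for
    every (read position, indexed k-mer) pair with >= min_hits of the 20
    sampled positions matching. The read is used as given; callers try
    both orientations.
    """
    enc = encode(read)
    n_pos = len(read) - SPACED_SPAN + 1
    if n_pos < 1:
        return []
    pos = np.arange(n_pos)
    gathered = enc[pos[:, None] + PATTERN[None, :]]             # (P, 20)
    counts = (gathered[:, None, :] == library.kmer_chars[None, :, :]).sum(axis=2)
    hits = []
    for p, k in zip(*np.nonzero(counts >= min_hits)):
        locus = library.loci[library.kmer_locus[k]]
        hits.append((locus, int(library.kmer_offset[k]) - int(p),
                     int(counts[p, k])))
    return hits


def map_read(read: str, reference: str, min_matches: int = 55,
             window: int = 100):
    """Best gap-free placement of a read on a reference.

    Considers every gap-free offset; the score of an offset is the
    maximum number of matches within any ``window`` consecutive aligned
    bases (the whole overlap when shorter). Returns
    (mapped, best_offset, best_score) with mapped = score >= min_matches;
    ties go to the smallest offset.
    """
    r = encode(read).astype(np.int8)
    ref = encode(reference).astype(np.int8)
    lr, lf = r.size, ref.size
    if lr == 0 or lf == 0:
        return False, 0, 0
    r = np.where(r == 4, 5, r)          # N never matches
    pad = np.full(lr, 6, dtype=np.int8)
    padded = np.concatenate([pad, ref, pad])
    views = sliding_window_view(padded, lr)      # offset o -> views[o + lr]
    m = (views == r[None, :]).astype(np.int32)   # (lf + lr + 1, lr)
    if lr <= window:
        scores = m.sum(axis=1)
    else:
        c = np.cumsum(m, axis=1)
        c = np.concatenate([np.zeros((m.shape[0], 1), dtype=np.int32), c], axis=1)
        scores = (c[:, window:] - c[:, :-window]).max(axis=1)
    best = int(scores.argmax())                  # argmax -> smallest offset
    return bool(scores[best] >= min_matches), best - lr, int(scores[best])


@dataclass
class ClusterRead:
    id: str
    seq: str            # stored in assembled orientation
    offset: int         # absolute reference coordinate of first base
    gap_pos: int | None = None   # 0-based read position carrying one gap

    def columns(self):
        """Yield (column, base_index) for ACGT bases of this read."""
        enc = encode(self.seq)
        g = self.gap_pos
        for i, b in enumerate(enc):
            if b >= 4:
                continue
            col = self.offset + i + (1 if g is not None and i >= g else 0)
            yield col, int(b)


@dataclass
class AssemblyCluster:
    locus: str
    individual: str
    reads: list                       # list[ClusterRead]

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def span(self):
        lo = min(r.offset for r in self.reads)
        hi = max(r.offset + len(r.seq) + (1 if r.gap_pos is not None else 0)
                 for r in self.reads)
        return lo, hi


@dataclass
class ConsensusSequence:
    locus: str
    individual: str
    seq: str                         # lowercase = soft-masked (coverage < 5)
    coverage: np.ndarray
    n_reads: int
    start: int                       # reference coordinate of first base

    def __post_init__(self):
        assert len(self.seq) == len(self.coverage)


def _kmers(seq: str, k: int = DENOVO_K):
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]


def recruit_reads(reads: list, library: ReferenceLibrary, min_hits: int = 17,
                  min_matches: int = 55, max_passes: int = 25) -> dict:
    """Assign reads to loci by mapping + iterative 60-mer extension.

    ``reads`` is a list of (id, seq). Returns
    {read_index: (locus, orientation, offset, oriented_seq)}. Passes over
    the unassigned reads repeat until a full pass recruits nothing; the
    recruited set only ever grows.
    """
    assigned: dict[int, tuple] = {}
    kmer_table: dict[str, tuple] = {}        # 60-mer -> (locus, abs position)
    map_cache: dict[int, tuple | None] = {}  # read idx -> mapping result

    def reference_placement(seq):
        best = None
        for orient in "+-":
            s = seq if orient == "+" else revcomp(seq)
            cands = {}
            for locus, est, nh in spaced_kmer_match(s, library, min_hits):
                cands[locus] = max(cands.get(locus, 0), nh)
            for locus in cands:
                ok, off, score = map_read(s, library.refs[locus], min_matches)
                if ok and (best is None or score > best[0]):
                    best = (score, locus, orient, off, s)
        if best is None:
            return None
        _, locus, orient, off, s = best
        return locus, orient, off, s

    def place(idx, locus, orient, off, s):
        assigned[idx] = (locus, orient, off, s)
        for p, km in _kmers(s):
            kmer_table.setdefault(km, (locus, off + p))

    for _ in range(max_passes):
        progress = False
        for idx, (rid, seq) in enumerate(reads):
            if idx in assigned:
                continue
            placed = False
            for orient in "+-":
                s = seq if orient == "+" else revcomp(seq)
                votes: dict[tuple, int] = {}
                for p, km in _kmers(s):
                    hit = kmer_table.get(km)
                    if hit is not None:
                        locus, abspos = hit
                        key = (locus, abspos - p)
                        votes[key] = votes.get(key, 0) + 1
                if votes:
                    (locus, off), _n = max(votes.items(),
                                           key=lambda kv: (kv[1], kv[0][1]))
                    place(idx, locus, orient, off, s)
                    placed = True
                    break
            if not placed:
                if idx not in map_cache:
                    map_cache[idx] = reference_placement(seq)
                res = map_cache[idx]
                if res is not None:
                    place(idx, *res)
                    placed = True
            progress = progress or placed
        if not progress:
            break
    else:
        log.warning("read recruitment did not reach a fixed point in %d passes",
                    max_passes)
    return assigned


def cluster_reads(reads: list, assigned: dict, individual: str) -> list:
    """Partition recruited reads of one individual into assembly clusters.

    Within each locus, 60-mers are joined when a pair of them co-occurs
    in at least two reads (union-find); each read goes to the component
    holding the majority of its 60-mers (ties to the largest component);
    reads sharing no component become singleton clusters.
    """
    by_locus: dict[str, list] = {}
    for idx, (locus, orient, off, s) in assigned.items():
        by_locus.setdefault(locus, []).append(
            ClusterRead(id=reads[idx][0], seq=s, offset=off))
    clusters = []
    for locus in sorted(by_locus):
        members = sorted(by_locus[locus], key=lambda r: (r.offset, r.id))
        kmer_sets = [frozenset(km for _, km in _kmers(r.seq)) for r in members]
        parent: dict[str, str] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            parent.setdefault(x, x)
            parent.setdefault(y, y)
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[ry] = rx

        # overlapping read pairs (by offset) are the only ones that can
        # share 60-mers barring exact intra-locus repeats
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].offset - members[i].offset >= len(members[i].seq):
                    break
                shared = kmer_sets[i] & kmer_sets[j]
                if len(shared) >= 2:
                    it = iter(sorted(shared))
                    first = next(it)
                    parent.setdefault(first, first)
                    for km in it:
                        union(first, km)
        comp_size: dict[str, int] = {}
        for km in parent:
            comp_size[find(km)] = comp_size.get(find(km), 0) + 1
        groups: dict[str, list] = {}
        for i, r in enumerate(members):
            votes: dict[str, int] = {}
            for km in kmer_sets[i]:
                if km in parent:
                    c = find(km)
                    votes[c] = votes.get(c, 0) + 1
            if votes:
                comp = max(votes, key=lambda c: (votes[c], comp_size.get(c, 0), c))
                groups.setdefault(comp, []).append(r)
            else:
                groups.setdefault(f"singleton:{r.id}", []).append(r)
        for key in sorted(groups):
            clusters.append(AssemblyCluster(locus=locus, individual=individual,
                                            reads=groups[key]))
    return clusters


def _profile_of(cluster: AssemblyCluster) -> dict:
    prof: dict[int, np.ndarray] = {}
    for r in cluster.reads:
        for col, b in r.columns():
            if col not in prof:
                prof[col] = np.zeros(4, dtype=np.int64)
            prof[col][b] += 1
    return prof


def _agreement(read: ClusterRead, prof: dict) -> int:
    """Sum over read bases of how many other reads agree at that column."""
    s = 0
    for col, b in read.columns():
        counts = prof.get(col)
        if counts is not None:
            s += int(counts[b])
    return s


def refine_offsets(cluster: AssemblyCluster, max_shift: int = 3,
                   max_passes: int = 10,
                   gap_trigger: float = 0.95) -> AssemblyCluster:
    """Greedy refinement of read offsets (and up to one gap per read).

    Each pass tries, for every read, offset shifts within +-max_shift and
    — when the read agrees with the majority at fewer than
    ``gap_trigger`` of its bases — a single gap at every position
    combined with those shifts. A variant is accepted only if it strictly
    increases the read's agreement with the rest of the cluster, so the
    total pairwise agreement never decreases; passes repeat to a fixed
    point.
    """
    if len(cluster.reads) < 2:
        return cluster
    prof = _profile_of(cluster)

    def without(read):
        for col, b in read.columns():
            prof[col][b] -= 1

    def add(read):
        for col, b in read.columns():
            if col not in prof:
                prof[col] = np.zeros(4, dtype=np.int64)
            prof[col][b] += 1

    for _ in range(max_passes):
        changed = False
        for r in cluster.reads:
            without(r)
            base_score = _agreement(r, prof)
            best = (base_score, r.offset, r.gap_pos)
            for d in range(-max_shift, max_shift + 1):
                if d == 0 and r.gap_pos is None:
                    continue
                cand = ClusterRead(r.id, r.seq, r.offset + d, None)
                sc = _agreement(cand, prof)
                if sc > best[0]:
                    best = (sc, r.offset + d, None)
            # majority agreement fraction of the current placement
            denom = 0
            agree = 0
            for col, b in r.columns():
                counts = prof.get(col)
                if counts is not None and counts.sum() > 0:
                    denom += 1
                    agree += int(b == counts.argmax() and counts[b] == counts.max())
            if denom and agree / denom < gap_trigger:
                for g in range(1, len(r.seq)):
                    for d in range(-max_shift, max_shift + 1):
                        cand = ClusterRead(r.id, r.seq, r.offset + d, g)
                        sc = _agreement(cand, prof)
                        if sc > best[0]:
                            best = (sc, r.offset + d, g)
            if (best[1], best[2]) != (r.offset, r.gap_pos):
                r.offset, r.gap_pos = best[1], best[2]
                changed = True
            add(r)
        if not changed:
            break
    return cluster


@lru_cache(maxsize=100_000)
def _binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k | n, p)."""
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def call_consensus(cluster: AssemblyCluster, p_err: float = 0.1,
                   alpha: float = 0.05, mask_cov: int = 5) -> ConsensusSequence:
    """Call a soft-masked IUPAC consensus from a refined cluster.

    Per column with coverage n and majority count m: the majority base is
    called when the site is monomorphic or its minority count can be
    explained as sequencing error (P(X >= n-m | n, p_err) >= alpha);
    otherwise the IUPAC code over the majority base plus every base whose
    own count is individually significant. Sites with coverage below
    ``mask_cov`` are lowercased; zero-coverage interior columns become N.
    """
    prof = _profile_of(cluster)
    lo = min(prof)
    hi = max(prof) + 1
    bases = []
    cov = np.zeros(hi - lo, dtype=np.int64)
    for col in range(lo, hi):
        counts = prof.get(col)
        if counts is None or counts.sum() == 0:
            bases.append("n")   # no data: N, lowercased like any <5x site
            continue
        n = int(counts.sum())
        cov[col - lo] = n
        m = int(counts.max())
        maj = BASES[int(counts.argmax())]     # tie -> lexicographic smallest
        if m == n or _binom_tail(n - m, n, p_err) >= alpha:
            call = maj
        else:
            members = {maj}
            for b in range(4):
                k = int(counts[b])
                if k > 0 and _binom_tail(k, n, p_err) < alpha:
                    members.add(BASES[b])
            call = IUPAC_FOR[frozenset(members)]
        bases.append(call.lower() if n < mask_cov else call)
    return ConsensusSequence(locus=cluster.locus, individual=cluster.individual,
                             seq="".join(bases), coverage=cov,
                             n_reads=cluster.n_reads, start=lo)


def assemble_individual(reads: list, library: ReferenceLibrary,
                        individual: str, min_hits: int = 17,
                        min_matches: int = 55, p_err: float = 0.1,
                        alpha: float = 0.05, mask_cov: int = 5):
    """Full assembly for one individual: recruit, cluster, refine, call.

    ``reads`` is a list of (id, seq) across the merged and unmerged read
    files. Returns (clusters, consensus_list).
    """
    assigned = recruit_reads(reads, library, min_hits, min_matches)
    clusters = cluster_reads(reads, assigned, individual)
    consensus = []
    for cl in clusters:
        refine_offsets(cl)
        consensus.append(call_consensus(cl, p_err=p_err, alpha=alpha,
                                        mask_cov=mask_cov))
    return clusters, consensus
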