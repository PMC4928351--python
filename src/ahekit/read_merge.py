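"""Statistical merging of overlapping paired-end reads.

Every possible degree of overlap between read 1 and the
reverse-complement of read 2 is scored with a one-sided binomial tail:
the probability of seeing at least the observed number of matching bases
by chance under a uniform-base null (p = 0.25). The overlap with the
smallest p-value wins; the pair is merged only if that p-value is below
alpha (1e-10 by default). Mismatches inside the overlap are reconciled
by base quality: the higher-quality base is kept with quality equal to
the difference, matching bases keep their base with the capped sum of
the two qualities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from ._seq import encode, revcomp, read_fastq, write_fastq

log = logging.getLogger(__name__)

QUAL_CAP = 93   # highest Phred encodable in Phred+33 printable ASCII


@dataclass
class QualRead:
    id: str
    seq: str
    qual: list
    mate: int = 1

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: list
    overlap: int
    pvalue: float


def overlap_pvalue(n_overlap: int, n_match: int, p_null: float = 0.25) -> float:
    """One-sided binomial tail P(X >= n_match | n_overlap, p_null)."""
    if not 0 <= n_match <= n_overlap:
        raise ValueError("require 0 <= n_match <= n_overlap")
    if n_match == 0:
        return 1.0
    return float(binom.sf(n_match - 1, n_overlap, p_null))


def _overlap_scores(a: np.ndarray, b: np.ndarray):
    """Match counts for every innie overlap degree 1..min(len a, len b).

    a is read 1 encoded; b is the reverse complement of read 2 encoded,
    with non-ACGT set to a distinct sentinel in each so N never matches.
    """
    la, lb = a.size, b.size
    omax = min(la, lb)
    counts = np.empty(omax, dtype=np.int64)
    for o in range(1, omax + 1):
        counts[o - 1] = int(np.count_nonzero(a[la - o :] == b[:o]))
    return counts


def best_overlap(seq1: str, seq2_rc: str, p_null: float = 0.25):
    """(overlap, n_match, p) minimizing p; ties go to the longer overlap."""
    a = encode(seq1).astype(np.int16)
    b = encode(seq2_rc).astype(np.int16)
    a[a == 4] = 5   # sentinels: N/ambiguity never matches anything
    b[b == 4] = 6
    counts = _overlap_scores(a, b)
    overlaps = np.arange(1, counts.size + 1)
    # exact tail via log-survival to rank; recompute the winner precisely
    pvals = binom.sf(counts - 1, overlaps, p_null)
    pvals[counts == 0] = 1.0
    best_p = pvals.min()
    o = int(overlaps[pvals == best_p].max())      # tie -> longer overlap
    return o, int(counts[o - 1]), float(pvals[o - 1])


def merge_pair(r1: QualRead, r2: QualRead, alpha: float = 1e-10,
               p_null: float = 0.25):
    """Merge a read pair if some overlap is statistically convincing.

    r2 is supplied in sequencing orientation and reverse-complemented
    internally. Returns a MergedRead, or the (r1, r2) tuple unchanged when
    no overlap reaches significance.
    """
    if len(r1.seq) == 0 or len(r2.seq) == 0:
        log.warning("zero-length read in pair %s: passed through unmerged", r1.id)
        return (r1, r2)
    seq2_rc = revcomp(r2.seq)
    qual2_rc = r2.qual[::-1]
    o, n_match, p = best_overlap(r1.seq, seq2_rc, p_null)
    if p >= alpha:
        return (r1, r2)
    l1 = len(r1.seq)
    left = list(r1.seq[: l1 - o])
    lq = list(r1.qual[: l1 - o])
    mid, mq = [], []
    for b1, q1, b2, q2 in zip(r1.seq[l1 - o :], r1.qual[l1 - o :],
                              seq2_rc[:o], qual2_rc[:o]):
        if b1.upper() == b2.upper() and b1.upper() != "N":
            mid.append(b1.upper())
            mq.append(min(q1 + q2, QUAL_CAP))
        else:
            # higher-quality base wins; N never wins a mismatch
            if b1.upper() == "N":
                winner = b2
            elif b2.upper() == "N":
                winner = b1
            else:
                winner = b1 if q1 >= q2 else b2
            mid.append(winner.upper())
            mq.append(abs(q1 - q2))
    right = list(seq2_rc[o:])
    rq = qual2_rc[o:]
    return MergedRead(id=r1.id, seq="".join(left + mid + right),
                      qual=lq + mq + list(rq), overlap=o, pvalue=p)


def merge_pairs(pairs, alpha: float = 1e-10, p_null: float = 0.25):
    """Merge an iterable of (r1, r2); returns (merged, unmerged1, unmerged2)."""
    merged, un1, un2 = [], [], []
    for r1, r2 in pairs:
        res = merge_pair(r1, r2, alpha=alpha, p_null=p_null)
        if isinstance(res, MergedRead):
            merged.append(res)
        else:
            un1.append(r1)
            un2.append(r2)
    return merged, un1, un2


def merge_files(r1_path, r2_path, out_dir, alpha: float = 1e-10,
                prefix: str = "reads") -> dict:
    """Merge paired FASTQ files into merged / unmerged-R1 / unmerged-R2.

    Returns counts; merged + unmerged pairs always partition the input.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    pairs = (
        (QualRead(i1, s1, q1, 1), QualRead(i2, s2, q2, 2))
        for (i1, s1, q1), (i2, s2, q2) in zip(read_fastq(r1_path),
                                              read_fastq(r2_path))
    )
    merged, un1, un2 = merge_pairs(pairs, alpha=alpha)
    write_fastq(os.path.join(out_dir, f"{prefix}_merged.fastq"),
                [(m.id, m.seq, m.qual) for m in merged])
    write_fastq(os.path.join(out_dir, f"{prefix}_unmerged_R1.fastq"),
                [(r.id, r.seq, r.qual) for r in un1])
    write_fastq(os.path.join(out_dir, f"{prefix}_unmerged_R2.fastq"),
                [(r.id, r.seq, r.qual) for r in un2])
    return {"merged": len(merged), "unmerged": len(un1),
            "total_pairs": len(merged) + len(un1)}
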