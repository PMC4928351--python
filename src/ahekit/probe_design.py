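"""Probe/target design from multi-species locus alignments.

Implements the classic anchored-enrichment design rules: select
gap-free, exon-boundary-free alignment regions with at least six taxa
and a 120 bp window above 50% pairwise identity, mask high-copy regions
detected by a 15-mer (Hamming radius 1) genome census, and tile 120 bp
probes uniformly at a configurable density (1.72x by default).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, encode

log = logging.getLogger(__name__)


@dataclass
class LocusAlignment:
    """Equal-length aligned nucleotide rows over {A,C,G,T,-,N} for one locus."""

    locus: str
    taxa: list
    rows: list

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.locus}: duplicate taxon labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.locus}: rows have unequal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def slice(self, start: int, end: int) -> list:
        return [r[start:end] for r in self.rows]


@dataclass
class TargetRegion:
    locus: str
    start: int          # 0-based half-open alignment columns
    end: int
    taxa: list
    min_identity: float  # percent, best 120bp window by the configured statistic
    mean_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Probe:
    locus: str
    source_taxon: str
    start: int          # alignment column of probe start
    sequence: str


@dataclass
class ProbeSet:
    probes: list = field(default_factory=list)
    probe_len: int = 120
    density: float = 1.72


class UndefinedIdentityError(ValueError):
    pass


def pairwise_identity(window_rows: list, stat: str = "mean") -> float:
    """Percent pairwise identity of an alignment slice.

    For each row pair, columns where either row has a gap are excluded;
    identity is matches / compared columns. ``stat`` selects the mean
    (default) or minimum over all pairs. Pairs with no comparable column
    are skipped.
    """
    if len(window_rows) < 2:
        raise UndefinedIdentityError("need >= 2 rows for pairwise identity")
    encs = [encode(r) for r in window_rows]
    gaps = [np.frombuffer(r.encode(), dtype=np.uint8) == ord("-") for r in window_rows]
    vals = []
    for (ea, ga), (eb, gb) in itertools.combinations(zip(encs, gaps), 2):
        ok = ~(ga | gb)
        n = int(ok.sum())
        if n == 0:
            continue
        vals.append(100.0 * int(((ea == eb) & ok & (ea < 4)).sum()) / n)
    if not vals:
        raise UndefinedIdentityError("no comparable columns in window")
    return float(min(vals) if stat == "min" else np.mean(vals))


def find_exon_boundaries(transcript: str, genome: str, k: int = 40):
    """Locate exon junctions on a transcript via exact k-mer matches.

    Each transcript position is assigned the genome coordinate implied by
    the leftmost exact k-mer match covering it; a boundary is reported
    between adjacent assigned positions whose genome coordinates are not
    consecutive. Returns (boundaries, unknown_runs): boundary b means a
    junction between transcript positions b-1 and b; unknown_runs are
    (start, end) half-open intervals of unassigned positions.
    """
    transcript = transcript.upper()
    genome = genome.upper()
    if len(transcript) < k:
        raise ValueError(f"transcript shorter than k={k}")
    index: dict[str, int] = {}
    for i in range(len(genome) - k + 1):
        index.setdefault(genome[i : i + k], i)   # leftmost occurrence wins
    assign = np.full(len(transcript), -1, dtype=np.int64)
    for s in range(len(transcript) - k + 1):
        g = index.get(transcript[s : s + k])
        if g is None:
            continue
        for t in range(s, s + k):      # leftmost covering match wins
            if assign[t] == -1:
                assign[t] = g + (t - s)
    if (assign == -1).all():
        log.warning("no %d-mer matches between transcript and genome", k)
        return [], [(0, len(transcript))]
    boundaries = []
    for t in range(1, len(transcript)):
        a, b = assign[t - 1], assign[t]
        if a >= 0 and b >= 0 and b != a + 1:
            boundaries.append(t)
    unknown = []
    t = 0
    while t < len(transcript):
        if assign[t] == -1:
            s = t
            while t < len(transcript) and assign[t] == -1:
                t += 1
            unknown.append((s, t))
        else:
            t += 1
    return boundaries, unknown


def select_targets(aln: LocusAlignment, boundaries: dict | None = None,
                   min_taxa: int = 6, min_len: int = 150, window: int = 120,
                   min_ident: float = 50.0, identity_stat: str = "mean",
                   masked: set | None = None) -> list:
    """Pick target regions obeying all design rules.

    Rules: the alignment must hold >= min_taxa rows; a region must be
    >= min_len columns, contain no gap character in any row, span no exon
    boundary of any member (``boundaries``: taxon -> alignment-column
    boundary positions), avoid ``masked`` columns, and contain at least
    one ``window``-length sub-window whose pairwise identity is strictly
    above ``min_ident`` percent.
    """
    if len(aln.rows) < min_taxa:
        return []
    ncol = aln.n_cols
    bad = np.zeros(ncol, dtype=bool)
    for row in aln.rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        bad |= arr == ord("-")
    if masked:
        for c in masked:
            if 0 <= c < ncol:
                bad[c] = True
    cut = set()
    for positions in (boundaries or {}).values():
        cut.update(positions)
    # maximal runs of good columns, split at exon boundaries (a boundary at
    # column b is a junction between columns b-1 and b)
    targets = []
    runs = []
    start = None
    for c in range(ncol + 1):
        if c < ncol and not bad[c]:
            if start is None:
                start = c
        elif start is not None:
            runs.append((start, c))
            start = None
    for a, b in runs:
        seg_start = a
        for cutpos in sorted(p for p in cut if a < p < b):
            runs_seg = (seg_start, cutpos)
            _maybe_add_target(aln, *runs_seg, min_len, window, min_ident,
                              identity_stat, targets)
            seg_start = cutpos
        _maybe_add_target(aln, seg_start, b, min_len, window, min_ident,
                          identity_stat, targets)
    return targets


def _maybe_add_target(aln, start, end, min_len, window, min_ident, stat, out):
    length = end - start
    if length < min_len or length < window:
        return
    best = -1.0
    ids = []
    for w in range(start, end - window + 1):
        ident = pairwise_identity(aln.slice(w, w + window), stat=stat)
        ids.append(ident)
        best = max(best, ident)
    if best > min_ident:
        out.append(TargetRegion(locus=aln.locus, start=start, end=end,
                                taxa=list(aln.taxa), min_identity=float(min(ids)),
                                mean_identity=float(np.mean(ids))))


def _neighbors_1(kmer: str):
    """The k-mer plus all k-mers at Hamming distance 1."""
    yield kmer
    for i, c in enumerate(kmer):
        for b in BASES:
            if b != c:
                yield kmer[:i] + b + kmer[i + 1 :]


def mask_high_copy(aln_seq: str, genome: str, count_threshold: int = 100_000,
                   k: int = 15) -> set:
    """Positions of ``aln_seq`` hit by high-copy genomic k-mers.

    Builds all k-mers of the species' (ungapped) alignment sequence plus
    every k-mer at Hamming distance 1, scans the genome exhaustively,
    tallies each genome occurrence at the alignment positions of the
    originating k-mer, and masks positions whose tally exceeds
    ``count_threshold``.
    """
    seq = aln_seq.upper()
    genome = genome.upper()
    if len(seq) < k:
        log.warning("sequence shorter than %d bp: no masking", k)
        return set()
    origin: dict[str, list] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "-" in kmer or "N" in kmer:
            continue
        for nb in _neighbors_1(kmer):
            origin.setdefault(nb, []).append(i)
    tally = np.zeros(len(seq), dtype=np.int64)
    for g in range(len(genome) - k + 1):
        starts = origin.get(genome[g : g + k])
        if starts:
            for s in starts:
                tally[s : s + k] += 1
    return set(np.nonzero(tally > count_threshold)[0].tolist())


def tile_probes(region: TargetRegion, source_taxon: str, source_seq: str,
                probe_len: int = 120, density: float = 1.72) -> ProbeSet:
    """Tile probes uniformly across a target region.

    The nominal start step is probe_len/density; n = max(1,
    ceil((L - probe_len)/step) + 1) probes are spread evenly with the
    first at the region start and the last ending exactly at the region
    end (integer starts).
    """
    L = region.length
    ps = ProbeSet(probe_len=probe_len, density=density)
    if L < probe_len:
        log.warning("region %s:%d-%d shorter than probe length; no probes",
                    region.locus, region.start, region.end)
        return ps
    step = probe_len / density
    n = max(1, math.ceil((L - probe_len) / step) + 1)
    for i in range(n):
        off = 0 if n == 1 else math.floor(i * (L - probe_len) / (n - 1))
        start = region.start + off
        ps.probes.append(Probe(locus=region.locus, source_taxon=source_taxon,
                               start=start,
                               sequence=source_seq[start : start + probe_len]))
    return ps


def probe_coverage(ps: ProbeSet, region: TargetRegion) -> float:
    """Realized mean per-base probe coverage over the region."""
    cov = np.zeros(region.length)
    for p in ps.probes:
        a = p.start - region.start
        cov[a : a + ps.probe_len] += 1
    return float(cov.mean())
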