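"""Contamination filtering and shared-k-mer orthology clustering.

Consensus sequences from clusters with fewer than 10 reads are discarded
(low-level contaminants rarely accumulate coverage). Surviving homologs
of each locus are then clustered by a 20-mer distance — one minus the
Jaccard similarity of each sequence's pooled consecutive and spaced
(every third base) 20-mer sets — agglomerating pairs in ascending
distance order. A merge that would put two sequences from the same
individual in one cluster is skipped outright, so paralogous copies can
never co-occupy an ortholog set; clusters covering fewer than half the
species are dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

K = 20
SPACED_STEP = 3
SPACED_SPAN = (K - 1) * SPACED_STEP + 1


@dataclass
class Homolog:
    seq_id: str
    individual: str
    locus: str
    seq: str
    n_reads: int = 0


@dataclass
class HomologSet:
    locus: str
    members: list = field(default_factory=list)   # list[Homolog]


@dataclass
class OrthologCluster:
    locus: str
    members: list                                 # list[Homolog], <=1/individual
    occupancy: float

    def __post_init__(self):
        inds = [m.individual for m in self.members]
        if len(set(inds)) != len(inds):
            raise ValueError("ortholog cluster holds two sequences from one "
                             "individual")


def filter_low_coverage(n_reads: int, min_reads: int = 10) -> bool:
    """Keep a consensus only when its source cluster had >= min_reads reads."""
    return n_reads >= min_reads


def kmer_set(seq: str) -> set:
    """Pooled consecutive + spaced (every 3rd base) 20-mers, case-folded.

    Spaced k-mers are tagged so a spaced k-mer only ever matches another
    spaced k-mer.
    """
    s = seq.upper()
    out = set()
    for i in range(len(s) - K + 1):
        out.add(s[i : i + K])
    for i in range(len(s) - SPACED_SPAN + 1):
        out.add("s" + s[i : i + SPACED_SPAN : SPACED_STEP])
    return out


def kmer_distance(a: str, b: str) -> float:
    """1 - Jaccard similarity of the two sequences' 20-mer sets, in [0, 1]."""
    if len(a) < K or len(b) < K:
        log.warning("sequence shorter than %d bp: distance 1", K)
        return 1.0
    ka, kb = kmer_set(a), kmer_set(b)
    union = len(ka | kb)
    if union == 0:
        return 1.0
    return 1.0 - len(ka & kb) / union


def cluster_orthologs(homologs: HomologSet, n_species: int,
                      min_occupancy: float = 0.5,
                      max_join_distance: float = 1.0) -> list:
    """Agglomerate homologs into ortholog clusters.

    Pairwise distances are ranked ascending (ties in lexicographic order
    of member ids); each pair joins/merges clusters unless the union
    would contain two sequences from one individual, in which case the
    merge is skipped, not deferred. Pairs at distance >=
    ``max_join_distance`` (no shared k-mers at the default) never join.
    Clusters whose species occupancy (distinct individuals / n_species)
    falls below ``min_occupancy`` are removed at the end.
    """
    members = sorted(homologs.members, key=lambda h: h.seq_id)
    if not members:
        return []
    dists = []
    for a, b in itertools.combinations(members, 2):
        d = kmer_distance(a.seq, b.seq)
        dists.append((d, a.seq_id, b.seq_id))
    dists.sort()
    cluster_of = {h.seq_id: h.seq_id for h in members}
    cluster_members = {h.seq_id: [h] for h in members}

    def find(x):
        while cluster_of[x] != x:
            cluster_of[x] = cluster_of[cluster_of[x]]
            x = cluster_of[x]
        return x

    for d, ia, ib in dists:
        if d >= max_join_distance:
            break
        ra, rb = find(ia), find(ib)
        if ra == rb:
            continue
        inds_a = {h.individual for h in cluster_members[ra]}
        inds_b = {h.individual for h in cluster_members[rb]}
        if inds_a & inds_b:
            continue                      # skipped, never deferred
        cluster_of[rb] = ra
        cluster_members[ra].extend(cluster_members.pop(rb))
    out = []
    for root in sorted(cluster_members):
        mem = sorted(cluster_members[root], key=lambda h: h.seq_id)
        occ = len({h.individual for h in mem}) / n_species
        if occ >= min_occupancy:
            out.append(OrthologCluster(locus=homologs.locus, members=mem,
                                       occupancy=occ))
    return out


def build_homolog_sets(consensus_list, min_reads: int = 10) -> dict:
    """Group kept consensus sequences by locus across individuals.

    ``consensus_list``: iterable of ConsensusSequence (assembly module).
    Returns {locus: HomologSet}; low-coverage consensus are filtered here.
    """
    sets: dict[str, HomologSet] = {}
    counter: dict[str, int] = {}
    for cons in consensus_list:
        if not filter_low_coverage(cons.n_reads, min_reads):
            continue
        locus = cons.locus
        counter[locus] = counter.get(locus, 0) + 1
        hs = sets.setdefault(locus, HomologSet(locus=locus))
        hs.members.append(Homolog(
            seq_id=f"{locus}|{cons.individual}|c{counter[locus]}",
            individual=cons.individual, locus=locus, seq=cons.seq,
            n_reads=cons.n_reads))
    return sets
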