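"""Synthetic anchored-enrichment data with planted truth.

Generates a random ultrametric species tree, evolves anchor loci along it
(a conserved core flanked by faster-evolving flanks, mimicking the
anchor/flank structure that hybrid enrichment targets), shears each locus
into ~150-350 bp fragments, and emits PE150-style paired reads with
per-base Phred qualities, a configurable base-error rate, low-level random
contaminants and optional locus duplications. Every read carries a
provenance label so downstream stages can be audited against the truth.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import BASES, revcomp, write_fastq

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic enrichment experiment.

    coverage_mean is the expected per-base sequencing depth (x) of each
    locus in each individual; the number of fragments drawn is
    depth * locus_length / mean_fragment_length.
    """

    seed: int = 0
    n_taxa: int = 8
    tree_height: float = 0.2          # expected substitutions/site root->tip
    n_loci: int = 30
    anchor_len: int = 300             # bp, conserved core
    flank_len: int = 200              # bp on each side
    anchor_rate_scale: float = 0.3
    flank_rate_scale: float = 1.5
    coverage_mean: float = 20.0       # mean depth (x) per locus per individual
    fragment_len_range: tuple[int, int] = (150, 350)
    read_len: int = 150
    base_error_rate: float = 0.003
    contam_fraction: float = 0.01     # proportion of read pairs
    dup_loci: list = field(default_factory=list)   # [(locus_id, taxon), ...]
    dup_divergence: float = 0.10      # per-site divergence of planted paralogs
    model: str = "JC"                 # "JC" or "HKY"
    kappa: float = 2.0                # HKY transition/transversion rate ratio

    def validate(self) -> None:
        lo, hi = self.fragment_len_range
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if lo > hi or lo < 1:
            raise ValueError("fragment_len_range must be a nonempty interval")
        if lo < self.read_len / 2:
            raise ValueError("fragment_len_range min must be >= read_len/2")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        if not self.anchor_rate_scale < self.flank_rate_scale:
            raise ValueError("anchor_rate_scale must be < flank_rate_scale")
        if self.anchor_len < 1 or self.flank_len < 1:
            raise ValueError("anchor_len and flank_len must be positive")
        if self.model not in ("JC", "HKY"):
            raise ValueError("model must be 'JC' or 'HKY'")

    @property
    def locus_len(self) -> int:
        return self.anchor_len + 2 * self.flank_len

    def locus_ids(self) -> list[str]:
        return [f"L{i:03d}" for i in range(self.n_loci)]


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: list
    seq2: str
    qual2: list


@dataclass
class TruthSet:
    """Planted ground truth for one simulated experiment."""

    tree: dendropy.Tree
    config: SimulationConfig
    haplotypes: dict        # locus -> taxon -> sequence (copy "0")
    duplications: dict      # (locus, taxon) -> duplicated-copy sequence
    reads: list             # list[ReadPair], all individuals
    provenance: dict        # read id -> dict(kind, taxon, locus, copy, start, frag_len)

    def reads_of(self, taxon: str):
        return [r for r in self.reads if self.provenance[r.id]["taxon"] == taxon]


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Random rooted binary ultrametric tree with n_taxa leaves.

    Built by coalescent-style random joins with exponential waiting times,
    then rescaled so the root-to-tip height equals ``tree_height``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    names = [f"T{i:02d}" for i in range(1, n + 1)]
    # (newick fragment, current height) per live lineage
    lineages = [(nm, 0.0) for nm in names]
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})"
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((merged, height))
    newick, root_h = lineages[0]
    scale = config.tree_height / root_h if root_h > 0 else 1.0
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length * scale, 1e-9)
    return tree


def _jc_evolve(seq: np.ndarray, dist: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor step: dist = expected substitutions/site."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 * dist / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    # replacement uniform over the three other bases
    out[hit] = (seq[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


def _hky_matrix(dist: float, kappa: float) -> np.ndarray:
    """HKY85 transition-probability matrix at equal base frequencies."""
    from scipy.linalg import expm

    q = np.full((4, 4), 0.25)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            if {BASES[i], BASES[j]} in ({"A", "G"}, {"C", "T"}):
                q[i, j] *= kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -0.25 * np.trace(q)
    return expm(q * dist / mean_rate)


def _hky_evolve(seq, dist, kappa, rng):
    pmat = _hky_matrix(dist, kappa)
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(seq.size)
    return (u[:, None] > cum[seq]).sum(axis=1).astype(np.int8)


def evolve_loci(tree: dendropy.Tree, config: SimulationConfig,
                rng: np.random.Generator | None = None) -> dict:
    """Evolve every locus down the tree.

    Returns {locus_id: {taxon: sequence}}. Each locus is
    flank + anchor + flank, with substitution rates scaled per region
    (anchor slower than flanks), site-independent under JC or HKY.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fl, al = config.flank_len, config.anchor_len
    scales = np.concatenate([
        np.full(fl, config.flank_rate_scale),
        np.full(al, config.anchor_rate_scale),
        np.full(fl, config.flank_rate_scale),
    ])

    def step(seq, dist):
        out = seq.copy()
        for scale in (config.anchor_rate_scale, config.flank_rate_scale):
            idx = np.nonzero(scales == scale)[0]
            if config.model == "JC":
                out[idx] = _jc_evolve(seq[idx], dist * scale, rng)
            else:
                out[idx] = _hky_evolve(seq[idx], dist * scale, config.kappa, rng)
        return out

    loci = {}
    for locus in config.locus_ids():
        root_seq = rng.integers(0, 4, config.locus_len).astype(np.int8)
        states = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                states[node] = root_seq
            else:
                states[node] = step(states[node.parent_node], node.edge.length)
        loci[locus] = {
            leaf.taxon.label: "".join(BASES[b] for b in states[leaf])
            for leaf in tree.leaf_node_iter()
        }
    return loci


def _sequence_fragment(frag: str, config, rng, rid, prov, provenance, reads):
    """Emit one read pair from a fragment, with per-base errors + qualities."""
    rl = config.read_len
    e = config.base_error_rate
    out = []
    for template in (frag[:rl], revcomp(frag)[:rl]):
        arr = list(template)
        quals = []
        errs = rng.random(len(arr)) < e
        for i, is_err in enumerate(errs):
            if is_err:
                arr[i] = BASES[(BASES.index(arr[i]) + rng.integers(1, 4)) % 4]
                quals.append(int(rng.integers(2, 21)))
            else:
                quals.append(40)
        out.append(("".join(arr), quals))
    (s1, q1), (s2, q2) = out
    reads.append(ReadPair(rid, s1, q1, s2, q2))
    provenance[rid] = prov


def make_reads(tree: dendropy.Tree, loci: dict, config: SimulationConfig,
               rng: np.random.Generator | None = None) -> TruthSet:
    """Shear haplotypes into fragments and sequence paired reads.

    Fragment lengths are uniform over fragment_len_range, start positions
    uniform over the locus; read 1 is the first read_len bases of the
    fragment, read 2 the first read_len bases of its reverse complement.
    Errors are Bernoulli(base_error_rate) per base; correct calls get
    Phred 40, error bases a Phred drawn uniformly from 2-20. A
    contam_fraction of read pairs comes from i.i.d. uniform random
    sequences. Planted duplications add a second, diverged copy of a locus
    in one taxon, sequenced at the same depth as the original.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.fragment_len_range
    mean_frag = (lo + hi) / 2.0
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    duplications = {}
    for locus, taxon in config.dup_loci:
        src = loci[locus][taxon]
        arr = np.array([BASES.index(c) for c in src], dtype=np.int8)
        hit = rng.random(arr.size) < config.dup_divergence
        arr[hit] = (arr[hit] + rng.integers(1, 4, hit.sum())) % 4
        duplications[(locus, taxon)] = "".join(BASES[b] for b in arr)

    reads: list[ReadPair] = []
    provenance: dict[str, dict] = {}
    counter = 0
    n_target = 0
    for taxon in taxa:
        for locus in sorted(loci):
            copies = [("0", loci[locus][taxon])]
            if (locus, taxon) in duplications:
                copies.append(("1", duplications[(locus, taxon)]))
            for copy_id, hap in copies:
                n_frags = int(round(config.coverage_mean * len(hap) / mean_frag))
                for _ in range(n_frags):
                    flen = int(rng.integers(lo, hi + 1))
                    flen = min(flen, len(hap))
                    if flen < 1:
                        log.warning("fragment shorter than 1 bp skipped")
                        continue
                    start = int(rng.integers(0, len(hap) - flen + 1))
                    rid = f"{taxon}:read{counter:06d}"
                    counter += 1
                    n_target += 1
                    _sequence_fragment(
                        hap[start : start + flen], config, rng, rid,
                        dict(kind="target", taxon=taxon, locus=locus,
                             copy=copy_id, start=start, frag_len=flen),
                        provenance, reads)
    # contaminants: independent uniform random source sequence per read pair
    if config.contam_fraction > 0:
        n_contam = int(round(n_target * config.contam_fraction
                             / (1.0 - config.contam_fraction)))
        per_taxon = np.zeros(len(taxa), dtype=int)
        per_taxon[: n_contam % len(taxa)] += 1
        per_taxon += n_contam // len(taxa)
        for taxon, n_c in zip(taxa, per_taxon):
            for _ in range(int(n_c)):
                flen = int(rng.integers(lo, hi + 1))
                frag = "".join(BASES[b] for b in rng.integers(0, 4, flen))
                rid = f"{taxon}:read{counter:06d}"
                counter += 1
                _sequence_fragment(
                    frag, config, rng, rid,
                    dict(kind="contaminant", taxon=taxon, locus=None,
                         copy=None, start=0, frag_len=flen),
                    provenance, reads)
    return TruthSet(tree=tree, config=config, haplotypes=loci,
                    duplications=duplications, reads=reads,
                    provenance=provenance)


def simulate(config: SimulationConfig) -> TruthSet:
    """Full generator: tree -> loci -> reads."""
    tree = simulate_tree(config)
    loci = evolve_loci(tree, config)
    return make_reads(tree, loci, config)


def write_truthset(truth: TruthSet, out_dir) -> None:
    """Write FASTQ pairs per individual, truth tables (TSV) and the tree."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    taxa = sorted(leaf.taxon.label for leaf in truth.tree.leaf_node_iter())
    for taxon in taxa:
        rs = truth.reads_of(taxon)
        write_fastq(os.path.join(out_dir, f"{taxon}_R1.fastq"),
                    [(r.id + "/1", r.seq1, r.qual1) for r in rs])
        write_fastq(os.path.join(out_dir, f"{taxon}_R2.fastq"),
                    [(r.id + "/2", r.seq2, r.qual2) for r in rs])
    truth.tree.write(path=os.path.join(out_dir, "true_tree.nwk"),
                     schema="newick")
    with open(os.path.join(out_dir, "provenance.tsv"), "w") as fh:
        fh.write("read_id\tkind\ttaxon\tlocus\tcopy\tstart\tfrag_len\n")
        for rid, p in truth.provenance.items():
            fh.write(f"{rid}\t{p['kind']}\t{p['taxon']}\t{p['locus']}"
                     f"\t{p['copy']}\t{p['start']}\t{p['frag_len']}\n")
    with open(os.path.join(out_dir, "haplotypes.tsv"), "w") as fh:
        fh.write("locus\ttaxon\tcopy\tsequence\n")
        for locus in sorted(truth.haplotypes):
            for taxon, seq in sorted(truth.haplotypes[locus].items()):
                fh.write(f"{locus}\t{taxon}\t0\t{seq}\n")
        for (locus, taxon), seq in sorted(truth.duplications.items()):
            fh.write(f"{locus}\t{taxon}\t1\t{seq}\n")


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "fragment_len_range" in data:
        data["fragment_len_range"] = tuple(data["fragment_len_range"])
    if "dup_loci" in data:
        data["dup_loci"] = [tuple(x) for x in data["dup_loci"]]
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)
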