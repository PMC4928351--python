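"""Supermatrix construction, dataset statistics and an NJ sanity tree.

Trimmed per-locus alignments are concatenated into one matrix with a
RAxML-style partition table (`DNA, locus = a-b`, 1-based inclusive);
taxa missing from a locus are padded with '?'. Parsimony-informative
sites are counted per standard definition (>= 2 states each in >= 2
taxa, ambiguities treated as missing). Maximum-likelihood inference is
left to external tools; a neighbor-joining tree on pairwise p-distances
(pairwise deletion) is provided as an internal sanity check of the
phylogenetic signal.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

MISSING = {"?", "-", "N"}
UNAMBIG = {"A", "C", "G", "T"}


@dataclass
class Supermatrix:
    taxa: list
    rows: dict                        # taxon -> concatenated string
    partitions: list                  # (locus, start1, end1) 1-based inclusive
    locus_taxa: dict = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def missingness(self) -> float:
        total = len(self.taxa) * self.n_cols
        if total == 0:
            return 0.0
        miss = sum(r.count("?") + r.count("-") + r.count("N")
                   for r in self.rows.values())
        return miss / total

    def per_taxon_missingness(self) -> dict:
        n = self.n_cols
        return {t: (r.count("?") + r.count("-") + r.count("N")) / n
                for t, r in self.rows.items()}


def concatenate(trimmed: list) -> Supermatrix:
    """Concatenate TrimmedAlignment objects into one partitioned matrix."""
    if not trimmed:
        raise ValueError("no loci to concatenate")
    taxa = sorted({t for aln in trimmed for t in aln.taxa})
    parts = []
    chunks = {t: [] for t in taxa}
    col = 0
    locus_taxa = {}
    for aln in trimmed:
        if len(set(aln.taxa)) != len(aln.taxa):
            raise ValueError(f"duplicate taxon labels in locus {aln.locus}")
        L = aln.n_cols
        rowmap = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            chunks[t].append(rowmap.get(t, "?" * L).upper())
        parts.append((aln.locus, col + 1, col + L))
        locus_taxa[aln.locus] = list(aln.taxa)
        col += L
    return Supermatrix(taxa=taxa,
                       rows={t: "".join(chunks[t]) for t in taxa},
                       partitions=parts, locus_taxa=locus_taxa)


def _column_states(matrix: Supermatrix, j: int):
    counts: dict[str, int] = {}
    for t in matrix.taxa:
        c = matrix.rows[t][j]
        if c in UNAMBIG:
            counts[c] = counts.get(c, 0) + 1
    return counts


def count_informative(matrix: Supermatrix) -> int:
    """Parsimony-informative sites: >= 2 unambiguous states in >= 2 taxa each."""
    arr = np.array([list(matrix.rows[t]) for t in matrix.taxa])
    n_inf = 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        _, counts = np.unique(col[np.isin(col, list(UNAMBIG))],
                              return_counts=True)
        if (counts >= 2).sum() >= 2:
            n_inf += 1
    return n_inf


def p_distance_matrix(matrix: Supermatrix) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of missing/ambiguous data."""
    taxa = matrix.taxa
    arr = np.array([list(matrix.rows[t]) for t in taxa])
    ok = np.isin(arr, list(UNAMBIG))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable sites")
            d[i, j] = d[j, i] = float((arr[i][both] != arr[j][both]).sum()) / m
    return d


def nj_tree(matrix: Supermatrix, outgroup: str | None = None) -> str:
    """Neighbor-joining tree (Newick) on the p-distance matrix.

    Negative branch lengths are clamped to zero. ``outgroup`` optionally
    roots the tree on that taxon's branch.
    """
    import dendropy
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(matrix.taxa) < 3:
        raise ValueError("need >= 3 taxa for a tree")
    dm = DistanceMatrix(p_distance_matrix(matrix), ids=matrix.taxa)
    newick = str(nj(dm)).strip()
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not in matrix")
        tree.reroot_at_edge(og.edge, update_bipartitions=False)
    return tree.as_string(schema="newick").strip()


def stats(matrix: Supermatrix) -> dict:
    return {
        "n_taxa": len(matrix.taxa),
        "n_loci": len(matrix.partitions),
        "n_sites": matrix.n_cols,
        "n_informative": count_informative(matrix),
        "pct_missing": 100.0 * matrix.missingness(),
    }


def write_phylip(matrix: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
    with open(path, "w") as fh:
        fh.write(f" {len(matrix.taxa)} {matrix.n_cols}\n")
        for t in matrix.taxa:
            fh.write(f"{t}  {matrix.rows[t]}\n")


def read_phylip(path) -> Supermatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n, L = int(header[0]), int(header[1])
        rows = {}
        for _ in range(n):
            name, seq = fh.readline().split()
            assert len(seq) == L
            rows[name] = seq
    return Supermatrix(taxa=sorted(rows), rows=rows,
                       partitions=[("all", 1, L)])


def write_fasta_matrix(matrix: Supermatrix, path) -> None:
    from ._seq import write_fasta

    write_fasta(path, [(t, matrix.rows[t]) for t in matrix.taxa])


def write_partitions(matrix: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for locus, a, b in matrix.partitions:
            fh.write(f"DNA, {locus} = {a}-{b}\n")


def write_outputs(matrix: Supermatrix, out_dir, tree_newick: str | None = None
                  ) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_phylip(matrix, os.path.join(out_dir, "supermatrix.phy"))
    write_fasta_matrix(matrix, os.path.join(out_dir, "supermatrix.fasta"))
    write_partitions(matrix, os.path.join(out_dir, "partitions.txt"))
    st = stats(matrix)
    with open(os.path.join(out_dir, "stats.tsv"), "w") as fh:
        fh.write("\t".join(st.keys()) + "\n")
        fh.write("\t".join(f"{v:.4f}" if isinstance(v, float) else str(v)
                           for v in st.values()) + "\n")
    if tree_newick is not None:
        with open(os.path.join(out_dir, "nj_tree.nwk"), "w") as fh:
            fh.write(tree_newick + "\n")
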