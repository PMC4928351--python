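"""Per-locus alignment and conservation-based trimming/masking.

Each ortholog set is aligned with an external aligner (MAFFT with
--genafpair --maxiterate 1000 by default; a bundled center-star
progressive aligner serves as a fallback when no executable is
available). The alignment is then cleaned in three fixed steps:

1. columns whose most common character exceeds 40% of the sequences are
   flagged "conserved";
2. any 20 bp stretch of a sequence containing fewer than 10 stable sites
   (conserved column AND the row matches the modal character) is masked
   to '?';
3. columns with fewer than 12 unmasked bases are removed.
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np

from ._seq import IUPAC_MEMBERS, read_fasta, write_fasta

log = logging.getLogger(__name__)

GAPLIKE = {"-", "?"}


@dataclass
class TrimmedAlignment:
    locus: str
    taxa: list
    rows: list
    conserved: np.ndarray | None = None
    removed_columns: int = 0
    masked_cells: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


class AlignerNotFoundError(RuntimeError):
    pass


def run_aligner(seqs: list, executable: str = "mafft",
                flags: tuple = ("--genafpair", "--maxiterate", "1000"),
                fallback: bool = False) -> list:
    """Align (name, sequence) pairs with an external aligner.

    Returns (name, aligned_sequence) pairs in input order. When the
    executable is missing, raises AlignerNotFoundError naming the
    ``aligner.executable`` config key — unless ``fallback`` is true, in
    which case the bundled progressive aligner is used instead.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences to align")
    exe = shutil.which(executable)
    if exe is None:
        if fallback:
            log.info("aligner %r not found; using bundled progressive aligner",
                     executable)
            return progressive_align(seqs)
        raise AlignerNotFoundError(
            f"aligner executable {executable!r} not found on PATH; set the "
            f"'aligner.executable' config key or pass fallback=True")
    with tempfile.TemporaryDirectory() as tmp:
        inp = os.path.join(tmp, "in.fasta")
        # temporary numeric names dodge aligner header munging
        write_fasta(inp, [(f"s{i}", s) for i, (_, s) in enumerate(seqs)])
        cmd = [exe, *flags, "--quiet", inp]
        log.info("aligner invocation: %s", " ".join(cmd))
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
        aligned = dict(read_fasta_string(res.stdout))
    return [(name, aligned[f"s{i}"]) for i, (name, _) in enumerate(seqs)]


def read_fasta_string(text: str) -> list:
    out = []
    name, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, "".join(chunks)))
            name, chunks = line[1:].strip(), []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


def _pairwise_global(a: str, b: str):
    """Global alignment via Biopython; returns gapped strings."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def progressive_align(seqs: list) -> list:
    """Center-star progressive alignment (tests/fallback only).

    Aligns every sequence to the center sequence (the one maximizing
    total pairwise score) and merges the pairwise alignments
    once-a-gap-always-a-gap.
    """
    names = [n for n, _ in seqs]
    raw = [s for _, s in seqs]
    if len(raw) == 1:
        return list(seqs)
    from Bio import Align

    scorer = Align.PairwiseAligner()
    scorer.mode = "global"
    scorer.match_score = 2
    scorer.mismatch_score = -1
    scorer.open_gap_score = -4
    scorer.extend_gap_score = -0.5
    totals = []
    for i, a in enumerate(raw):
        t = sum(scorer.score(a.upper(), b.upper())
                for j, b in enumerate(raw) if j != i)
        totals.append(t)
    center = int(np.argmax(totals))
    rows: dict[int, list] = {center: list(raw[center])}
    for i, s in enumerate(raw):
        if i == center:
            continue
        old_center = rows[center]
        ac, ai = _pairwise_global("".join(c for c in old_center if c != "-"), s)
        new_rows: dict[int, list] = {k: [] for k in rows}
        new_row_i: list = []
        pos = 0
        for j, c in enumerate(old_center):
            if c == "-":
                for k in rows:
                    new_rows[k].append(rows[k][j])
                new_row_i.append("-")
                continue
            while ac[pos] == "-":   # insertion relative to current center
                for k in rows:
                    new_rows[k].append("-")
                new_row_i.append(ai[pos])
                pos += 1
            for k in rows:
                new_rows[k].append(rows[k][j])
            new_row_i.append(ai[pos])
            pos += 1
        while pos < len(ac):        # trailing insertions
            for k in rows:
                new_rows[k].append("-")
            new_row_i.append(ai[pos])
            pos += 1
        rows = new_rows
        rows[i] = new_row_i
    return [(name, "".join(rows[i])) for i, name in enumerate(names)]


def _modal_char(column: list):
    """(modal character, frequency over all rows) ignoring gaps/missing."""
    counts: dict[str, int] = {}
    for c in column:
        u = c.upper()
        if u in GAPLIKE:
            continue
        counts[u] = counts.get(u, 0) + 1
    if not counts:
        return None, 0.0
    modal = max(sorted(counts), key=counts.get)
    return modal, counts[modal] / len(column)


def flag_conserved(rows: list, threshold: float = 0.40) -> np.ndarray:
    """Per-column conserved flags: modal character frequency strictly > threshold.

    The frequency denominator is the total number of sequences; all-gap
    columns are never conserved.
    """
    if not rows or not rows[0]:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    flags = np.zeros(ncol, dtype=bool)
    for j in range(ncol):
        _, freq = _modal_char([r[j] for r in rows])
        flags[j] = freq > threshold
    return flags


def _matches_modal(char: str, modal: str | None) -> bool:
    if modal is None:
        return False
    u = char.upper()
    if u == modal:
        return True
    members = IUPAC_MEMBERS.get(u)
    return bool(members and modal in members)


def mask_unstable_regions(rows: list, flags: np.ndarray, window: int = 20,
                          min_stable: int = 10) -> tuple:
    """Mask poorly aligned stretches of each sequence to '?'.

    A site of a row is stable iff its column is conserved and the row's
    character matches the column's modal character (IUPAC codes match
    when the modal base is among their members). Windows run over the
    row's own (ungapped) coordinates; every window of ``window`` sites
    with fewer than ``min_stable`` stable sites is masked entirely;
    overlapping masked windows union. Rows shorter than the window are
    evaluated as a single window.
    """
    ncol = len(rows[0])
    modal = [_modal_char([r[j] for r in rows])[0] for j in range(ncol)]
    out_rows = []
    masked_cells = 0
    for row in rows:
        cols = [j for j in range(ncol) if row[j] not in GAPLIKE]
        stable = [bool(flags[j]) and _matches_modal(row[j], modal[j])
                  for j in cols]
        to_mask = np.zeros(len(cols), dtype=bool)
        if cols:
            if len(cols) <= window:
                if sum(stable) < min_stable:
                    to_mask[:] = True
            else:
                csum = np.concatenate([[0], np.cumsum(stable)])
                for s in range(len(cols) - window + 1):
                    if csum[s + window] - csum[s] < min_stable:
                        to_mask[s : s + window] = True
        new = list(row)
        for k, j in enumerate(cols):
            if to_mask[k]:
                new[j] = "?"
                masked_cells += 1
        out_rows.append("".join(new))
    return out_rows, masked_cells


def drop_sparse_columns(rows: list, min_unmasked: int = 12) -> tuple:
    """Remove columns with fewer than ``min_unmasked`` non-gap, non-'?' cells."""
    ncol = len(rows[0]) if rows else 0
    keep = []
    for j in range(ncol):
        n = sum(1 for r in rows if r[j] not in GAPLIKE)
        if n >= min_unmasked:
            keep.append(j)
    new_rows = ["".join(r[j] for j in keep) for r in rows]
    return new_rows, ncol - len(keep)


def trim_alignment(locus: str, taxa: list, rows: list, threshold: float = 0.40,
                   window: int = 20, min_stable: int = 10,
                   min_unmasked: int = 12, max_rounds: int = 50
                   ) -> TrimmedAlignment:
    """The full three-step trimming procedure, applied to a fixed point.

    One round = flag conserved columns, mask unstable stretches, drop
    sparse columns, in that order. Masking lowers modal counts and column
    removal rejoins a row's window coordinates, so a single round is not
    a no-op on its own output; rounds therefore repeat until nothing
    changes (masked cells and removed columns grow monotonically, so this
    terminates). Re-applying the trimmer to its result then changes
    nothing, columns never increase and an alignment of identical rows
    passes through untouched.
    """
    cur = list(rows)
    flags = None
    total_masked = total_removed = 0
    for _ in range(max_rounds):
        if cur and not cur[0]:
            break
        flags = flag_conserved(cur, threshold)
        masked, n_masked = mask_unstable_regions(cur, flags, window,
                                                 min_stable)
        nxt, n_removed = drop_sparse_columns(masked, min_unmasked)
        total_masked += n_masked
        total_removed += n_removed
        if nxt == cur:
            break
        cur = nxt
    else:
        log.warning("locus %s: trimming did not stabilize in %d rounds",
                    locus, max_rounds)
    if cur and not cur[0]:
        log.warning("locus %s: every column removed by trimming", locus)
    return TrimmedAlignment(locus=locus, taxa=list(taxa), rows=cur,
                            conserved=flags, removed_columns=total_removed,
                            masked_cells=total_masked)


def align_and_trim(locus: str, seqs: list, executable: str = "mafft",
                   flags: tuple = ("--genafpair", "--maxiterate", "1000"),
                   fallback: bool = True, **trim_kw) -> TrimmedAlignment:
    """Align an ortholog set then trim it; sequences are uppercased first
    (soft-mask case carries coverage, not alignment information)."""
    up = [(n, s.upper()) for n, s in seqs]
    aligned = run_aligner(up, executable=executable, flags=flags,
                          fallback=fallback)
    return trim_alignment(locus, [n for n, _ in aligned],
                          [s for _, s in aligned], **trim_kw)
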