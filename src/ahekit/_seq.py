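"""Shared sequence utilities: encoding, complements, IUPAC codes, FASTA/FASTQ I/O.

Nucleotides are encoded as int8: A=0, C=1, G=2, T=3. Anything else (N,
gaps, ambiguity codes) maps to 4 and never matches during comparisons.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# base-set -> IUPAC single letter
IUPAC_FOR = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}
IUPAC_MEMBERS = {code.upper(): members for members, code in IUPAC_FOR.items()}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0,C=1,G=2,T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] if i < 4 else "N" for i in arr)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fastq(path, records) -> None:
    """Write (id, seq, quals) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            qline = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qline}\n")


def read_fastq(path):
    """Yield (id, seq, quals-list) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qline = fh.readline().strip()
            yield header[1:].strip(), seq, [ord(c) - 33 for c in qline]


def write_fasta(path, records, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Return list of (name, sequence) preserving case and order."""
    from Bio import SeqIO

    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
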