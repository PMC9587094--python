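"""Thin FASTA / alignment readers returning ordered id → sequence mappings."""

from __future__ import annotations

from Bio import AlignIO, SeqIO


def read_fasta(path) -> dict:
    """Ordered mapping id → sequence from a FASTA file."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def read_alignment(path, fmt: str = "fasta") -> dict:
    """Ordered mapping id → aligned row; ``fmt`` is 'fasta' or 'phylip-relaxed'."""
    aln = AlignIO.read(str(path), fmt)
    out = {}
    for rec in aln:
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, sequences: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
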