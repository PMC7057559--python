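"""Genome container and FASTA round-trip.

A :class:`Genome` is an ordered mapping of contig id to an uppercase DNA
string over ``{A, C, G, T, N}``.  FASTA reading and writing go through
Biopython; sequences are normalised to uppercase on input and validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A named set of contigs.

    Parameters
    ----------
    id:
        Genome identifier (e.g. a cultivar or line name).
    sequences:
        Ordered mapping of contig id to sequence.  Insertion order is
        preserved and is semantically meaningful (it fixes output order).
    role:
        One of ``host``, ``alien_cultivar`` or ``line``; informational.
    """

    id: str
    sequences: Dict[str, str] = field(default_factory=dict)
    role: str = "host"

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"contig {cid!r} in genome {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def read_fasta(path: str | Path, genome_id: str | None = None, role: str = "host") -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lowercase input is accepted and normalised to uppercase; characters
    outside ``ACGTN`` are rejected.  Duplicate record ids and empty records
    are errors.
    """
    path = Path(path)
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} in {path} contains invalid characters: {sorted(bad)}"
            )
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(id=genome_id or path.stem, sequences=sequences, role=role)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    """Write a genome as multi-record FASTA with fixed line width."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.sequences.items()
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
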