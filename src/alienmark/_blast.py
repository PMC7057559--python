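"""Thin wrapper around the blastn command-line tool.

Local host-homology search and scaffold anchoring both ride on blastn,
which is the kind of aligner a marker-design workflow uses for the
"compare everything against the host reference" step.  Only the pieces
needed here are wrapped: batch query FASTA against a subject FASTA, tabular
output with aligned sequence strings so callers can walk alignment columns.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd

_OUTFMT = "6 qseqid sseqid pident length qstart qend sstart send bitscore qseq sseq"

COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "qstart",
    "qend",
    "sstart",
    "send",
    "bitscore",
    "qseq",
    "sseq",
]


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def blastn(
    queries: Mapping[str, str],
    subject: Mapping[str, str],
    task: str = "blastn",
    evalue: float = 1e-6,
    word_size: int | None = None,
) -> pd.DataFrame:
    """Run blastn of *queries* against *subject*, both given as id->sequence.

    Returns a DataFrame with one row per HSP (columns as in
    :data:`COLUMNS`), sorted by query id then descending bitscore.  Dust
    masking is disabled so results on synthetic sequence are deterministic
    and complete.
    """
    if not subject:
        raise ValueError("empty subject sequence set")
    if not queries:
        return pd.DataFrame(columns=COLUMNS)
    with tempfile.TemporaryDirectory(prefix="alienmark_blast_") as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        _write_fasta(queries, qpath)
        _write_fasta(subject, spath)
        cmd = [
            "blastn",
            "-query",
            str(qpath),
            "-subject",
            str(spath),
            "-task",
            task,
            "-dust",
            "no",
            "-soft_masking",
            "false",
            "-evalue",
            str(evalue),
            "-outfmt",
            _OUTFMT,
        ]
        if word_size is not None:
            cmd += ["-word_size", str(word_size)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
        rows = [line.split("\t") for line in proc.stdout.splitlines() if line]
    df = pd.DataFrame(rows, columns=COLUMNS)
    if len(df):
        for col in ("pident", "bitscore"):
            df[col] = df[col].astype(float)
        for col in ("length", "qstart", "qend", "sstart", "send"):
            df[col] = df[col].astype(int)
        df = df.sort_values(
            ["qseqid", "bitscore", "sseqid", "sstart"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Best HSP (highest bitscore) per query from a :func:`blastn` table."""
    if not len(df):
        return df
    return df.groupby("qseqid", sort=False).head(1).reset_index(drop=True)
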