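"""Pairwise identity via end-free alignment.

Identity between two sequences is defined as matched columns over total
alignment columns of an end-free alignment in which the shorter sequence is
aligned globally and the longer sequence's ends are free (edlib "HW" mode).
For the near-equal-length fragments produced by size selection this is the
natural metric; it is symmetric in its arguments.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def identity(a: str, b: str) -> float:
    """Fraction of matching columns in an end-free alignment of *a* and *b*.

    Returns 1.0 for identical sequences, 0.0 if either is empty.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    dist = res["editDistance"]
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    if columns == 0:
        return 0.0
    return (columns - dist) / columns
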