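"""In-silico restriction digestion, size selection and locus clustering.

The reduced-representation step: each genome is digested to completion with
a blunt four-cutter (RsaI, GT^AC, by default), fragments inside a narrow
electrophoresis window (464-494 bp inclusive by default) are retained, and
near-identical fragments are clustered into loci, one representative per
locus.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from alienmark.align import identity
from alienmark.genome import Genome

DEFAULT_SITE = "GTAC"
DEFAULT_CUT_OFFSET = 2
DEFAULT_SIZE_WINDOW = (464, 494)
DEFAULT_CLUSTER_IDENTITY = 0.90


@dataclass(frozen=True)
class RestrictionFragment:
    """One fragment of a complete digest; fragments tile their contig."""

    contig: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SLAFLocus:
    """A cluster of near-identical size-selected fragments.

    The representative is the first (longest, ties broken by input order)
    member; every other member joined because its identity to the
    representative exceeded the clustering threshold.
    """

    locus_id: str
    cultivar: str
    sequence: str
    members: List[RestrictionFragment] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.sequence)

    @property
    def n_members(self) -> int:
        return len(self.members)


def digest(
    genome: Genome,
    site: str = DEFAULT_SITE,
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> List[RestrictionFragment]:
    """Complete digestion of every contig at each occurrence of *site*.

    The cut is placed *cut_offset* bases into the recognition site (GT^AC:
    offset 2).  The site must be plain ACGT (no IUPAC ambiguity, no N); the
    palindromic default is scanned on the forward strand only.  Per contig
    the returned fragments tile it exactly: concatenating them reproduces
    the contig.
    """
    if not genome.sequences:
        raise ValueError(f"genome {genome.id!r} has no contigs")
    if not site or set(site) - set("ACGT"):
        raise ValueError(f"restriction site {site!r} must be non-empty plain ACGT")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut offset outside the recognition site")

    fragments: List[RestrictionFragment] = []
    for contig, seq in genome.sequences.items():
        cuts = [0]
        pos = seq.find(site)
        while pos != -1:
            cuts.append(pos + cut_offset)
            pos = seq.find(site, pos + 1)
        cuts.append(len(seq))
        for start, end in zip(cuts, cuts[1:]):
            if end > start:
                fragments.append(
                    RestrictionFragment(contig, start, end, seq[start:end])
                )
    return fragments


def size_select(
    fragments: Sequence[RestrictionFragment],
    window: Tuple[int, int] = DEFAULT_SIZE_WINDOW,
) -> List[RestrictionFragment]:
    """Keep fragments whose length is inside *window*, both ends inclusive."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"size window lower bound {lo} exceeds upper bound {hi}")
    return [f for f in fragments if lo <= f.size <= hi]


def cluster_loci(
    fragments: Sequence[RestrictionFragment],
    cultivar: str,
    identity_threshold: float = DEFAULT_CLUSTER_IDENTITY,
) -> List[SLAFLocus]:
    """Greedy centroid clustering of fragments into loci.

    Fragments are visited in descending length (ties by input order); each
    is assigned to the first existing locus whose representative it matches
    with identity strictly above *identity_threshold*, else it founds a new
    locus.  Deterministic and seed-free.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(range(len(fragments)), key=lambda i: (-fragments[i].size, i))
    loci: List[SLAFLocus] = []
    for idx in order:
        frag = fragments[idx]
        target = None
        for locus in loci:
            if identity(frag.sequence, locus.sequence) > identity_threshold:
                target = locus
                break
        if target is None:
            target = SLAFLocus(
                locus_id=f"{cultivar}_L{len(loci) + 1:05d}",
                cultivar=cultivar,
                sequence=frag.sequence,
            )
            loci.append(target)
        target.members.append(frag)
    return loci
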