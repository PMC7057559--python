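"""Alien-specificity filtering and cross-cultivar conservation.

A locus is alien-specific when its best local alignment against the host
genome is weak.  "Homology" is deliberately a composite score,
``identity x query coverage`` of the best local hit, so that both a
diverged full-length hit and a near-perfect partial hit score below a 0.5
threshold; both components are reported so users can re-filter on either
reading.  Loci passing the filter in every cultivar and mutually identical
above a conservation threshold become conserved alien-specific loci, the
substrate for marker design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from alienmark import _blast
from alienmark.align import identity as pair_identity
from alienmark.digestion import SLAFLocus
from alienmark.genome import Genome

DEFAULT_SPECIFICITY_THRESHOLD = 0.50
DEFAULT_CONSERVATION_THRESHOLD = 0.90


@dataclass
class HomologyReport:
    locus_id: str
    hit: Optional[Tuple[str, int, int]]  # contig, 0-based start, end of best local hit
    identity: float
    coverage: float
    score: float
    is_specific: bool


@dataclass
class ConservedLocus:
    """An alien-specific locus present in every cultivar.

    The consensus is the first cultivar's member verbatim (primers are
    designed on real observed sequence, not on a base-called consensus).
    """

    locus_id: str
    sequence: str
    members: Dict[str, str]  # cultivar -> member locus id
    min_pairwise_identity: float


def _reports_from_hits(
    loci: Sequence[SLAFLocus], hits: pd.DataFrame, threshold: float
) -> List[HomologyReport]:
    best = _blast.best_hits(hits)
    by_query = {row.qseqid: row for row in best.itertuples()}
    reports = []
    for locus in loci:
        row = by_query.get(locus.locus_id)
        if row is None:
            reports.append(
                HomologyReport(locus.locus_id, None, 0.0, 0.0, 0.0, threshold > 0)
            )
            continue
        ident = row.pident / 100.0
        coverage = (row.qend - row.qstart + 1) / locus.size
        score = ident * coverage
        s, e = sorted((row.sstart, row.send))
        reports.append(
            HomologyReport(
                locus.locus_id,
                (row.sseqid, s - 1, e),
                ident,
                coverage,
                score,
                score < threshold,
            )
        )
    return reports


def homology_reports(
    loci: Sequence[SLAFLocus],
    host: Genome,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> List[HomologyReport]:
    """Batch host-homology search for a set of loci (one blastn run)."""
    if not host.sequences:
        raise ValueError("host genome has no contigs")
    hits = _blast.blastn(
        {loc.locus_id: loc.sequence for loc in loci}, host.sequences
    )
    return _reports_from_hits(loci, hits, threshold)


def homology_to_host(
    locus: SLAFLocus,
    host: Genome,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> HomologyReport:
    """Best local alignment of one locus against the host genome."""
    return homology_reports([locus], host, threshold)[0]


def filter_specific(
    loci: Sequence[SLAFLocus],
    host: Genome,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> List[SLAFLocus]:
    """Keep exactly the loci whose homology score is strictly below *threshold*."""
    reports = homology_reports(loci, host, threshold)
    return [locus for locus, rep in zip(loci, reports) if rep.is_specific]


def intersect_cultivars(
    per_cultivar: Dict[str, Sequence[SLAFLocus]],
    conservation_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> List[ConservedLocus]:
    """Cross-cultivar intersection of specific loci.

    Emits one conserved locus per group that has a member in every cultivar
    with all pairwise identities at or above the threshold.  A cultivar with
    zero loci yields an empty result.  Symmetric under cultivar reordering
    up to the choice of consensus (first cultivar's member).
    """
    if len(per_cultivar) < 2:
        raise ValueError("need at least two cultivars to intersect")
    cultivars = list(per_cultivar)
    if any(len(per_cultivar[c]) == 0 for c in cultivars):
        return []
    first, rest = cultivars[0], cultivars[1:]
    used: Dict[str, set] = {c: set() for c in rest}
    conserved: List[ConservedLocus] = []
    for ref in per_cultivar[first]:
        chosen: Dict[str, SLAFLocus] = {first: ref}
        for cult in rest:
            best, best_ident = None, conservation_threshold
            for cand in per_cultivar[cult]:
                if cand.locus_id in used[cult]:
                    continue
                ident = pair_identity(ref.sequence, cand.sequence)
                if ident >= best_ident:
                    best, best_ident = cand, ident
            if best is None:
                chosen = {}
                break
            chosen[cult] = best
        if not chosen:
            continue
        members = list(chosen.values())
        min_pair = min(
            pair_identity(a.sequence, b.sequence)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        if min_pair < conservation_threshold:
            continue
        for cult in rest:
            used[cult].add(chosen[cult].locus_id)
        conserved.append(
            ConservedLocus(
                locus_id=f"CONS_{ref.locus_id}",
                sequence=ref.sequence,
                members={c: l.locus_id for c, l in chosen.items()},
                min_pairwise_identity=min_pair,
            )
        )
    return conserved


def reports_to_frame(reports: Sequence[HomologyReport]) -> pd.DataFrame:
    """Homology reports as a table (for the TSV export)."""
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in reports],
            "hit_contig": [r.hit[0] if r.hit else "" for r in reports],
            "hit_start": [r.hit[1] if r.hit else -1 for r in reports],
            "hit_end": [r.hit[2] if r.hit else -1 for r in reports],
            "identity": [round(r.identity, 4) for r in reports],
            "coverage": [round(r.coverage, 4) for r in reports],
            "score": [round(r.score, 4) for r in reports],
            "specific": [int(r.is_specific) for r in reports],
        }
    )
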