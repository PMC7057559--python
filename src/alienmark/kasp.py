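"""Co-dominant KASP assay construction and validation.

A KASP assay genotypes a single diagnostic SNP between the alien donor and
the host: two allele-specific forward primers, identical except for their
3'-terminal base (one per allele) and each carrying a universal
fluorophore tail (FAM for allele 1 = alien, HEX for allele 2 = host),
compete against one common reverse primer.  Candidate SNPs are called
from an alignment of alien sequence against the host genome and accepted
only when they are the single mismatch within a host-consistent flanking
window, so both allele primers and the common primer sit on sequence
shared by host and donor — that is what makes the assay co-dominant.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from alienmark import _blast
from alienmark.genome import Genome, revcomp
from alienmark.primers import (
    MismatchPolicy,
    SiteCache,
    gc_fraction,
    insilico_pcr,
    melting_temperature,
)
from alienmark.specificity import ConservedLocus

TAIL_FAM = "gaaggtgaccaagttcatgct"
TAIL_HEX = "gaaggtcggagtcaacggatt"

DEFAULT_FLANK_RANGE = (40, 120)
DEFAULT_CONSISTENCY = 0.90


@dataclass
class DiagnosticSNP:
    """A single alien/host mismatch with clean, host-consistent flanks."""

    locus_id: str
    position: int  # 0-based offset in the alien (query) sequence
    alien_allele: str
    host_allele: str
    left_flank: str
    right_flank: str
    flank_host_identity: float

    def __post_init__(self) -> None:
        if self.alien_allele == self.host_allele:
            raise ValueError("diagnostic SNP alleles must differ")


@dataclass
class ScaffoldAnchor:
    locus_id: str
    scaffold_id: Optional[str]
    identity: float
    unique: bool
    expanded_sequence: Optional[str] = None
    hit_start: int = -1  # 0-based on the scaffold, query-strand oriented
    hit_end: int = -1


@dataclass
class KASPAssay:
    assay_id: str
    arm: str
    allele1_primer: str  # FAM tail + allele-specific sequence, 5'->3'
    allele2_primer: str  # HEX tail + allele-specific sequence
    common_primer: str
    alleles: Tuple[str, str]  # (allele 1 base, allele 2 base)
    snp_id: str = ""

    @property
    def allele1_core(self) -> str:
        return self.allele1_primer[len(TAIL_FAM) :]

    @property
    def allele2_core(self) -> str:
        return self.allele2_primer[len(TAIL_HEX) :]


@dataclass
class KaspPrimerConfig:
    """Allele-specific and common primer constraints.

    The allele-specific primer ends exactly on the SNP base and is extended
    5'-ward until its Tm reaches the target; the common primer is designed
    on the opposite strand within the right flank so the amplicon stays
    short, as endpoint-read chemistry prefers.
    """

    allele_min_length: int = 16
    allele_max_length: int = 28
    allele_tm_target: float = 52.0
    common_min_length: int = 18
    common_max_length: int = 25
    common_tm_target: float = 52.0
    common_gc_min: float = 0.25
    common_gc_max: float = 0.75
    product_min: int = 50
    product_max: int = 120


@dataclass
class KaspValidationReport:
    n_valid: int
    n_arms: int
    failures: List[Tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# scaffold anchoring


def anchor_to_scaffolds(
    locus: ConservedLocus | str,
    scaffolds: Genome,
    best_min_identity: float = 0.95,
    second_max_identity: float = 0.90,
    min_coverage: float = 0.80,
    expansion: int = 5000,
    locus_id: str = "locus",
) -> ScaffoldAnchor:
    """Anchor a locus to a donor scaffold set and expand around the hit.

    The anchor is unique when the best hit's identity reaches
    *best_min_identity* and no second hit (anywhere else) reaches
    *second_max_identity*.  The expanded sequence around a unique hit,
    oriented to the locus strand, is returned for diagnostic SNP search.
    """
    if not scaffolds.sequences:
        raise ValueError("scaffold set is empty")
    if isinstance(locus, ConservedLocus):
        seq, locus_id = locus.sequence, locus.locus_id
    else:
        seq = locus
    hits = _blast.blastn({locus_id: seq}, scaffolds.sequences)
    hits = hits[hits["length"] >= min_coverage * len(seq)].reset_index(drop=True)
    if not len(hits):
        return ScaffoldAnchor(locus_id, None, 0.0, False)
    best = hits.iloc[0]
    unique = best.pident / 100.0 >= best_min_identity and not any(
        row.pident / 100.0 >= second_max_identity for row in hits.iloc[1:].itertuples()
    )
    expanded = None
    start = end = -1
    if unique:
        scaffold = scaffolds.sequences[best.sseqid]
        s, e = sorted((best.sstart, best.send))
        start, end = max(0, s - 1 - expansion), min(len(scaffold), e + expansion)
        expanded = scaffold[start:end]
        if best.sstart > best.send:  # hit on minus strand: orient to locus
            expanded = revcomp(expanded)
    return ScaffoldAnchor(
        locus_id, best.sseqid, best.pident / 100.0, unique, expanded, start, end
    )


# ---------------------------------------------------------------------------
# diagnostic SNP calling


def _snps_from_hsp(
    qseq: str,
    sseq: str,
    qstart: int,
    locus_id: str,
    alien_seq: str,
    flank_range: Tuple[int, int],
    consistency: float,
) -> List[DiagnosticSNP]:
    """Walk one gapped HSP alignment and apply the single-SNP window rule."""
    min_flank, max_flank = flank_range
    columns = []  # (query_pos or None, kind, qbase, sbase)
    qpos = qstart
    for qb, sb in zip(qseq, sseq):
        if qb == "-":
            columns.append((None, "indel", qb, sb))
        elif sb == "-":
            columns.append((qpos, "indel", qb, sb))
            qpos += 1
        elif qb == sb:
            columns.append((qpos, "match", qb, sb))
            qpos += 1
        else:
            columns.append((qpos, "mismatch", qb, sb))
            qpos += 1

    n = len(columns)
    dirty = [i for i, c in enumerate(columns) if c[1] != "match"]
    out = []
    for i in dirty:
        pos, kind, qb, sb = columns[i]
        if kind != "mismatch" or qb not in "ACGT" or sb not in "ACGT":
            continue
        left_clean = i - max((j for j in dirty if j < i), default=-1) - 1
        right_clean = min((j for j in dirty if j > i), default=n) - i - 1
        # alignment edges also bound the clean flank
        left_clean = min(left_clean, i)
        right_clean = min(right_clean, n - 1 - i)
        if left_clean < min_flank or right_clean < min_flank:
            continue
        lo, hi = max(0, i - max_flank), min(n, i + max_flank + 1)
        window = columns[lo:hi]
        matches = sum(1 for c in window if c[1] == "match")
        if matches / (len(window) - 1) < consistency:  # SNP column excluded
            continue
        lf = min(max_flank, left_clean)
        rf = min(max_flank, right_clean)
        out.append(
            DiagnosticSNP(
                locus_id=locus_id,
                position=pos,
                alien_allele=qb,
                host_allele=sb,
                left_flank=alien_seq[pos - lf : pos],
                right_flank=alien_seq[pos + 1 : pos + 1 + rf],
                flank_host_identity=matches / (len(window) - 1),
            )
        )
    return out


def call_diagnostic_snps(
    alien_seq: str,
    host: Genome,
    flank_range: Tuple[int, int] = DEFAULT_FLANK_RANGE,
    consistency: float = DEFAULT_CONSISTENCY,
    min_hit_identity: float = 0.80,
    locus_id: str = "locus",
) -> List[DiagnosticSNP]:
    """Diagnostic SNPs between an alien sequence and its best host homolog.

    Every aligned mismatch column is accepted iff it is the only mismatch
    within *flank_range* clean columns on each side (indel-adjacent columns
    are excluded) and the surrounding window matches the host at or above
    the consistency threshold.  Returns an empty list when no host homolog
    aligns at *min_hit_identity* or better.
    """
    if not host.sequences:
        raise ValueError("host genome has no contigs")
    min_flank, _ = flank_range
    hits = _blast.blastn({locus_id: alien_seq}, host.sequences)
    if not len(hits):
        return []
    hits = hits[
        (hits["pident"] >= 100.0 * min_hit_identity)
        & (hits["length"] >= 2 * min_flank + 1)
    ]
    seen = set()
    snps: List[DiagnosticSNP] = []
    for row in hits.itertuples():
        for snp in _snps_from_hsp(
            row.qseq,
            row.sseq,
            row.qstart - 1,
            locus_id,
            alien_seq,
            flank_range,
            consistency,
        ):
            if snp.position not in seen:
                seen.add(snp.position)
                snps.append(snp)
    snps.sort(key=lambda s: s.position)
    return snps


# ---------------------------------------------------------------------------
# assay construction


def _allele_primer_core(
    template: str, snp_index: int, cfg: KaspPrimerConfig
) -> str:
    """Extend 5'-ward from the SNP base until the Tm target is reached."""
    for length in range(cfg.allele_min_length, cfg.allele_max_length + 1):
        start = snp_index - length + 1
        if start < 0:
            break
        core = template[start : snp_index + 1]
        if melting_temperature(core) >= cfg.allele_tm_target:
            return core
    raise ValueError("primer window exhausted")


def build_kasp_assay(
    snp: DiagnosticSNP,
    arm: str,
    cfg: Optional[KaspPrimerConfig] = None,
    assay_id: Optional[str] = None,
) -> KASPAssay:
    """Turn a diagnostic SNP into a tailed co-dominant KASP assay.

    Both allele primers share the same template footprint ending on the
    SNP; the common primer primes the opposite strand inside the right
    flank within the product-size bounds.  Raises ``ValueError("primer
    window exhausted")`` when no primer satisfying the constraints exists.
    """
    cfg = cfg or KaspPrimerConfig()
    template = snp.left_flank + snp.alien_allele + snp.right_flank
    p = len(snp.left_flank)

    core1 = _allele_primer_core(template, p, cfg)
    core2 = core1[:-1] + snp.host_allele
    allele_start = p - len(core1) + 1

    best = None
    for length in range(cfg.common_min_length, cfg.common_max_length + 1):
        for s in range(p + 1, len(template) - length + 1):
            product = s + length - allele_start
            if product > cfg.product_max:
                break
            if product < cfg.product_min:
                continue
            primer = revcomp(template[s : s + length])
            gc = gc_fraction(primer)
            if not cfg.common_gc_min <= gc <= cfg.common_gc_max:
                continue
            tm = melting_temperature(primer)
            penalty = abs(tm - cfg.common_tm_target)
            if best is None or penalty < best[0]:
                best = (penalty, primer)
    if best is None:
        raise ValueError("primer window exhausted")

    return KASPAssay(
        assay_id=assay_id or f"K_{snp.locus_id}",
        arm=arm,
        allele1_primer=TAIL_FAM + core1,
        allele2_primer=TAIL_HEX + core2,
        common_primer=best[1],
        alleles=(snp.alien_allele, snp.host_allele),
        snp_id=f"{snp.locus_id}:{snp.position}",
    )


# ---------------------------------------------------------------------------
# validation and serialisation


def _check_assay(assay: KASPAssay) -> Optional[str]:
    a1, a2 = assay.allele1_primer, assay.allele2_primer
    if not a1.lower().startswith(TAIL_FAM) or not a2.lower().startswith(TAIL_HEX):
        return "tail mismatch"
    core1 = a1[len(TAIL_FAM) :].upper()
    core2 = a2[len(TAIL_HEX) :].upper()
    if not core1 or not core2 or len(core1) != len(core2):
        return "allele-specific length mismatch"
    if core1[:-1] != core2[:-1]:
        return "non-terminal variant"
    if core1[-1] == core2[-1]:
        return "identical alleles"
    if (core1[-1], core2[-1]) != tuple(b.upper() for b in assay.alleles):
        return "allele mismatch"
    if not assay.arm:
        return "missing arm label"
    common = assay.common_primer.upper()
    if not common or set(common) - set("ACGT"):
        return "bad common primer"
    return None


def validate_kasp_table(assays: Sequence[KASPAssay]) -> KaspValidationReport:
    """Check every assay invariant; failures are report entries, not errors."""
    failures = []
    arms = set()
    for assay in assays:
        reason = _check_assay(assay)
        if reason is None:
            arms.add(assay.arm)
        else:
            failures.append((assay.assay_id, reason))
    return KaspValidationReport(
        n_valid=len(assays) - len(failures), n_arms=len(arms), failures=failures
    )


def write_kasp_table(assays: Sequence[KASPAssay], path) -> None:
    rows = []
    for a in assays:
        rows.append((a.assay_id, a.arm, "F", a.allele1_primer))
        rows.append((a.assay_id, a.arm, "H", a.allele2_primer))
        rows.append((a.assay_id, a.arm, "C", a.common_primer))
    pd.DataFrame(rows, columns=["assay_id", "arm", "primer_role", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def load_kasp_table(path) -> List[KASPAssay]:
    """Read a long-format KASP table (assay_id, arm, primer_role, sequence)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    assays = []
    for (assay_id, arm), grp in df.groupby(["assay_id", "arm"], sort=False):
        roles = dict(zip(grp["primer_role"], grp["sequence"]))
        missing = {"F", "H", "C"} - set(roles)
        if missing:
            raise ValueError(f"assay {assay_id!r} is missing primer roles {sorted(missing)}")
        a1 = roles["F"][len(TAIL_FAM) :].upper()
        a2 = roles["H"][len(TAIL_HEX) :].upper()
        alleles = (a1[-1] if a1 else "N", a2[-1] if a2 else "N")
        assays.append(
            KASPAssay(
                assay_id=str(assay_id),
                arm=str(arm),
                allele1_primer=roles["F"],
                allele2_primer=roles["H"],
                common_primer=roles["C"],
                alleles=alleles,
            )
        )
    return assays


def bundled_rye_panel() -> List[KASPAssay]:
    """The published 14-assay rye chromosome-arm KASP panel shipped with
    the package (one co-dominant assay per arm, 1RS through 7RL)."""
    ref = importlib.resources.files("alienmark").joinpath("data/kasp_panel_rye.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_kasp_table(path)


# ---------------------------------------------------------------------------
# in-silico genotyping of an assay on a genome


def insilico_kasp_genotype(
    assay: KASPAssay,
    genome: Genome,
    policy: Optional[MismatchPolicy] = None,
    cache: Optional[SiteCache] = None,
) -> str:
    """Predicted endpoint genotype of *genome* for *assay*.

    Runs each untailed allele primer with the common primer under the
    3'-clamp policy; returns ``A1A1``, ``A2A2``, ``A1A2`` or ``no_amp``.
    """
    policy = policy or MismatchPolicy(max_product=300)
    cache = cache or SiteCache()
    a1 = bool(insilico_pcr((assay.allele1_core, assay.common_primer), genome, policy, cache))
    a2 = bool(insilico_pcr((assay.allele2_core, assay.common_primer), genome, policy, cache))
    if a1 and a2:
        return "A1A2"
    if a1:
        return "A1A1"
    if a2:
        return "A2A2"
    return "no_amp"
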