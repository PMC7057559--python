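"""PCR primer design and in-silico amplification.

Primer pairs are designed on conserved alien-specific loci with a
nearest-neighbor melting-temperature model and ranked by a penalty that
sums Tm deviation from target and GC deviation.  In-silico PCR finds every
correctly oriented primer-site pair on a genome under a mismatch policy
with a strict 3' clamp (zero mismatches in the 3'-terminal bases), the
standard allele-discrimination assumption.  The boolean marker x line
amplification matrix over a diagnostic panel is the input to chromosome
and arm assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from alienmark.genome import Genome, revcomp
from alienmark.panel import LinePanel
from alienmark.specificity import ConservedLocus


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm (degC), Allawi & SantaLucia 1997 parameters.

    50 mM Na+, 25 nM each strand (the model defaults); no chemical
    corrections.
    """
    return float(_mt.Tm_NN(seq))


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass
class PrimerConfig:
    """Constraints for PCR primer design (annealing at 58 degC downstream)."""

    min_length: int = 18
    max_length: int = 25
    tm_target: float = 60.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    product_min: int = 100
    product_max: int = 450
    max_run: int = 4
    max_pairs: int = 5
    candidates_per_side: int = 40


@dataclass
class MismatchPolicy:
    """Binding-site tolerance for in-silico PCR."""

    max_mismatches: int = 2
    clamp: int = 3  # 3'-terminal bases requiring exact match
    max_product: int = 2000


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size: int
    forward_start: int  # 0-based start of the forward primer in the source
    reverse_site_start: int  # 0-based start of the reverse primer's revcomp site


@dataclass
class PCRMarker:
    marker_id: str
    pair: PrimerPair
    source: str  # ConservedLocus id

    @property
    def expected_size(self) -> int:
        return self.pair.product_size


@dataclass(frozen=True)
class Amplicon:
    contig: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class AmplificationMatrix:
    """Boolean marker x line in-silico PCR outcomes."""

    values: pd.DataFrame  # index: marker ids, columns: line ids, dtype bool

    @property
    def markers(self) -> List[str]:
        return list(self.values.index)

    @property
    def lines(self) -> List[str]:
        return list(self.values.columns)

    def row(self, marker_id: str) -> Dict[str, bool]:
        return {k: bool(v) for k, v in self.values.loc[marker_id].items()}

    def to_tsv(self, path) -> None:
        out = self.values.astype(int)
        out.index.name = "marker_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "AmplificationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
        return cls(values=df)


# ---------------------------------------------------------------------------
# primer design


def _candidates(seq: str, cfg: PrimerConfig, reverse: bool) -> List[dict]:
    """Enumerate and rank single-primer candidates on one strand."""
    out = []
    n = len(seq)
    for length in range(cfg.min_length, cfg.max_length + 1):
        for start in range(0, n - length + 1):
            site = seq[start : start + length]
            primer = revcomp(site) if reverse else site
            gc = gc_fraction(primer)
            if not cfg.gc_min <= gc <= cfg.gc_max:
                continue
            if max_homopolymer_run(primer) > cfg.max_run:
                continue
            if seq.count(site) != 1:
                continue
            tm = melting_temperature(primer)
            penalty = abs(tm - cfg.tm_target) + 5.0 * abs(gc - 0.5)
            out.append(
                {
                    "primer": primer,
                    "start": start,
                    "length": length,
                    "tm": tm,
                    "gc": gc,
                    "penalty": penalty,
                }
            )
    out.sort(key=lambda c: (c["penalty"], c["start"], c["length"]))
    return out[: cfg.candidates_per_side]


def design_primers(
    locus: ConservedLocus | str,
    cfg: Optional[PrimerConfig] = None,
) -> List[PrimerPair]:
    """Ranked candidate primer pairs for a locus; empty if none satisfy.

    Deterministic: candidates are enumerated exhaustively, ranked by the
    penalty ``|Tm - target| + GC deviation`` per primer plus the pair's Tm
    difference, ties broken by position.
    """
    cfg = cfg or PrimerConfig()
    seq = locus.sequence if isinstance(locus, ConservedLocus) else locus
    if len(seq) < cfg.product_min:
        raise ValueError(
            f"locus length {len(seq)} below minimum product size {cfg.product_min}"
        )
    fwd = _candidates(seq, cfg, reverse=False)
    rev = _candidates(seq, cfg, reverse=True)
    pairs = []
    for f in fwd:
        for r in rev:
            if r["start"] < f["start"] + f["length"]:
                continue
            product = r["start"] + r["length"] - f["start"]
            if not cfg.product_min <= product <= cfg.product_max:
                continue
            penalty = f["penalty"] + r["penalty"] + abs(f["tm"] - r["tm"])
            pairs.append((penalty, f, r, product))
    pairs.sort(key=lambda t: (t[0], t[1]["start"], t[2]["start"]))
    out = []
    for penalty, f, r, product in pairs[: cfg.max_pairs]:
        out.append(
            PrimerPair(
                forward=f["primer"],
                reverse=r["primer"],
                tm_forward=f["tm"],
                tm_reverse=r["tm"],
                gc_forward=f["gc"],
                gc_reverse=r["gc"],
                product_size=product,
                forward_start=f["start"],
                reverse_site_start=r["start"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# in-silico PCR


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _find_sites(
    pattern: str,
    arr: np.ndarray,
    max_mm: int,
    clamp: int,
    clamp_at_end: bool,
) -> np.ndarray:
    """Start positions where *pattern* matches with <= max_mm mismatches and
    an exact clamp (the clamp bases must match with zero mismatches)."""
    p = _encode(pattern)
    L = len(p)
    n = arr.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    clamp = min(clamp, L)
    clamp_positions = range(L - clamp, L) if clamp_at_end else range(0, clamp)
    mask: Optional[np.ndarray] = None
    for j in clamp_positions:
        eq = arr[j : j + n] == p[j]
        mask = eq if mask is None else (mask & eq)
    cand = np.nonzero(mask)[0] if mask is not None else np.arange(n)
    if cand.size == 0:
        return cand
    mm = np.zeros(cand.size, dtype=np.int32)
    clamp_set = set(clamp_positions)
    for j in range(L):
        if j in clamp_set:
            continue
        mm += (arr[cand + j] != p[j]).astype(np.int32)
    return cand[mm <= max_mm]


class SiteCache:
    """Memoises primer binding-site scans per (pattern, contig).

    Contigs are identified by name, length and string hash; within one
    analysis a contig name always denotes one sequence, so cached scans are
    shared across panel lines that carry the same contig.
    """

    def __init__(self) -> None:
        self._sites: Dict[tuple, np.ndarray] = {}
        self._arrays: Dict[tuple, np.ndarray] = {}

    def sites(
        self,
        pattern: str,
        contig: str,
        seq: str,
        max_mm: int,
        clamp: int,
        clamp_at_end: bool,
    ) -> np.ndarray:
        token = (contig, len(seq), hash(seq))
        key = (pattern, clamp_at_end, token)
        if key not in self._sites:
            if token not in self._arrays:
                self._arrays[token] = _encode(seq)
            self._sites[key] = _find_sites(
                pattern, self._arrays[token], max_mm, clamp, clamp_at_end
            )
        return self._sites[key]


def insilico_pcr(
    pair: PrimerPair | Tuple[str, str],
    genome: Genome,
    policy: Optional[MismatchPolicy] = None,
    cache: Optional[SiteCache] = None,
) -> List[Amplicon]:
    """Every amplicon the pair supports on *genome* under *policy*.

    Both primer-role orientations are considered (either primer may act as
    the left, plus-strand primer).  Primer sites must not overlap and the
    product must not exceed the policy's size cap.
    """
    policy = policy or MismatchPolicy()
    fwd, rev = (pair.forward, pair.reverse) if isinstance(pair, PrimerPair) else pair
    cache = cache or SiteCache()
    found = set()
    for contig, seq in genome.sequences.items():
        for left, right in ((fwd, rev), (rev, fwd)):
            lsites = cache.sites(
                left, contig, seq, policy.max_mismatches, policy.clamp, True
            )
            rpattern = revcomp(right)
            rsites = cache.sites(
                rpattern, contig, seq, policy.max_mismatches, policy.clamp, False
            )
            if lsites.size == 0 or rsites.size == 0:
                continue
            lL, rL = len(left), len(right)
            for a in lsites:
                lo = np.searchsorted(rsites, a + lL)
                hi = np.searchsorted(rsites, a + policy.max_product - rL, side="right")
                for s in rsites[lo:hi]:
                    found.add((contig, int(a), int(s) + rL))
    return [Amplicon(c, s, e) for c, s, e in sorted(found)]


def amplification_matrix(
    markers: Sequence[PCRMarker],
    panel: LinePanel,
    line_genomes: Dict[str, Genome],
    policy: Optional[MismatchPolicy] = None,
    size_tolerance: float = 0.10,
) -> AmplificationMatrix:
    """In-silico amplification of every marker on every panel line.

    A cell is True iff at least one amplicon falls within +/- 10% (by
    default) of the marker's expected product size, standing in for band
    scoring at gel resolution.
    """
    policy = policy or MismatchPolicy()
    for line in panel.lines:
        if line.line_id not in line_genomes:
            raise ValueError(f"no genome provided for panel line {line.line_id!r}")
    cache = SiteCache()
    data = {}
    for line in panel.lines:
        genome = line_genomes[line.line_id]
        col = []
        for marker in markers:
            amps = insilico_pcr(marker.pair, genome, policy, cache)
            expected = marker.expected_size
            tol = size_tolerance * expected
            col.append(any(abs(a.size - expected) <= tol for a in amps))
        data[line.line_id] = col
    df = pd.DataFrame(data, index=[m.marker_id for m in markers], dtype=bool)
    return AmplificationMatrix(values=df)


def markers_to_frame(markers: Sequence[PCRMarker], arms: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Primer table: marker_id, arm (if assigned), sequences, product size."""
    arms = arms or {}
    return pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "arm": [arms.get(m.marker_id, "") for m in markers],
            "forward": [m.pair.forward for m in markers],
            "reverse": [m.pair.reverse for m in markers],
            "product_size": [m.expected_size for m in markers],
        }
    )
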