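"""Synthetic host/alien genomes, diagnostic panels and fluorescence plates.

The simulator emulates the discovery design this pipeline was built for:
several cultivars of an outcrossing alien donor sharing conserved
donor-specific regions, a host genome to which the donor background is
largely homologous, a complete disomic/ditelosomic addition-line panel for
placement, and endpoint-fluorescence plates.  Every feature is recorded in
a truth table so downstream stages can be scored exactly.

Model choices (see docs/methods.md): alien chromosomes are host-homologous
backgrounds (per-base substitutions at 1 - background identity) carrying
embedded donor-specific regions of random sequence; cultivar divergence is
substitution-only and, by default, applied outside conserved regions so
universal markers exist by construction; the centromere sits at the
chromosome midpoint and no region straddles it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from alienmark.genome import Genome
from alienmark.genotyping import (
    CALL_A1A1,
    CALL_A2A2,
    CALL_HET,
    CALL_NTC,
    FluorescenceReading,
    GenotypeCall,
)
from alienmark.panel import (
    ARMS,
    LinePanel,
    LineSpec,
    ROLE_ALIEN,
    ROLE_DISOMIC,
    ROLE_HOST,
    ROLE_TELO,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic discovery experiment.

    Defaults are the package's reference conditions: 7 alien chromosomes of
    750 kb against a 2 x 750 kb host, backgrounds at 99% identity to the
    host, 56 donor-specific regions per Mb of 4-8 kb, five discovery
    cultivars (plus one held-out donor) diverged at 0.5% outside conserved
    regions, and fluorescence clusters separated far beyond the noise.
    """

    seed: int = 0
    n_host_chromosomes: int = 2
    n_alien_chromosomes: int = 7
    chromosome_length: int = 750_000
    n_cultivars: int = 5  # discovery cultivars; one held-out donor is always added
    alien_specific_region_rate: float = 56.0  # regions per Mb
    alien_specific_region_length: Tuple[int, int] = (4_000, 8_000)
    cultivar_divergence: float = 0.005  # substitutions per base between cultivars
    host_alien_background_identity: float = 0.99
    conserved_region_fraction: float = 1.0
    diverge_specific_regions: bool = False
    fluorescence_noise_sd: float = 0.05
    ntc_signal_mean: float = 0.06
    signal_high: float = 1.0
    signal_low: float = 0.08
    scaffold_piece_length: int = 20_000

    def validate(self) -> None:
        for name in (
            "cultivar_divergence",
            "host_alien_background_identity",
            "conserved_region_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.alien_specific_region_length
        if lo <= 0 or hi < lo:
            raise ValueError("region length range must be positive and ordered")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.alien_specific_region_rate < 0:
            raise ValueError("region rate must be non-negative")
        if self.fluorescence_noise_sd < 0:
            raise ValueError("fluorescence noise sd must be non-negative")
        n_regions = self._regions_per_chromosome()
        if n_regions * hi > 0.8 * self.chromosome_length:
            raise ValueError(
                "configuration error: specific regions would cover more than "
                "80% of each chromosome"
            )

    def _regions_per_chromosome(self) -> int:
        return int(round(self.alien_specific_region_rate * self.chromosome_length / 1e6))


@dataclass(frozen=True)
class Region:
    region_id: str
    chromosome: str
    start: int
    end: int
    arm: str  # "S" (first half) or "L" (second half)
    conserved: bool

    @property
    def arm_id(self) -> str:
        return self.chromosome + self.arm


@dataclass
class TruthTable:
    """Ground truth: every planted donor-specific region with its arm."""

    regions: List[Region]
    midpoints: Dict[str, int]  # chromosome -> centromere coordinate

    @property
    def empty(self) -> bool:
        return not self.regions

    def region_overlapping(self, chromosome: str, start: int, end: int) -> Optional[Region]:
        for r in self.regions:
            if r.chromosome == chromosome and r.start < end and start < r.end:
                return r
        return None

    def arm_of(self, chromosome: str, position: int) -> str:
        return "S" if position < self.midpoints[chromosome] else "L"

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "chromosome": [r.chromosome for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "arm": [r.arm for r in self.regions],
                "conserved": [int(r.conserved) for r in self.regions],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, midpoints: Optional[Dict[str, int]] = None) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        regions = [
            Region(
                region_id=str(r.region_id),
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                arm=str(r.arm),
                conserved=bool(r.conserved),
            )
            for r in df.itertuples()
        ]
        return cls(regions=regions, midpoints=midpoints or {})


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _mutate(
    codes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    protect: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Substitute each unprotected base with probability *rate*; a
    substituted base always changes (shift by 1-3 in code space)."""
    out = codes.copy()
    if rate <= 0:
        return out
    hits = rng.random(codes.size) < rate
    if protect is not None:
        hits &= ~protect
    idx = np.nonzero(hits)[0]
    if idx.size:
        shift = rng.integers(1, 4, idx.size, dtype=np.uint8)
        out[idx] = (out[idx] + shift) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genomes(
    config: SimulationConfig,
) -> Tuple[Genome, List[Genome], TruthTable]:
    """Generate the host, the cultivar set and the ground truth.

    Returns ``(host, cultivars, truth)`` where *cultivars* holds the
    discovery cultivars followed by one held-out donor (the addition-line
    parent, last element).  Fixed seed implies byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length

    host_codes = {
        f"H{i + 1}": _random_codes(rng, L) for i in range(config.n_host_chromosomes)
    }

    # ancestral alien genome: host-homologous background + specific regions
    bg_rate = 1.0 - config.host_alien_background_identity
    lo, hi = config.alien_specific_region_length
    n_regions = config._regions_per_chromosome()
    ancestral: Dict[str, np.ndarray] = {}
    regions: List[Region] = []
    midpoints: Dict[str, int] = {}
    for j in range(config.n_alien_chromosomes):
        chrom = f"{j + 1}R"
        base = host_codes[f"H{(j % config.n_host_chromosomes) + 1}"]
        codes = _mutate(base, bg_rate, rng)
        mid = L // 2
        midpoints[chrom] = mid
        n_short = n_regions // 2
        counter = 0
        for arm, astart, aend, n_arm in (
            ("S", 0, mid, n_short),
            ("L", mid, L, n_regions - n_short),
        ):
            if n_arm == 0:
                continue
            slot = (aend - astart) // n_arm
            if slot < hi + 400:
                raise ValueError(
                    "configuration error: arm too short for the requested "
                    "number and length of specific regions"
                )
            for k in range(n_arm):
                length = int(rng.integers(lo, hi + 1))
                offset = int(rng.integers(200, slot - length - 200 + 1))
                start = astart + k * slot + offset
                codes[start : start + length] = _random_codes(rng, length)
                counter += 1
                conserved = bool(rng.random() < config.conserved_region_fraction)
                regions.append(
                    Region(
                        region_id=f"{chrom}{arm}_{counter:03d}",
                        chromosome=chrom,
                        start=start,
                        end=start + length,
                        arm=arm,
                        conserved=conserved,
                    )
                )
        ancestral[chrom] = codes

    truth = TruthTable(regions=regions, midpoints=midpoints)

    # protection mask: conserved regions do not diverge between cultivars
    protect: Dict[str, np.ndarray] = {}
    for chrom in ancestral:
        mask = np.zeros(L, dtype=bool)
        if not config.diverge_specific_regions:
            for r in regions:
                if r.chromosome == chrom and r.conserved:
                    mask[r.start : r.end] = True
        protect[chrom] = mask

    cultivars: List[Genome] = []
    names = [f"cultivar_{i + 1}" for i in range(config.n_cultivars)] + ["donor"]
    for name in names:
        seqs = {
            chrom: _to_str(
                _mutate(ancestral[chrom], config.cultivar_divergence, rng, protect[chrom])
            )
            for chrom in ancestral
        }
        cultivars.append(Genome(id=name, sequences=seqs, role="alien_cultivar"))

    host = Genome(
        id="host",
        sequences={cid: _to_str(codes) for cid, codes in host_codes.items()},
        role="host",
    )
    return host, cultivars, truth


def build_panel(host: Genome, alien: Genome) -> Tuple[LinePanel, Dict[str, Genome]]:
    """Complete addition-line panel: host and alien controls, one disomic
    addition per alien chromosome, and S/L ditelosomic additions per
    chromosome.  Returns the panel and each line's genome."""
    if not alien.sequences:
        raise ValueError("alien genome has no chromosomes")
    lines: List[LineSpec] = [
        LineSpec("host_ctrl", ROLE_HOST, ()),
        LineSpec("alien_ctrl", ROLE_ALIEN, tuple(alien.sequences)),
    ]
    genomes: Dict[str, Genome] = {
        "host_ctrl": Genome("host_ctrl", dict(host.sequences), role="line"),
        # the alien control is the donor cultivar itself, no host background
        "alien_ctrl": Genome("alien_ctrl", dict(alien.sequences), role="line"),
    }
    for chrom, seq in alien.sequences.items():
        line_id = f"DA_{chrom}"
        lines.append(LineSpec(line_id, ROLE_DISOMIC, (chrom,)))
        genomes[line_id] = Genome(
            line_id, dict(host.sequences) | {chrom: seq}, role="line"
        )
        mid = len(seq) // 2
        for arm, piece in zip(ARMS, (seq[:mid], seq[mid:])):
            line_id = f"DT_{chrom}{arm}"
            lines.append(LineSpec(line_id, ROLE_TELO, (chrom + arm,)))
            genomes[line_id] = Genome(
                line_id, dict(host.sequences) | {chrom + arm: piece}, role="line"
            )
    panel = LinePanel(lines=lines, host_id=host.id, alien_id=alien.id)
    panel.validate(chromosomes=list(alien.sequences))
    return panel, genomes


def make_scaffolds(genome: Genome, piece_length: int = 20_000) -> Genome:
    """Chop a genome into a scaffold-like assembly of fixed-size pieces.

    Scaffold ids encode their source contig and offset (``3R:40000``), so
    anchors can be compared against truth coordinates.
    """
    pieces = {}
    for contig, seq in genome.sequences.items():
        for start in range(0, len(seq), piece_length):
            piece = seq[start : start + piece_length]
            if piece:
                pieces[f"{contig}:{start}"] = piece
    return Genome(id=f"{genome.id}_scaffolds", sequences=pieces, role="alien_cultivar")


_PLATE_MEANS = {
    CALL_A1A1: ("high", "low"),
    CALL_A2A2: ("low", "high"),
    CALL_HET: ("high", "high"),
    CALL_NTC: ("ntc", "ntc"),
}


def simulate_plate(
    assay_id: str,
    sample_genotypes: Sequence[Tuple[str, str]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[FluorescenceReading], List[GenotypeCall]]:
    """Endpoint fluorescence for samples of known genotype.

    Each genotype class is a 2-D Gaussian on the FAM/HEX plane (no
    passive-reference drift is modelled); no-template wells sit near the
    NTC signal mean and are flagged as declared controls.
    """
    if config.fluorescence_noise_sd < 0:
        raise ValueError("configuration error: negative fluorescence noise sd")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    levels = {
        "high": config.signal_high,
        "low": config.signal_low,
        "ntc": config.ntc_signal_mean,
    }
    readings, truth = [], []
    for sample_id, genotype in sample_genotypes:
        if genotype not in _PLATE_MEANS:
            raise ValueError(f"unknown genotype {genotype!r} for sample {sample_id!r}")
        fam_mean, hex_mean = (levels[k] for k in _PLATE_MEANS[genotype])
        fam = max(0.0, fam_mean + rng.normal(0.0, config.fluorescence_noise_sd))
        hex_ = max(0.0, hex_mean + rng.normal(0.0, config.fluorescence_noise_sd))
        readings.append(
            FluorescenceReading(
                sample_id=sample_id,
                fam=fam,
                hex=hex_,
                is_ntc_control=genotype == CALL_NTC,
            )
        )
        truth.append(GenotypeCall(sample_id, genotype, 1.0))
    return readings, truth
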