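"""Endpoint-fluorescence genotype calling and screen summaries.

Samples live on the FAM/HEX plane: allele-1 homozygotes along the FAM
axis, allele-2 homozygotes along the HEX axis, heterozygotes on the
diagonal, and no-template wells near the origin.  After an NTC magnitude
gate, callable samples are normalised to unit vectors and clustered by a
spherical k-means seeded at the three known genotype directions.  The
whole decision path is built from commuted sums and products of the two
channels, so swapping FAM and HEX provably swaps the two homozygote calls
and multiplying both channels by a constant leaves calls unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CALL_A1A1 = "A1A1"
CALL_HET = "A1A2"
CALL_A2A2 = "A2A2"
CALL_NTC = "NTC"
CALL_NONE = "no_call"

GENOTYPE_CALLS = (CALL_A1A1, CALL_HET, CALL_A2A2)

# maximal dot-product gap between adjacent cluster directions (unit vectors
# 45 degrees apart); normalises the confidence margin to [0, 1]
_MAX_GAP = 1.0 - math.cos(math.pi / 4)


@dataclass(frozen=True)
class FluorescenceReading:
    sample_id: str
    fam: float
    hex: float
    is_ntc_control: bool = False

    def __post_init__(self) -> None:
        for name, v in (("fam", self.fam), ("hex", self.hex)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{name} signal of sample {self.sample_id!r} must be finite and >= 0"
                )


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass
class CallerConfig:
    ntc_floor: float = 0.20  # magnitude gate when no NTC controls declared
    ntc_sigma: float = 3.0  # gate = NTC mean + sigma * sd when declared
    no_call_margin: float = 0.10  # minimum normalised margin between clusters
    max_iterations: int = 50


def _cluster_directions(
    units: Sequence[Tuple[float, float]], max_iterations: int
) -> List[Tuple[float, float]]:
    """Spherical k-means with fixed genotype seeds; empty clusters keep them."""
    s = math.sqrt(0.5)
    centers = [(1.0, 0.0), (s, s), (0.0, 1.0)]
    assign = [-1] * len(units)
    for _ in range(max_iterations):
        new_assign = [
            max(range(3), key=lambda k: f * centers[k][0] + h * centers[k][1])
            for f, h in units
        ]
        if new_assign == assign:
            break
        assign = new_assign
        for k in range(3):
            fs = sum(f for (f, _), a in zip(units, assign) if a == k)
            hs = sum(h for (_, h), a in zip(units, assign) if a == k)
            norm = math.hypot(fs, hs)
            if norm > 0:
                centers[k] = (fs / norm, hs / norm)
    return centers


def call_genotypes(
    readings: Sequence[FluorescenceReading],
    config: Optional[CallerConfig] = None,
) -> List[GenotypeCall]:
    """Call co-dominant genotypes from two-channel endpoint fluorescence.

    The NTC gate comes from declared no-template controls (mean + k sd of
    their magnitudes) when present, else from the configured floor.  A
    sample whose best and second-best cluster directions are closer than
    the no-call margin is reported as ``no_call``.
    """
    if not readings:
        raise ValueError("no fluorescence readings supplied")
    config = config or CallerConfig()

    mags = [math.hypot(r.fam, r.hex) for r in readings]
    ntc_mags = [m for r, m in zip(readings, mags) if r.is_ntc_control]
    if ntc_mags:
        mean = sum(ntc_mags) / len(ntc_mags)
        sd = math.sqrt(sum((m - mean) ** 2 for m in ntc_mags) / len(ntc_mags))
        gate = max(config.ntc_floor, mean + config.ntc_sigma * sd)
    else:
        gate = config.ntc_floor

    callable_idx = [i for i, m in enumerate(mags) if m > gate and not readings[i].is_ntc_control]
    if not callable_idx:
        warnings.warn("no sample rises above the no-template gate; all calls are NTC")
    units = [(readings[i].fam / mags[i], readings[i].hex / mags[i]) for i in callable_idx]
    centers = _cluster_directions(units, config.max_iterations) if units else []

    calls: List[GenotypeCall] = []
    unit_of = dict(zip(callable_idx, units))
    for i, reading in enumerate(readings):
        if i not in unit_of:
            conf = min(1.0, max(0.0, 1.0 - mags[i] / gate)) if gate > 0 else 1.0
            calls.append(GenotypeCall(reading.sample_id, CALL_NTC, conf))
            continue
        f, h = unit_of[i]
        dots = [f * cx + h * cy for cx, cy in centers]
        order = sorted(range(3), key=lambda k: dots[k], reverse=True)
        margin = (dots[order[0]] - dots[order[1]]) / _MAX_GAP
        margin = min(1.0, max(0.0, margin))
        if margin < config.no_call_margin:
            calls.append(GenotypeCall(reading.sample_id, CALL_NONE, margin))
        else:
            calls.append(GenotypeCall(reading.sample_id, GENOTYPE_CALLS[order[0]], margin))
    return calls


@dataclass
class ScreenSummary:
    counts: Dict[str, int]
    n_samples: int  # non-NTC wells
    carriers: Optional[int] = None
    carrier_fraction: Optional[float] = None
    low_quality: bool = False
    concordance: Optional[float] = None
    concordance_table: Optional[pd.DataFrame] = None


def summarize_screen(
    calls: Sequence[GenotypeCall],
    semantics: str = "alien_arm_screen",
    second_calls: Optional[Sequence[GenotypeCall]] = None,
) -> ScreenSummary:
    """Summarise one assay's calls across a screened population.

    Under ``alien_arm_screen`` semantics the alien arm is hemizygous in a
    host background, so carriers show both alleles (heterozygous signal);
    the donor control is the only allele-1 homozygote.  Carriers are
    therefore counted as A1A2 plus A1A1.  A second call set (for example
    gel-based calls of the matching PCR marker) yields a concordance table.
    """
    if semantics not in ("alien_arm_screen", "codominant"):
        raise ValueError(f"unknown screen semantics {semantics!r}")
    counts: Dict[str, int] = {}
    for c in calls:
        counts[c.call] = counts.get(c.call, 0) + 1
    if not calls:
        return ScreenSummary(counts={}, n_samples=0)
    n_samples = sum(v for k, v in counts.items() if k != CALL_NTC)
    summary = ScreenSummary(counts=counts, n_samples=n_samples)
    summary.low_quality = n_samples > 0 and counts.get(CALL_NONE, 0) == n_samples
    if semantics == "alien_arm_screen":
        carriers = counts.get(CALL_HET, 0) + counts.get(CALL_A1A1, 0)
        summary.carriers = carriers
        summary.carrier_fraction = carriers / n_samples if n_samples else 0.0
    if second_calls is not None:
        a = {c.sample_id: c.call for c in calls}
        b = {c.sample_id: c.call for c in second_calls}
        shared = sorted(set(a) & set(b))
        if shared:
            table = pd.crosstab(
                pd.Series([a[s] for s in shared], name="calls"),
                pd.Series([b[s] for s in shared], name="second"),
            )
            summary.concordance_table = table
            summary.concordance = sum(a[s] == b[s] for s in shared) / len(shared)
    return summary


def read_plate_csv(path) -> List[FluorescenceReading]:
    """Plate CSV with columns sample_id,fam,hex[,ntc]."""
    df = pd.read_csv(path)
    required = {"sample_id", "fam", "hex"}
    if not required <= set(df.columns):
        raise ValueError(f"plate file must have columns {sorted(required)}")
    has_ntc = "ntc" in df.columns
    return [
        FluorescenceReading(
            sample_id=str(r.sample_id),
            fam=float(r.fam),
            hex=float(r.hex),
            is_ntc_control=bool(r.ntc) if has_ntc else False,
        )
        for r in df.itertuples()
    ]


def write_calls_tsv(calls: Sequence[GenotypeCall], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "call": [c.call for c in calls],
            "confidence": [round(c.confidence, 4) for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
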