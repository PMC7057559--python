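"""Diagnostic line panels.

A panel declares the lines used to place markers: a host (euploid)
control, an alien (donor) control, one disomic addition line per alien
chromosome (host background plus one whole added alien chromosome pair)
and two ditelosomic addition lines per chromosome (one added telocentric
arm each).  Panels are data, not code: the assignment rule engine reads
roles from the panel, so any donor species works.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd

ROLE_HOST = "host_control"
ROLE_ALIEN = "alien_control"
ROLE_DISOMIC = "disomic_addition"
ROLE_TELO = "ditelosomic_addition"
ROLE_DERIVED = "derived"

ROLES = (ROLE_HOST, ROLE_ALIEN, ROLE_DISOMIC, ROLE_TELO, ROLE_DERIVED)

ARMS = ("S", "L")


@dataclass(frozen=True)
class LineSpec:
    """One panel line: id, role, and the alien content it carries.

    Content identifiers are chromosome ids (e.g. ``3R``) or arm ids
    (chromosome id + ``S``/``L``, e.g. ``3RS``).
    """

    line_id: str
    role: str
    content: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown panel role {self.role!r}")


@dataclass
class LinePanel:
    lines: List[LineSpec]
    host_id: str
    alien_id: str

    def validate(self, chromosomes: List[str] | None = None) -> None:
        """Check structural invariants (one chromosome per disomic line, one
        arm per ditelosomic line, empty host control, complete alien control)."""
        for line in self.lines:
            if line.role == ROLE_HOST and line.content:
                raise ValueError("host control must carry no alien content")
            if line.role == ROLE_DISOMIC and len(line.content) != 1:
                raise ValueError(
                    f"disomic line {line.line_id!r} must carry exactly one chromosome"
                )
            if line.role == ROLE_TELO:
                if len(line.content) != 1 or line.content[0][-1] not in ARMS:
                    raise ValueError(
                        f"ditelosomic line {line.line_id!r} must carry exactly one arm"
                    )
        if chromosomes is not None:
            telo_arms = {l.content[0] for l in self.lines if l.role == ROLE_TELO}
            for chrom in chromosomes:
                for arm in ARMS:
                    if sum(1 for a in telo_arms if a == chrom + arm) != 1:
                        raise ValueError(f"panel lacks a unique {chrom}{arm} ditelosomic line")

    # -- role lookups ------------------------------------------------------

    def host_control(self) -> LineSpec:
        return self._single(ROLE_HOST)

    def alien_control(self) -> LineSpec:
        return self._single(ROLE_ALIEN)

    def _single(self, role: str) -> LineSpec:
        found = [l for l in self.lines if l.role == role]
        if len(found) != 1:
            raise ValueError(f"panel must declare exactly one {role} line")
        return found[0]

    def disomic_by_chromosome(self) -> Dict[str, LineSpec]:
        return {l.content[0]: l for l in self.lines if l.role == ROLE_DISOMIC}

    def telo_by_arm(self) -> Dict[str, LineSpec]:
        return {l.content[0]: l for l in self.lines if l.role == ROLE_TELO}

    def chromosomes(self) -> List[str]:
        return sorted(self.disomic_by_chromosome())

    # -- serialisation -----------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "line_id": [l.line_id for l in self.lines],
                "role": [l.role for l in self.lines],
                "content": [",".join(l.content) for l in self.lines],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, host_id: str = "host", alien_id: str = "alien") -> "LinePanel":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        lines = [
            LineSpec(
                line_id=str(r.line_id),
                role=str(r.role),
                content=tuple(c for c in str(r.content).split(",") if c),
            )
            for r in df.itertuples()
        ]
        return cls(lines=lines, host_id=host_id, alien_id=alien_id)
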