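"""Chromosome and arm assignment from panel amplification patterns.

The three-step funnel: a marker must (1) amplify in every donor cultivar
but not the host to count as universal alien-specific, (2) amplify in the
alien control and exactly one disomic addition line to be placed on a
chromosome, and (3) amplify in exactly one of that chromosome's two
ditelosomic addition lines to be placed on an arm.  A positive in any
non-corresponding ditelosomic line rejects the marker (conservative
reading of the "but not in others" rule); positives in both or neither
corresponding ditelosomic lines leave the marker placed at chromosome
level only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from alienmark.panel import LinePanel, ROLE_DISOMIC, ROLE_TELO

STATUS_UNIVERSAL = "universal_specific"
STATUS_CHROMOSOME = "chromosome_assigned"
STATUS_ARM = "arm_assigned"
STATUS_REJECTED = "rejected"


@dataclass(frozen=True)
class ArmAssignment:
    marker_id: str
    status: str
    chromosome: Optional[str] = None
    arm: Optional[str] = None  # "S" or "L"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.arm is not None and self.chromosome is None:
            raise ValueError("arm set without chromosome")
        if self.status == STATUS_REJECTED and (self.chromosome or self.arm):
            raise ValueError("rejected assignment must carry no location")

    @property
    def arm_id(self) -> Optional[str]:
        return self.chromosome + self.arm if self.arm else None


def screen_universal(
    pattern: Mapping[str, bool],
    cultivars: Sequence[str],
    host: str,
) -> bool:
    """True iff a band is present in every donor cultivar and absent in the host."""
    for key in list(cultivars) + [host]:
        if key not in pattern:
            raise KeyError(f"pattern is missing a lane for {key!r}")
    return all(pattern[c] for c in cultivars) and not pattern[host]


def assign_chromosome(
    marker_id: str,
    row: Mapping[str, bool],
    panel: LinePanel,
) -> ArmAssignment:
    """Place a marker on a chromosome from its disomic-addition pattern."""
    host = panel.host_control()
    alien = panel.alien_control()
    disomic = panel.disomic_by_chromosome()
    if not disomic:
        raise ValueError("panel declares no disomic addition lines")
    for line in [host, alien] + list(disomic.values()):
        if line.line_id not in row:
            raise KeyError(f"amplification row is missing line {line.line_id!r}")

    if row[host.line_id]:
        return ArmAssignment(marker_id, STATUS_REJECTED, reason="not alien-specific")
    if not row[alien.line_id]:
        return ArmAssignment(
            marker_id, STATUS_REJECTED, reason="no alien-control amplification"
        )
    positive = [chrom for chrom, line in disomic.items() if row[line.line_id]]
    if len(positive) == 0:
        return ArmAssignment(marker_id, STATUS_REJECTED, reason="no disomic positive")
    if len(positive) > 1:
        return ArmAssignment(marker_id, STATUS_REJECTED, reason="multi-chromosome")
    return ArmAssignment(
        marker_id, STATUS_CHROMOSOME, chromosome=positive[0], reason="single disomic positive"
    )


def assign_arm(
    assignment: ArmAssignment,
    row: Mapping[str, bool],
    panel: LinePanel,
) -> ArmAssignment:
    """Refine a chromosome-level assignment to an arm from ditelosomic lines."""
    if assignment.status != STATUS_CHROMOSOME:
        raise ValueError("arm assignment requires a chromosome_assigned marker")
    chrom = assignment.chromosome
    telo = panel.telo_by_arm()
    own = {arm_id: line for arm_id, line in telo.items() if arm_id[:-1] == chrom}
    if len(own) != 2:
        raise ValueError(f"panel lacks the two ditelosomic lines of {chrom}")
    for line in telo.values():
        if line.line_id not in row:
            raise KeyError(f"amplification row is missing line {line.line_id!r}")

    foreign_positive = [
        arm_id for arm_id, line in telo.items() if arm_id[:-1] != chrom and row[line.line_id]
    ]
    if foreign_positive:
        return ArmAssignment(
            assignment.marker_id,
            STATUS_REJECTED,
            reason=f"non-corresponding ditelosomic positive ({','.join(sorted(foreign_positive))})",
        )
    own_positive = [arm_id for arm_id, line in own.items() if row[line.line_id]]
    if len(own_positive) == 1:
        return replace(
            assignment,
            status=STATUS_ARM,
            arm=own_positive[0][-1],
            reason="single corresponding ditelosomic positive",
        )
    reason = "arm-ambiguous" if len(own_positive) == 2 else "no ditelosomic positive"
    return replace(assignment, reason=reason)


def validate_universality(
    assignment: ArmAssignment,
    row: Mapping[str, bool],
    second_panel: LinePanel,
) -> bool:
    """Check an assigned marker on an independent second addition-line panel.

    True iff the marker amplifies in the second panel's alien control and
    the addition line corresponding to its chromosome, and in nothing else
    (second host control and all non-corresponding lines negative).  Never
    upgrades a rejected marker.
    """
    if assignment.status == STATUS_REJECTED or assignment.chromosome is None:
        return False
    disomic = second_panel.disomic_by_chromosome()
    if assignment.chromosome not in disomic:
        raise ValueError(
            f"second panel has no addition line for chromosome {assignment.chromosome}"
        )
    host = second_panel.host_control()
    alien = second_panel.alien_control()
    corresponding = {disomic[assignment.chromosome].line_id, alien.line_id}
    if assignment.arm is not None:
        for line in second_panel.lines:
            if line.role == ROLE_TELO and line.content[0] == assignment.arm_id:
                corresponding.add(line.line_id)
    for line in second_panel.lines:
        if line.line_id not in row:
            raise KeyError(f"second-panel row is missing line {line.line_id!r}")
        expected = line.line_id in corresponding
        if line.role in (ROLE_DISOMIC, ROLE_TELO) and not expected:
            # non-corresponding lines may legitimately contain the marker's
            # chromosome arm only if they carry that chromosome; they do not.
            if row[line.line_id]:
                return False
        elif line.role not in (ROLE_DISOMIC, ROLE_TELO):
            if line.line_id == host.line_id and row[line.line_id]:
                return False
    if not row[alien.line_id]:
        return False
    if not row[disomic[assignment.chromosome].line_id]:
        return False
    return True
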