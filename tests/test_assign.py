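"""The three-step assignment rule engine, checked exhaustively against an
independently written truth-table implementation."""

import itertools

import pytest

from alienmark.assign import (
    STATUS_ARM,
    STATUS_CHROMOSOME,
    STATUS_REJECTED,
    ArmAssignment,
    assign_arm,
    assign_chromosome,
    screen_universal,
    validate_universality,
)
from alienmark.panel import (
    LinePanel,
    LineSpec,
    ROLE_ALIEN,
    ROLE_DISOMIC,
    ROLE_HOST,
    ROLE_TELO,
)


def make_panel(chromosomes=("1R", "2R", "3R")) -> LinePanel:
    lines = [LineSpec("host", ROLE_HOST, ()), LineSpec("alien", ROLE_ALIEN, tuple(chromosomes))]
    for c in chromosomes:
        lines.append(LineSpec(f"DA_{c}", ROLE_DISOMIC, (c,)))
        lines.append(LineSpec(f"DT_{c}S", ROLE_TELO, (c + "S",)))
        lines.append(LineSpec(f"DT_{c}L", ROLE_TELO, (c + "L",)))
    return LinePanel(lines=lines, host_id="host", alien_id="alien")


def engine(row, panel):
    a = assign_chromosome("m", row, panel)
    if a.status == STATUS_CHROMOSOME:
        a = assign_arm(a, row, panel)
    return a


def oracle(row, chromosomes):
    """Direct restatement of the screening rules, written independently of
    the engine: alien control positive, host negative, exactly one disomic
    positive gives the chromosome; then exactly one of that chromosome's
    two ditelosomic lines positive (and no other ditelosomic line anywhere
    positive) gives the arm."""
    if row["host"] or not row["alien"]:
        return ("rejected", None, None)
    disomics = [c for c in chromosomes if row[f"DA_{c}"]]
    if len(disomics) != 1:
        return ("rejected", None, None)
    chrom = disomics[0]
    foreign = [
        c + a for c in chromosomes for a in "SL"
        if c != chrom and row[f"DT_{c}{a}"]
    ]
    if foreign:
        return ("rejected", None, None)
    own = [a for a in "SL" if row[f"DT_{chrom}{a}"]]
    if len(own) == 1:
        return ("arm_assigned", chrom, own[0])
    return ("chromosome_assigned", chrom, None)


class TestScreenUniversal:
    CULTIVARS = ["cv1", "cv2", "cv3"]

    def test_all_cultivars_positive_host_negative(self):
        pattern = {c: True for c in self.CULTIVARS} | {"host": False}
        assert screen_universal(pattern, self.CULTIVARS, "host")

    def test_one_cultivar_negative(self):
        pattern = {"cv1": True, "cv2": False, "cv3": True, "host": False}
        assert not screen_universal(pattern, self.CULTIVARS, "host")

    def test_host_positive(self):
        pattern = {c: True for c in self.CULTIVARS} | {"host": True}
        assert not screen_universal(pattern, self.CULTIVARS, "host")

    def test_missing_lane_is_an_error(self):
        with pytest.raises(KeyError):
            screen_universal({"cv1": True, "host": False}, self.CULTIVARS, "host")


class TestAssignmentExamples:
    def test_single_disomic_gives_chromosome(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_3R": True}
        a = assign_chromosome("m", row, panel)
        assert (a.status, a.chromosome) == (STATUS_CHROMOSOME, "3R")

    def test_two_disomics_rejected_multichromosome(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_1R": True, "DA_2R": True}
        a = assign_chromosome("m", row, panel)
        assert a.status == STATUS_REJECTED and a.reason == "multi-chromosome"

    def test_host_positive_rejected_not_specific(self):
        panel = make_panel()
        row = {l.line_id: True for l in panel.lines}
        a = assign_chromosome("m", row, panel)
        assert a.status == STATUS_REJECTED and a.reason == "not alien-specific"

    def test_single_corresponding_telo_gives_arm(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_3R": True, "DT_3RS": True}
        a = engine(row, panel)
        assert (a.status, a.arm_id) == (STATUS_ARM, "3RS")

    def test_long_arm_assignment(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_2R": True, "DT_2RL": True}
        a = engine(row, panel)
        assert (a.status, a.arm_id) == (STATUS_ARM, "2RL")

    def test_both_telos_stay_chromosome_level(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_3R": True, "DT_3RS": True, "DT_3RL": True}
        a = engine(row, panel)
        assert a.status == STATUS_CHROMOSOME
        assert a.arm is None
        assert a.reason == "arm-ambiguous"

    def test_foreign_telo_rejects(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_3R": True, "DT_3RS": True, "DT_1RL": True}
        a = engine(row, panel)
        assert a.status == STATUS_REJECTED

    def test_missing_telo_lane_is_an_error(self):
        panel = make_panel()
        row = {l.line_id: False for l in panel.lines}
        row |= {"alien": True, "DA_3R": True}
        del row["DT_1RS"]
        with pytest.raises(KeyError):
            engine(row, panel)


class TestExhaustiveOracle:
    def test_rule_engine_matches_truth_table_on_all_patterns(self):
        """Every presence/absence pattern over an 11-line panel (2 controls,
        3 disomics, 6 ditelosomics) agrees exactly with the independent
        truth-table implementation."""
        chromosomes = ("1R", "2R", "3R")
        panel = make_panel(chromosomes)
        line_ids = [l.line_id for l in panel.lines]
        assert len(line_ids) == 11
        for bits in itertools.product([False, True], repeat=len(line_ids)):
            row = dict(zip(line_ids, bits))
            a = engine(row, panel)
            expected = oracle(row, chromosomes)
            assert (a.status, a.chromosome, a.arm) == expected, row


class TestSecondPanelValidation:
    def second_panel(self):
        return make_panel(("1R", "2R", "3R"))

    def _row(self, panel, positives):
        row = {l.line_id: False for l in panel.lines}
        row |= {p: True for p in positives}
        return row

    def test_corresponding_addition_positive_validates(self):
        panel = self.second_panel()
        a = ArmAssignment("m", STATUS_ARM, chromosome="2R", arm="L")
        row = self._row(panel, ["alien", "DA_2R", "DT_2RL"])
        assert validate_universality(a, row, panel)

    def test_negative_in_corresponding_line_fails(self):
        panel = self.second_panel()
        a = ArmAssignment("m", STATUS_ARM, chromosome="2R", arm="L")
        row = self._row(panel, ["alien"])
        assert not validate_universality(a, row, panel)

    def test_positive_in_second_host_fails(self):
        panel = self.second_panel()
        a = ArmAssignment("m", STATUS_ARM, chromosome="2R", arm="L")
        row = self._row(panel, ["host", "alien", "DA_2R", "DT_2RL"])
        assert not validate_universality(a, row, panel)

    def test_rejected_marker_is_never_upgraded(self):
        panel = self.second_panel()
        a = ArmAssignment("m", STATUS_REJECTED, reason="multi-chromosome")
        row = self._row(panel, ["alien", "DA_2R"])
        assert not validate_universality(a, row, panel)

    def test_unknown_chromosome_is_an_error(self):
        panel = self.second_panel()
        a = ArmAssignment("m", STATUS_ARM, chromosome="9R", arm="S")
        with pytest.raises(ValueError, match="no addition line"):
            validate_universality(a, self._row(panel, ["alien"]), panel)
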